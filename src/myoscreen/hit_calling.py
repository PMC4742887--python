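"""Two-criterion, replicate-aware hit calling and cross-arm comparison.

A well scores positive when the knockdown (a) significantly increases the
Myogenin-positive fraction relative to the GM negative-control wells of the
same plate (one-sided pooled-variance Student's t-test at alpha = 0.05 on
the per-site fractions) and (b) decreases the well's mean nuclei count per
the cell-number criterion. A kinase is a hit when enough replicate wells
are positive: 2 of 3 in the vehicle arm, 3 of 3 in the sensitizer arm. In
the sensitizer arm the cell-number criterion is disabled, because the
CDK4/6 inhibitor suppresses myoblast cell number independently of any
knockdown.

The cell-number criterion exists in two dialects:

* ``methods`` (default): well mean nuclei <= median(GM reference) - 1 MAD
  (raw, unscaled MAD of GM well means);
* ``results``: well mean nuclei at or below median(DM+I reference) + 1 MAD,
  i.e., the count has fallen to within one MAD of the differentiated
  positive-control level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normalize_qc import (
    EmptyWellError,
    mad,
    robust_scale,
    summarize_well,
)
from .screen_data import (
    ARM_SENSITIZER,
    ScreenDataset,
    ScreenValidationError,
    Well,
    WellRole,
)

__all__ = [
    "HitCallConfig",
    "WellScore",
    "KinaseCall",
    "HitComparison",
    "score_well",
    "call_kinase",
    "call_screen",
    "compare_arms",
    "cell_number_only_report",
    "calls_to_frame",
    "hit_genes",
]

logger = logging.getLogger(__name__)

CellDialect = Literal["methods", "results"]


@dataclass(frozen=True)
class HitCallConfig:
    """Thresholds and rule variants of the hit-calling procedure."""

    alpha: float = 0.05
    replicate_rule_vehicle: int = 2
    replicate_rule_sensitizer: int = 3
    cell_criterion_dialect: CellDialect = "methods"
    cell_criterion_in_sensitizer: bool = False
    mad_multiplier: float = 1.0
    t_test_unit: Literal["sites", "replicate_means"] = "sites"
    t_test_sided: Literal["one_sided_increase", "two_sided"] = "one_sided_increase"
    kinase_z_reference: Literal["experimental", "gm"] = "experimental"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("replicate_rule_vehicle", "replicate_rule_sensitizer"):
            v = getattr(self, name)
            if not 1 <= v <= 3:
                raise ValueError(f"{name} must be in 1..3, got {v}")

    def replicate_minimum(self, arm: str) -> int:
        return (
            self.replicate_rule_sensitizer
            if arm == ARM_SENSITIZER
            else self.replicate_rule_vehicle
        )

    def cell_criterion_enabled(self, arm: str) -> bool:
        return arm != ARM_SENSITIZER or self.cell_criterion_in_sensitizer


@dataclass(frozen=True)
class WellScore:
    """Per-well positivity decision under both criteria."""

    gene: str | None
    arm: str
    replicate_index: int
    p_value: float
    myog_positive: bool
    cell_positive: bool
    well_positive: bool
    plate_id: str = ""
    well_coordinate: str = ""
    insufficient_data: bool = False


@dataclass(frozen=True)
class KinaseCall:
    """Replicate-aggregated call for one kinase in one arm."""

    gene: str
    arm: str
    n_positive_replicates: int
    is_hit: bool
    kinase_z: float = float("nan")
    min_p: float = float("nan")


@dataclass(frozen=True)
class HitComparison:
    """Set algebra between the vehicle-arm and sensitizer-arm hit lists."""

    hits_vehicle: frozenset[str]
    hits_sensitizer: frozenset[str]
    library_size: int

    @property
    def double_hits(self) -> frozenset[str]:
        return self.hits_vehicle & self.hits_sensitizer

    @property
    def union_hits(self) -> frozenset[str]:
        return self.hits_vehicle | self.hits_sensitizer

    def _rate(self, count: int) -> float:
        return round(100.0 * count / self.library_size, 1)

    @property
    def rates(self) -> dict[str, float]:
        """Hit rates as percentages of the library, one-decimal precision."""
        return {
            "vehicle": self._rate(len(self.hits_vehicle)),
            "sensitizer": self._rate(len(self.hits_sensitizer)),
            "double": self._rate(len(self.double_hits)),
            "union": self._rate(len(self.union_hits)),
        }

    def to_dict(self) -> dict:
        return {
            "n_vehicle_hits": len(self.hits_vehicle),
            "n_sensitizer_hits": len(self.hits_sensitizer),
            "n_double_hits": len(self.double_hits),
            "n_union_hits": len(self.union_hits),
            "library_size": self.library_size,
            "rates_percent": self.rates,
            "double_hits": sorted(self.double_hits),
        }


# ---- the Myogenin t-test criterion --------------------------------


def _students_t_p(sample: np.ndarray, reference: np.ndarray, sided: str) -> float:
    """Pooled-variance Student's t p-value with degenerate-variance limits.

    If both samples are constant: p = 1 when the means are equal; otherwise
    p = 0 for the favorable direction (or two-sided), 1 against it.
    """
    # exact-constancy guard: near-constant samples otherwise produce
    # catastrophic-cancellation variances (~1e-35) and a spurious t
    if np.ptp(sample) == 0.0 and np.ptp(reference) == 0.0:
        diff = sample[0] - reference[0]
        if diff == 0.0:
            return 1.0
        if sided == "two_sided":
            return 0.0
        return 0.0 if diff > 0 else 1.0
    alternative = "greater" if sided == "one_sided_increase" else "two-sided"
    res = stats.ttest_ind(sample, reference, equal_var=True, alternative=alternative)
    return float(res.pvalue)


@dataclass(frozen=True)
class _CellReference:
    """Precomputed cell-number thresholds for one plate/arm."""

    gm_median: float
    gm_mad: float
    dmi_median: float | None
    dmi_mad: float | None

    def cell_positive(self, mean_nuclei: float, config: HitCallConfig) -> bool:
        if config.cell_criterion_dialect == "methods":
            return mean_nuclei <= self.gm_median - config.mad_multiplier * self.gm_mad
        if self.dmi_median is None:
            raise ScreenValidationError(
                "results dialect requires DM+I reference wells on the plate"
            )
        return mean_nuclei <= self.dmi_median + config.mad_multiplier * self.dmi_mad


def _cell_reference(
    gm_reference_wells: Sequence[Well],
    dmi_reference_wells: Sequence[Well] | None,
) -> _CellReference:
    gm_means = []
    for w in gm_reference_wells:
        try:
            gm_means.append(summarize_well(w).mean_nuclei)
        except EmptyWellError:
            continue
    if not gm_means:
        raise ScreenValidationError("no summarizable GM reference wells")
    dmi_median = dmi_mad = None
    if dmi_reference_wells:
        dmi_means = []
        for w in dmi_reference_wells:
            try:
                dmi_means.append(summarize_well(w).mean_nuclei)
            except EmptyWellError:
                continue
        if dmi_means:
            dmi_median = float(np.median(dmi_means))
            dmi_mad = mad(dmi_means)
    return _CellReference(
        gm_median=float(np.median(gm_means)),
        gm_mad=mad(gm_means),
        dmi_median=dmi_median,
        dmi_mad=dmi_mad,
    )


def _pooled_site_fractions(wells: Sequence[Well]) -> np.ndarray:
    fracs: list[float] = []
    for w in wells:
        try:
            fracs.extend(summarize_well(w).site_fractions)
        except EmptyWellError:
            continue
    return np.asarray(fracs, dtype=float)


def score_well(
    well: Well,
    gm_reference_wells: Sequence[Well],
    config: HitCallConfig | None = None,
    dmi_reference_wells: Sequence[Well] | None = None,
) -> WellScore:
    """Score one well against same-plate GM (and optionally DM+I) references.

    The Myogenin criterion compares the well's per-site Myogenin fractions
    against the pooled site fractions of the GM reference wells; the
    cell-number criterion compares the well's mean nuclei per site against
    the reference median and raw MAD per the configured dialect. Wells with
    fewer than 2 usable site fractions on either side are scored
    not-positive and flagged.
    """
    if config is None:
        config = HitCallConfig()
    gm_fracs = _pooled_site_fractions(gm_reference_wells)
    cell_ref = _cell_reference(gm_reference_wells, dmi_reference_wells)
    return _score_well_fast(well, gm_fracs, cell_ref, config)


def _score_well_fast(
    well: Well,
    gm_site_fractions: np.ndarray,
    cell_ref: _CellReference,
    config: HitCallConfig,
) -> WellScore:
    try:
        summary = summarize_well(well)
    except EmptyWellError:
        return WellScore(
            gene=well.gene_key,
            arm=well.arm,
            replicate_index=well.replicate_index,
            p_value=float("nan"),
            myog_positive=False,
            cell_positive=False,
            well_positive=False,
            plate_id=well.plate_id,
            well_coordinate=well.well_coordinate,
            insufficient_data=True,
        )
    fracs = np.asarray(summary.site_fractions, dtype=float)
    if fracs.size < 2 or gm_site_fractions.size < 2:
        logger.warning(
            "well %s/%s: <2 usable site fractions; scored not-positive",
            well.plate_id,
            well.well_coordinate,
        )
        p = float("nan")
        myog_positive = False
        insufficient = True
    else:
        p = _students_t_p(fracs, gm_site_fractions, config.t_test_sided)
        if config.t_test_sided == "two_sided":
            myog_positive = p < config.alpha and fracs.mean() > gm_site_fractions.mean()
        else:
            myog_positive = p < config.alpha
        insufficient = False
    cell_positive = cell_ref.cell_positive(summary.mean_nuclei, config)
    if config.cell_criterion_enabled(well.arm):
        well_positive = myog_positive and cell_positive
    else:
        well_positive = myog_positive
    return WellScore(
        gene=well.gene_key,
        arm=well.arm,
        replicate_index=well.replicate_index,
        p_value=p,
        myog_positive=myog_positive,
        cell_positive=cell_positive,
        well_positive=well_positive,
        plate_id=well.plate_id,
        well_coordinate=well.well_coordinate,
        insufficient_data=insufficient,
    )


# ---- replicate aggregation ----------------------------------------


def call_kinase(
    well_scores: Sequence[WellScore],
    config: HitCallConfig | None = None,
    kinase_z: float = float("nan"),
) -> KinaseCall:
    """Aggregate one gene's replicate well scores into a hit call.

    Vehicle arm: hit iff >= 2 of 3 wells positive; sensitizer arm: all 3.
    """
    if config is None:
        config = HitCallConfig()
    genes = {s.gene for s in well_scores}
    arms = {s.arm for s in well_scores}
    if len(genes) != 1 or len(arms) != 1:
        raise ScreenValidationError(
            f"well scores mix genes {genes} / arms {arms}; one gene+arm required"
        )
    if len(well_scores) != 3:
        raise ScreenValidationError(
            f"expected 3 replicate scores, got {len(well_scores)}"
        )
    arm = next(iter(arms))
    n_pos = sum(1 for s in well_scores if s.well_positive)
    p_values = [s.p_value for s in well_scores if not np.isnan(s.p_value)]
    return KinaseCall(
        gene=next(iter(genes)),
        arm=arm,
        n_positive_replicates=n_pos,
        is_hit=n_pos >= config.replicate_minimum(arm),
        kinase_z=kinase_z,
        min_p=min(p_values) if p_values else float("nan"),
    )


def _score_dataset_wells(
    dataset: ScreenDataset, config: HitCallConfig
) -> dict[tuple[str, str], list[WellScore]]:
    """Score every experimental well; returns scores keyed by (gene, arm)."""
    gm_fracs_cache: dict[str, np.ndarray] = {}
    cell_ref_cache: dict[str, _CellReference] = {}
    for plate_id in dataset.plate_ids:
        gm = dataset.wells_where(plate_id=plate_id, role=WellRole.GM_NEG_CONTROL)
        dmi = dataset.wells_where(plate_id=plate_id, role=WellRole.DM_I_POS_CONTROL)
        if not gm:
            raise ScreenValidationError(f"plate {plate_id} has no GM reference wells")
        gm_fracs_cache[plate_id] = _pooled_site_fractions(gm)
        cell_ref_cache[plate_id] = _cell_reference(gm, dmi or None)
    scores: dict[tuple[str, str], list[WellScore]] = {}
    for (gene, arm), wells in sorted(dataset.replicate_wells().items()):
        scores[(gene, arm)] = [
            _score_well_fast(w, gm_fracs_cache[w.plate_id], cell_ref_cache[w.plate_id], config)
            for w in wells
        ]
    return scores


def _kinase_z_scores(
    dataset: ScreenDataset, config: HitCallConfig
) -> dict[tuple[str, str], float]:
    """Robust Z of each kinase's mean percent-Myogenin (reporting only).

    The reference population is, per arm, the per-kinase means of all
    kinases sharing the same set of physical plates (i.e., the same library
    plate), or the GM control wells when configured.
    """
    means: dict[tuple[str, str], float] = {}
    plate_groups: dict[tuple[str, str], frozenset[str]] = {}
    for (gene, arm), wells in dataset.replicate_wells().items():
        pcts = []
        for w in wells:
            try:
                pcts.append(summarize_well(w).percent_myogenin)
            except EmptyWellError:
                continue
        if pcts:
            means[(gene, arm)] = float(np.mean(pcts))
            plate_groups[(gene, arm)] = frozenset(w.plate_id for w in wells)
    out: dict[tuple[str, str], float] = {}
    by_group: dict[tuple[str, frozenset[str]], list[tuple[str, float]]] = {}
    for (gene, arm), m in means.items():
        by_group.setdefault((arm, plate_groups[(gene, arm)]), []).append((gene, m))
    for (arm, plates), members in by_group.items():
        if config.kinase_z_reference == "gm":
            ref = [
                summarize_well(w).percent_myogenin
                for pid in plates
                for w in dataset.wells_where(plate_id=pid, role=WellRole.GM_NEG_CONTROL, arm=arm)
                if sum(s.total_nuclei for s in w.sites) > 0
            ]
        else:
            ref = [m for _, m in members]
        try:
            scale = robust_scale(ref)
        except Exception:
            for gene, _ in members:
                out[(gene, arm)] = float("nan")
            continue
        for gene, m in members:
            out[(gene, arm)] = float(scale.z([m])[0])
    return out


def call_screen(dataset: ScreenDataset, config: HitCallConfig | None = None) -> list[KinaseCall]:
    """Call every library kinase in every arm present in the dataset.

    Deterministic given (dataset, config) and invariant to well ordering.
    Genes with missing replicate wells are excluded from calls and logged.
    """
    if config is None:
        config = HitCallConfig()
    scores = _score_dataset_wells(dataset, config)
    kz = _kinase_z_scores(dataset, config)
    calls: list[KinaseCall] = []
    for (gene, arm), well_scores in sorted(scores.items()):
        if len(well_scores) != 3:
            logger.warning(
                "gene %s arm %s: %d replicate wells (need 3); excluded from calls",
                gene,
                arm,
                len(well_scores),
            )
            continue
        if config.t_test_unit == "replicate_means":
            well_scores = _rescore_replicate_means(dataset, gene, arm, well_scores, config)
        calls.append(call_kinase(well_scores, config, kinase_z=kz.get((gene, arm), float("nan"))))
    return calls


def _rescore_replicate_means(
    dataset: ScreenDataset,
    gene: str,
    arm: str,
    well_scores: Sequence[WellScore],
    config: HitCallConfig,
) -> list[WellScore]:
    """Alternative t-test unit: 3 replicate well means vs. GM well means.

    The gene-level p-value replaces each well's site-level p; a well is
    Myogenin-positive iff the gene-level test is significant, so the
    replicate rule then reduces to the cell-number criterion.
    """
    wells = dataset.replicate_wells()[(gene, arm)]
    gene_pcts, gm_pcts = [], []
    for w in wells:
        try:
            gene_pcts.append(summarize_well(w).percent_myogenin)
        except EmptyWellError:
            continue
        for g in dataset.wells_where(plate_id=w.plate_id, role=WellRole.GM_NEG_CONTROL, arm=arm):
            try:
                gm_pcts.append(summarize_well(g).percent_myogenin)
            except EmptyWellError:
                continue
    if len(gene_pcts) < 2 or len(gm_pcts) < 2:
        return list(well_scores)
    p = _students_t_p(np.asarray(gene_pcts), np.asarray(gm_pcts), config.t_test_sided)
    myog = p < config.alpha
    out = []
    for s in well_scores:
        well_positive = myog and (
            s.cell_positive if config.cell_criterion_enabled(arm) else True
        )
        out.append(
            replace(s, p_value=p, myog_positive=myog, well_positive=well_positive)
        )
    return out


# ---- cross-arm comparison and reports -----------------------------


def hit_genes(calls: Iterable[KinaseCall], arm: str | None = None) -> frozenset[str]:
    return frozenset(
        c.gene for c in calls if c.is_hit and (arm is None or c.arm == arm)
    )


def compare_arms(
    calls_vehicle: Iterable[KinaseCall],
    calls_sensitizer: Iterable[KinaseCall],
    library_size: int,
) -> HitComparison:
    """Set algebra between the two arms' hit lists.

    Both call tables must cover the same gene universe; rates are reported
    as percentages of the library to one decimal.
    """
    veh = list(calls_vehicle)
    sen = list(calls_sensitizer)
    universe_v = {c.gene for c in veh}
    universe_s = {c.gene for c in sen}
    if universe_v != universe_s:
        raise ScreenValidationError(
            f"call tables cover different gene universes "
            f"({len(universe_v)} vs {len(universe_s)} genes)"
        )
    return HitComparison(
        hits_vehicle=hit_genes(veh),
        hits_sensitizer=hit_genes(sen),
        library_size=library_size,
    )


def cell_number_only_report(
    dataset: ScreenDataset, config: HitCallConfig | None = None
) -> pd.DataFrame:
    """Wells/genes meeting the cell-number criterion without Myogenin gain.

    Mirrors the observation that knocking down core cell-cycle kinases
    depletes cells without inducing Myogenin: reports, per arm, the number
    of experimental wells that are cell-positive but not Myogenin-positive,
    and the genes whose replicate wells meet the cell criterion at the arm's
    replicate rule yet are not hits (disjoint from the hit list by
    construction).
    """
    if config is None:
        config = HitCallConfig()
    scores = _score_dataset_wells(dataset, config)
    rows = []
    arms = sorted({arm for _, arm in scores})
    for arm in arms:
        n_cell_only_wells = 0
        genes = []
        for (gene, a), well_scores in scores.items():
            if a != arm:
                continue
            n_cell_only_wells += sum(
                1 for s in well_scores if s.cell_positive and not s.myog_positive
            )
            if len(well_scores) != 3:
                continue
            n_cell = sum(1 for s in well_scores if s.cell_positive)
            n_pos = sum(1 for s in well_scores if s.well_positive)
            is_hit = n_pos >= config.replicate_minimum(arm)
            if n_cell >= config.replicate_minimum(arm) and not is_hit:
                genes.append(gene)
        rows.append(
            {
                "arm": arm,
                "n_cell_only_wells": n_cell_only_wells,
                "n_genes": len(genes),
                "genes": tuple(sorted(genes)),
            }
        )
    return pd.DataFrame(rows)


def calls_to_frame(calls: Iterable[KinaseCall]) -> pd.DataFrame:
    """Hit table as a DataFrame (gene, arm, replicates, hit flag, Z, min p)."""
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "arm": c.arm,
                "n_positive_replicates": c.n_positive_replicates,
                "is_hit": c.is_hit,
                "kinase_z": c.kinase_z,
                "min_p": c.min_p,
            }
            for c in sorted(calls, key=lambda c: (c.arm, c.gene))
        ]
    )
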