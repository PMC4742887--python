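"""Seeded simulator of kinome siRNA screen datasets.

The generator emulates the screen's physical design — two 384-well library
plates, each run in triplicate under a vehicle arm and a CDK4/6-inhibitor
(sensitizer) arm, with 32 growth-medium (GM) negative-control and 32
differentiation-medium-plus-insulin (DM+I) positive-control wells per plate
— and its assumed statistical structure:

* per-site total nuclei are negative-binomial (overdispersed counts);
* per-site Myogenin-positive nuclei are beta-binomial around a fraction set
  on the logit scale, so knockdown and sensitizer effects compose as odds
  multipliers and fractions stay in (0, 1);
* the baseline Myogenin-positive fraction is low in GM and high in DM+I;
* the sensitizer suppresses cell number globally, independent of knockdown,
  and by default adds no detectable Myogenin shift of its own;
* planted hit genes perturb the differentiation odds and/or proliferation
  only in their own experimental wells.

A ground-truth table of planted effects accompanies every dataset so hit
recovery can be measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_data import (
    ARM_SENSITIZER,
    ARMS,
    PAPER_PLATE_LAYOUTS,
    KinaseLibrary,
    ScreenDataset,
    ScreenValidationError,
    SiteMeasurement,
    Well,
    WellRole,
    normalize_symbol,
)

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "GroundTruth",
    "default_library",
    "build_layouts",
    "simulate_screen",
    "truth_recovery_report",
]

_ROWS = "ABCDEFGHIJKLMNOP"


@dataclass(frozen=True)
class PlantedEffect:
    """Knockdown effect for one planted gene.

    ``differentiation_odds_multiplier`` scales the odds of a nucleus being
    Myogenin-positive; ``proliferation_multiplier`` in (0, 1] scales the
    expected nuclei count per site.
    """

    differentiation_odds_multiplier: float = 1.0
    proliferation_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.differentiation_odds_multiplier <= 0:
            raise ValueError("differentiation_odds_multiplier must be positive")
        if not 0 < self.proliferation_multiplier <= 1:
            raise ValueError("proliferation_multiplier must be in (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Defaults describe the screen's design conditions: a ~2% Myogenin-positive
    fraction in proliferating GM myoblasts, a ~40% fraction in DM+I
    positive-control wells, ~250 nuclei per imaged site in GM, a sensitizer
    that halves cell number everywhere while adding no detectable Myogenin
    shift on its own, and 4 imaged sites per well.
    """

    seed: int = 0
    n_sites_per_well: int = 4
    gm_myog_fraction: float = 0.02
    dmi_myog_fraction: float = 0.40
    gm_mean_nuclei_per_site: float = 250.0
    nuclei_dispersion: float = 10.0
    site_overdispersion: float = 0.01
    planted_hits: Mapping[str, PlantedEffect] = field(default_factory=dict)
    sensitizer_proliferation_multiplier: float = 0.5
    sensitizer_myog_shift: float = 1.0
    dmi_proliferation_multiplier: float = 0.5
    kif11_proliferation_multiplier: float = 0.3
    # optional plate-position hooks (additive logit/log offsets); off by default
    row_logit_offsets: Mapping[str, float] = field(default_factory=dict)
    col_logit_offsets: Mapping[int, float] = field(default_factory=dict)
    row_log_nuclei_offsets: Mapping[str, float] = field(default_factory=dict)
    col_log_nuclei_offsets: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("gm_myog_fraction", "dmi_myog_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.gm_mean_nuclei_per_site <= 0 or self.nuclei_dispersion <= 0:
            raise ValueError("nuclei mean and dispersion must be positive")
        if not 0 <= self.site_overdispersion < 1:
            raise ValueError("site_overdispersion must be in [0, 1)")
        for name in (
            "sensitizer_proliferation_multiplier",
            "dmi_proliferation_multiplier",
            "kif11_proliferation_multiplier",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.sensitizer_myog_shift <= 0:
            raise ValueError("sensitizer_myog_shift must be positive")
        if self.n_sites_per_well < 1:
            raise ValueError("n_sites_per_well must be >= 1")


@dataclass(frozen=True)
class GroundTruthRecord:
    gene: str
    is_planted_hit: bool
    differentiation_odds_multiplier: float
    proliferation_multiplier: float


@dataclass
class GroundTruth:
    """Per-gene planted effects; keys are normalized library symbols."""

    records: dict[str, GroundTruthRecord]

    @property
    def planted_genes(self) -> set[str]:
        return {g for g, r in self.records.items() if r.is_planted_hit}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_symbol": r.gene,
                    "is_hit": r.is_planted_hit,
                    "odds_multiplier": r.differentiation_odds_multiplier,
                    "proliferation_multiplier": r.proliferation_multiplier,
                }
                for r in sorted(self.records.values(), key=lambda r: r.gene)
            ]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_library(n: int = 571) -> KinaseLibrary:
    """Synthetic stand-in library of ``n`` placeholder kinase symbols."""
    width = len(str(n))
    return KinaseLibrary(tuple(f"KIN{i:0{width}d}" for i in range(1, n + 1)))


def build_layouts(
    library: KinaseLibrary,
    plate_layouts: Sequence[Mapping[WellRole, int]] = PAPER_PLATE_LAYOUTS,
) -> list[list[tuple[str, WellRole, str | None]]]:
    """Assign roles and library genes to plate positions deterministically.

    Returns, per library plate, an ordered list of
    (well_coordinate, role, target_gene). Positions are filled row-major;
    control blocks come first, experimental wells take the remainder with
    genes assigned in library order (plate 1 gets the first block of the
    library, plate 2 the rest).
    """
    capacity = sum(layout.get(WellRole.EXPERIMENTAL, 0) for layout in plate_layouts)
    if library.size > capacity:
        raise ScreenValidationError(
            f"library of {library.size} genes exceeds experimental capacity {capacity}"
        )
    coords = [f"{row}{col}" for row in _ROWS for col in range(1, 25)]
    role_order = [
        WellRole.GM_NEG_CONTROL,
        WellRole.DM_I_POS_CONTROL,
        WellRole.MOCK,
        WellRole.UNIVERSAL_CONTROL,
        WellRole.KIF11_CONTROL,
        WellRole.EXPERIMENTAL,
    ]
    plates: list[list[tuple[str, WellRole, str | None]]] = []
    gene_cursor = 0
    for layout in plate_layouts:
        total = sum(layout.values())
        if total > len(coords):
            raise ScreenValidationError(f"layout of {total} wells exceeds 384 positions")
        plate: list[tuple[str, WellRole, str | None]] = []
        pos = 0
        for role in role_order:
            count = layout.get(role, 0)
            if role is WellRole.EXPERIMENTAL:
                count = min(count, library.size - gene_cursor)
            for _ in range(count):
                gene = None
                if role is WellRole.EXPERIMENTAL:
                    gene = library.gene_symbols[gene_cursor]
                    gene_cursor += 1
                elif role is WellRole.KIF11_CONTROL:
                    gene = "Kif11"
                plate.append((coords[pos], role, gene))
                pos += 1
        plates.append(plate)
    if gene_cursor < library.size:
        raise ScreenValidationError(
            f"{library.size - gene_cursor} library genes did not fit the layout"
        )
    return plates


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_screen(
    config: SimulationConfig,
    library: KinaseLibrary | None = None,
    plate_layouts: Sequence[Mapping[WellRole, int]] = PAPER_PLATE_LAYOUTS,
) -> tuple[ScreenDataset, GroundTruth]:
    """Generate a full screen dataset plus its ground truth.

    Physical plates are named ``LP{i}-{arm}-r{rep}`` for library plate ``i``,
    arm in {vehicle, sensitizer} and replicate 1-3. With a fixed seed the
    output is bit-reproducible.
    """
    if library is None:
        library = default_library()
    layouts = build_layouts(library, plate_layouts)
    planted = {normalize_symbol(g): eff for g, eff in config.planted_hits.items()}
    lib_keys = set(library.normalized_symbols)
    unknown = set(planted) - lib_keys
    if unknown:
        raise ScreenValidationError(f"planted hits not in library: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    r = config.nuclei_dispersion
    rho = config.site_overdispersion
    wells: list[Well] = []

    for plate_index, layout in enumerate(layouts, start=1):
        for arm in ARMS:
            for rep in (1, 2, 3):
                plate_id = f"LP{plate_index}-{arm}-r{rep}"
                for coord, role, gene in layout:
                    mu = config.gm_mean_nuclei_per_site
                    if role is WellRole.DM_I_POS_CONTROL:
                        logit_p = _logit(config.dmi_myog_fraction)
                        mu *= config.dmi_proliferation_multiplier
                    else:
                        logit_p = _logit(config.gm_myog_fraction)
                    if role is WellRole.KIF11_CONTROL:
                        mu *= config.kif11_proliferation_multiplier
                    if role is WellRole.EXPERIMENTAL:
                        eff = planted.get(normalize_symbol(gene))
                        if eff is not None:
                            logit_p += math.log(eff.differentiation_odds_multiplier)
                            mu *= eff.proliferation_multiplier
                    if arm == ARM_SENSITIZER:
                        mu *= config.sensitizer_proliferation_multiplier
                        logit_p += math.log(config.sensitizer_myog_shift)
                    row_letter, col = coord[0], int(coord[1:])
                    logit_p += config.row_logit_offsets.get(row_letter, 0.0)
                    logit_p += config.col_logit_offsets.get(col, 0.0)
                    mu *= math.exp(
                        config.row_log_nuclei_offsets.get(row_letter, 0.0)
                        + config.col_log_nuclei_offsets.get(col, 0.0)
                    )
                    p = _expit(logit_p)

                    totals = rng.negative_binomial(
                        r, r / (r + mu), size=config.n_sites_per_well
                    )
                    if rho > 0:
                        a = p * (1.0 - rho) / rho
                        b = (1.0 - p) * (1.0 - rho) / rho
                        p_sites = rng.beta(a, b, size=config.n_sites_per_well)
                    else:
                        p_sites = np.full(config.n_sites_per_well, p)
                    positives = rng.binomial(totals, p_sites)
                    sites = tuple(
                        SiteMeasurement(int(t), int(m))
                        for t, m in zip(totals, positives)
                    )
                    wells.append(
                        Well(
                            plate_id=plate_id,
                            well_coordinate=coord,
                            role=role,
                            arm=arm,
                            replicate_index=rep,
                            sites=sites,
                            target_gene=gene,
                        )
                    )

    # a gene is a planted *hit* only if it perturbs differentiation odds;
    # purely anti-proliferative plants are recorded but are not hits
    truth = GroundTruth(
        records={
            key: GroundTruthRecord(
                gene=key,
                is_planted_hit=(
                    key in planted
                    and planted[key].differentiation_odds_multiplier != 1.0
                ),
                differentiation_odds_multiplier=(
                    planted[key].differentiation_odds_multiplier if key in planted else 1.0
                ),
                proliferation_multiplier=(
                    planted[key].proliferation_multiplier if key in planted else 1.0
                ),
            )
            for key in library.normalized_symbols
        }
    )
    dataset = ScreenDataset(
        wells=wells,
        library=library,
        metadata={
            "generator": "myoscreen.synthetic_screen.simulate_screen",
            "seed": config.seed,
            "n_planted_hits": len(planted),
        },
    )
    return dataset, truth


def truth_recovery_report(calls: Iterable, truth: GroundTruth) -> pd.DataFrame:
    """Confusion counts and rates of a hit table against the planted truth.

    ``calls`` is an iterable of objects (or mapping rows) with ``gene``,
    ``arm`` and ``is_hit`` fields covering the full library per arm. Returns
    one row per arm with TP/FP/TN/FN, sensitivity and specificity.
    """
    rows = []
    for c in calls:
        if isinstance(c, Mapping):
            rows.append((normalize_symbol(c["gene"]), c["arm"], bool(c["is_hit"])))
        else:
            rows.append((normalize_symbol(c.gene), c.arm, bool(c.is_hit)))
    truth_genes = set(truth.records)
    out = []
    for arm in sorted({arm for _, arm, _ in rows}):
        arm_calls = {g: h for g, a, h in rows if a == arm}
        if set(arm_calls) != truth_genes:
            raise ScreenValidationError(
                f"arm {arm}: call table covers {len(arm_calls)} genes, "
                f"truth covers {len(truth_genes)}"
            )
        planted = truth.planted_genes
        tp = sum(1 for g in planted if arm_calls[g])
        fn = len(planted) - tp
        fp = sum(1 for g, h in arm_calls.items() if h and g not in planted)
        tn = len(truth_genes) - len(planted) - fp
        out.append(
            {
                "arm": arm,
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
                "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
                "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
            }
        )
    return pd.DataFrame(out)
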