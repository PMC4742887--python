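"""Per-well quantification, robust normalization and assay-window QC.

Wells are summarized by the Myogenin-positive percentage (pooled over
imaged sites) and the mean nuclei count per site. Plate-level statistics
use robust estimators — the median and the median absolute deviation
(MAD) — so a handful of strong knockdown phenotypes cannot distort the
reference scale. Assay quality is reported as the Z'-factor of the
GM-negative vs. DM+I-positive control separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .screen_data import ARMS, ScreenDataset, Well, WellRole

__all__ = [
    "EmptyWellError",
    "DegenerateScaleError",
    "WellSummary",
    "RobustScale",
    "summarize_well",
    "mad",
    "robust_scale",
    "robust_z",
    "z_factor",
    "score_controls",
    "qc_report",
]

#: Scale factor making the MAD a consistent estimator of the standard
#: deviation under normality; applied only inside robust Z-scores.
MAD_NORMAL_CONSISTENCY = 1.4826


class EmptyWellError(ValueError):
    """All sites of a well are empty; the well cannot be summarized."""


class DegenerateScaleError(ValueError):
    """The reference population has zero spread (MAD = 0)."""


@dataclass(frozen=True)
class WellSummary:
    """Quantified readout of one well.

    ``percent_myogenin`` pools counts across sites (weights sites by cell
    content); ``site_fractions`` keeps the per-site fractions, which are the
    sampling unit of the per-well t-test.
    """

    percent_myogenin: float
    site_fractions: tuple[float, ...]
    mean_nuclei: float
    n_sites_recorded: int

    @property
    def n_sites_used(self) -> int:
        return len(self.site_fractions)


def summarize_well(well: Well) -> WellSummary:
    """Compute the pooled Myogenin percentage and mean nuclei of a well.

    Sites with zero total nuclei are excluded from fractions;
    ``mean_nuclei`` averages over all recorded sites. Raises
    :class:`EmptyWellError` when every site is empty.
    """
    totals = np.array([s.total_nuclei for s in well.sites], dtype=float)
    positives = np.array([s.myogenin_pos_nuclei for s in well.sites], dtype=float)
    if totals.size == 0 or totals.sum() == 0:
        raise EmptyWellError(
            f"well {well.plate_id}/{well.well_coordinate} has no nuclei in any site"
        )
    nonempty = totals > 0
    fractions = tuple((positives[nonempty] / totals[nonempty]).tolist())
    return WellSummary(
        percent_myogenin=100.0 * positives.sum() / totals.sum(),
        site_fractions=fractions,
        mean_nuclei=float(totals.mean()),
        n_sites_recorded=int(totals.size),
    )


def mad(values: Iterable[float]) -> float:
    """Raw (unscaled) median absolute deviation from the median."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mad of an empty collection is undefined")
    return float(np.median(np.abs(arr - np.median(arr))))


@dataclass(frozen=True)
class RobustScale:
    """Robust location/scale of a reference population.

    ``scale`` is 1.4826 x MAD, consistent with the standard deviation for
    normal data.
    """

    center: float
    scale: float

    def z(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) / self.scale


def robust_scale(reference: Iterable[float]) -> RobustScale:
    ref = np.asarray(list(reference), dtype=float)
    if ref.size < 2 or np.unique(ref).size < 2:
        raise DegenerateScaleError("reference needs >= 2 distinct values")
    scale = MAD_NORMAL_CONSISTENCY * mad(ref)
    if scale == 0:
        raise DegenerateScaleError("reference MAD is zero; robust Z undefined")
    return RobustScale(center=float(np.median(ref)), scale=float(scale))


def robust_z(values: Iterable[float], reference: Iterable[float]) -> np.ndarray:
    """Robust Z-scores of ``values`` against a reference population.

    z_i = (x_i - median(ref)) / (1.4826 x MAD(ref)). Raises
    :class:`DegenerateScaleError` when the reference MAD is zero.
    """
    return robust_scale(reference).z(list(values))


def z_factor(positive_values: Iterable[float], negative_values: Iterable[float]) -> float:
    """Z'-factor of the assay window between control populations.

    1 - 3(s_pos + s_neg)/|m_pos - m_neg| with sample (n-1) standard
    deviations; 1.0 is a noiseless assay, values above ~0.5 indicate an
    excellent screening window.
    """
    pos = np.asarray(list(positive_values), dtype=float)
    neg = np.asarray(list(negative_values), dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each control group needs >= 2 values")
    window = abs(pos.mean() - neg.mean())
    if window == 0:
        raise ValueError("control group means are equal; assay window undefined")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / window)


def _summaries(wells: Sequence[Well]) -> list[tuple[Well, WellSummary]]:
    out = []
    for w in wells:
        try:
            out.append((w, summarize_well(w)))
        except EmptyWellError:
            continue
    return out


def score_controls(dataset: ScreenDataset, config=None) -> pd.DataFrame:
    """Apply the hit-calling well criteria to the control wells.

    Each DM+I positive-control and GM negative-control well is scored with
    the same per-well positivity rules used for experimental wells (GM wells
    are scored leave-one-out against the remaining GM wells of their plate).
    Returns, per arm, the fraction of positive controls scoring positive and
    the fraction of negative controls scoring positive.
    """
    from .hit_calling import HitCallConfig, score_well  # deferred: avoids cycle

    if config is None:
        config = HitCallConfig()
    rows = []
    for arm in ARMS:
        pos_scored = pos_total = neg_scored = neg_total = 0
        for plate_id in dataset.plate_ids:
            gm = dataset.wells_where(plate_id=plate_id, role=WellRole.GM_NEG_CONTROL, arm=arm)
            dmi = dataset.wells_where(
                plate_id=plate_id, role=WellRole.DM_I_POS_CONTROL, arm=arm
            )
            if not gm:
                continue
            for w in dmi:
                score = score_well(w, gm, config, dmi_reference_wells=dmi)
                pos_total += 1
                pos_scored += int(score.well_positive)
            for w in gm:
                others = [g for g in gm if g is not w]
                if len(others) < 2:
                    continue
                score = score_well(w, others, config, dmi_reference_wells=dmi or None)
                neg_total += 1
                neg_scored += int(score.well_positive)
        if pos_total == 0 and neg_total == 0:
            continue
        rows.append(
            {
                "arm": arm,
                "n_positive_controls": pos_total,
                "positive_control_hit_fraction": pos_scored / pos_total if pos_total else float("nan"),
                "n_negative_controls": neg_total,
                "negative_control_hit_fraction": neg_scored / neg_total if neg_total else float("nan"),
            }
        )
    if not rows:
        raise ValueError("dataset contains no GM / DM+I control wells")
    return pd.DataFrame(rows)


def qc_report(dataset: ScreenDataset, config=None) -> pd.DataFrame:
    """Per (plate, arm) assay-window QC on the percent-Myogenin readout.

    Reports the Z'-factor between DM+I and GM control wells, control medians
    and the number of unsummarizable (all-empty) wells.
    """
    rows = []
    for plate_id in dataset.plate_ids:
        for arm in ARMS:
            gm = _summaries(
                dataset.wells_where(plate_id=plate_id, role=WellRole.GM_NEG_CONTROL, arm=arm)
            )
            dmi = _summaries(
                dataset.wells_where(plate_id=plate_id, role=WellRole.DM_I_POS_CONTROL, arm=arm)
            )
            if not gm and not dmi:
                continue
            gm_pct = [s.percent_myogenin for _, s in gm]
            dmi_pct = [s.percent_myogenin for _, s in dmi]
            try:
                zf = z_factor(dmi_pct, gm_pct)
            except ValueError:
                zf = float("nan")
            n_empty = sum(
                1
                for w in dataset.wells_where(plate_id=plate_id, arm=arm)
                if sum(s.total_nuclei for s in w.sites) == 0
            )
            rows.append(
                {
                    "plate_id": plate_id,
                    "arm": arm,
                    "z_factor_percent_myogenin": zf,
                    "gm_median_percent_myogenin": float(np.median(gm_pct)) if gm_pct else float("nan"),
                    "dmi_median_percent_myogenin": float(np.median(dmi_pct)) if dmi_pct else float("nan"),
                    "gm_median_mean_nuclei": (
                        float(np.median([s.mean_nuclei for _, s in gm])) if gm else float("nan")
                    ),
                    "dmi_median_mean_nuclei": (
                        float(np.median([s.mean_nuclei for _, s in dmi])) if dmi else float("nan")
                    ),
                    "n_unsummarizable_wells": n_empty,
                }
            )
    return pd.DataFrame(rows)
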