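"""Binomial pathway enrichment of hit sets against the screened library.

For each gene set, with N screened library genes of which K belong to the
set, and m hits of which k belong, the enrichment p-value is the upper
binomial tail P(X >= k) for X ~ Binomial(m, K/N) and the fold enrichment is
(k/m)/(K/N) — the percentage of hits in the pathway divided by the expected
percentage. The background is the screened library, not the genome, so
pathway membership is intersected with the library before counting.
P-values are Benjamini-Hochberg adjusted across all tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .screen_data import (
    KinaseLibrary,
    ScreenFormatError,
    ScreenValidationError,
    normalize_symbol,
)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "bh_adjust",
    "binomial_enrichment",
    "enrichment_to_frame",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    source: str
    members: frozenset[str]  # normalized symbols

    def __post_init__(self) -> None:
        if not self.members:
            raise ScreenValidationError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ScreenValidationError(f"duplicate gene-set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    source: str
    k: int  # hits in pathway
    K: int  # library genes in pathway
    m: int  # total hits
    N: int  # library size
    fold_enrichment: float
    p_value: float
    q_value: float


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name<TAB>description<TAB>member...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ScreenFormatError(
                    f"{path}:{lineno}: GMT lines need name, description and >= 1 member"
                )
            members = frozenset(
                normalize_symbol(c) for c in cols[2:] if c.strip()
            )
            if not members:
                raise ScreenFormatError(f"{path}:{lineno}: gene set has no members")
            sets.append(GeneSet(name=cols[0], source=cols[1], members=members))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.source, *sorted(s.members)]) + "\n")


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ScreenValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_enrichment(
    hits: Iterable[str],
    library: KinaseLibrary,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    method: str = "binomial",
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation among the hits.

    Results are sorted by p ascending (ties by name); the full table is
    returned with a one-sided p-value and BH q-value per set — callers
    filter at ``p < alpha`` for reporting. Sets with no screened member
    (K = 0) are skipped. ``method`` selects the binomial model (default)
    or a hypergeometric variant.
    """
    lib_keys = set(library.normalized_symbols)
    hit_keys = {normalize_symbol(h) for h in hits}
    offenders = sorted(hit_keys - lib_keys)
    if offenders:
        raise ScreenValidationError(f"hits not in library: {offenders}")
    if method not in ("binomial", "hypergeometric"):
        raise ValueError(f"unknown method {method!r}")
    N = len(lib_keys)
    m = len(hit_keys)
    rows: list[EnrichmentResult] = []
    for gs in sets:
        screened = gs.members & lib_keys
        K = len(screened)
        if K == 0:
            continue
        k = len(screened & hit_keys)
        p0 = K / N
        if m == 0:
            p = 1.0
            fold = float("nan")
        else:
            if method == "binomial":
                p = float(stats.binom.sf(k - 1, m, p0))
            else:
                p = float(stats.hypergeom.sf(k - 1, N, K, m))
            fold = (k / m) / p0
        rows.append(
            EnrichmentResult(
                pathway=gs.name,
                source=gs.source,
                k=k,
                K=K,
                m=m,
                N=N,
                fold_enrichment=fold,
                p_value=min(p, 1.0),
                q_value=float("nan"),
            )
        )
    if not rows:
        return []
    q = bh_adjust([r.p_value for r in rows])
    rows = [
        EnrichmentResult(
            pathway=r.pathway,
            source=r.source,
            k=r.k,
            K=r.K,
            m=r.m,
            N=r.N,
            fold_enrichment=r.fold_enrichment,
            p_value=r.p_value,
            q_value=float(qi),
        )
        for r, qi in zip(rows, q)
    ]
    rows.sort(key=lambda r: (r.p_value, r.pathway))
    return rows


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "source": r.source,
                "k": r.k,
                "K": r.K,
                "m": r.m,
                "N": r.N,
                "fold_enrichment": r.fold_enrichment,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )
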