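"""Domain types and I/O for high-content siRNA screen readouts.

The screen readout is a table of per-site nuclei counts: each 384-well
plate well is imaged at several sites (fields of view) and, per site, the
total nuclei count and the number of Myogenin-positive nuclei are recorded.
Wells carry a role (negative/positive control, mock, experimental, ...), a
treatment arm (vehicle or CDK4/6-inhibitor sensitizer), a replicate index
and, for experimental wells, the kinase gene targeted by the pooled siRNAs.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

__all__ = [
    "ScreenFormatError",
    "ScreenValidationError",
    "WellRole",
    "ARM_VEHICLE",
    "ARM_SENSITIZER",
    "ARMS",
    "normalize_symbol",
    "SiteMeasurement",
    "Well",
    "KinaseLibrary",
    "ScreenDataset",
    "LayoutDeviation",
    "PAPER_PLATE_LAYOUTS",
    "read_screen_csv",
    "write_screen_csv",
    "read_library_csv",
    "write_library_csv",
    "validate_layout",
]


class ScreenFormatError(ValueError):
    """A file does not conform to the expected screen/library format."""


class ScreenValidationError(ValueError):
    """A record violates a screen-data invariant."""


ARM_VEHICLE = "vehicle"
ARM_SENSITIZER = "sensitizer"
ARMS = (ARM_VEHICLE, ARM_SENSITIZER)

_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows of a 384-well plate
_N_COLS = 24


class WellRole(str, Enum):
    """Role of a well within the plate layout."""

    GM_NEG_CONTROL = "GM_NEG_CONTROL"
    DM_I_POS_CONTROL = "DM_I_POS_CONTROL"
    MOCK = "MOCK"
    UNIVERSAL_CONTROL = "UNIVERSAL_CONTROL"
    KIF11_CONTROL = "KIF11_CONTROL"
    EXPERIMENTAL = "EXPERIMENTAL"


def normalize_symbol(symbol: str) -> str:
    """Canonical form used for all gene-symbol comparisons.

    Symbols are stored exactly as read but compared case-insensitively
    after trimming whitespace (mouse and human sources mix capitalization).
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class SiteMeasurement:
    """Nuclei counts for one imaged site of a well."""

    total_nuclei: int
    myogenin_pos_nuclei: int

    def __post_init__(self) -> None:
        if self.total_nuclei < 0 or self.myogenin_pos_nuclei < 0:
            raise ScreenValidationError(
                f"negative nuclei count: {self.total_nuclei}, {self.myogenin_pos_nuclei}"
            )
        if self.myogenin_pos_nuclei > self.total_nuclei:
            raise ScreenValidationError(
                f"myogenin_pos_nuclei ({self.myogenin_pos_nuclei}) exceeds "
                f"total_nuclei ({self.total_nuclei})"
            )

    @property
    def fraction(self) -> float | None:
        """Myogenin-positive fraction, or None for an empty site."""
        if self.total_nuclei == 0:
            return None
        return self.myogenin_pos_nuclei / self.total_nuclei


def _check_coordinate(coord: str) -> tuple[str, int]:
    coord = coord.strip().upper()
    if len(coord) < 2 or coord[0] not in _ROWS or not coord[1:].isdigit():
        raise ScreenValidationError(f"invalid 384-well coordinate: {coord!r}")
    col = int(coord[1:])
    if not 1 <= col <= _N_COLS:
        raise ScreenValidationError(f"column out of range 1-24: {coord!r}")
    return coord[0], col


@dataclass(frozen=True)
class Well:
    """One well of a physical plate, with its imaged sites.

    ``plate_id`` identifies the physical plate (library plate x arm x
    replicate); ``replicate_index`` runs 1-3.
    """

    plate_id: str
    well_coordinate: str
    role: WellRole
    arm: str
    replicate_index: int
    sites: tuple[SiteMeasurement, ...]
    target_gene: str | None = None

    def __post_init__(self) -> None:
        _check_coordinate(self.well_coordinate)
        if self.arm not in ARMS:
            raise ScreenValidationError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if not 1 <= self.replicate_index <= 3:
            raise ScreenValidationError(f"replicate_index must be 1-3, got {self.replicate_index}")
        if self.role is WellRole.EXPERIMENTAL and not self.target_gene:
            raise ScreenValidationError(
                f"experimental well {self.plate_id}/{self.well_coordinate} lacks a target_gene"
            )
        if (
            self.target_gene
            and self.role not in (WellRole.EXPERIMENTAL, WellRole.KIF11_CONTROL)
        ):
            raise ScreenValidationError(
                f"{self.role.value} well {self.plate_id}/{self.well_coordinate} "
                "must not carry a target_gene"
            )

    @property
    def sort_key(self) -> tuple[str, str, int]:
        row, col = _check_coordinate(self.well_coordinate)
        return (self.plate_id, row, col)

    @property
    def gene_key(self) -> str | None:
        return normalize_symbol(self.target_gene) if self.target_gene else None


@dataclass(frozen=True)
class KinaseLibrary:
    """The siRNA library: an ordered set of target gene symbols."""

    gene_symbols: tuple[str, ...]
    sirna_pool_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        keys = [normalize_symbol(s) for s in self.gene_symbols]
        dupes = [s for s, n in Counter(keys).items() if n > 1]
        if dupes:
            raise ScreenValidationError(f"duplicate library symbols: {sorted(dupes)}")
        if self.sirna_pool_ids is not None and len(self.sirna_pool_ids) != len(self.gene_symbols):
            raise ScreenValidationError("sirna_pool_ids length must match gene_symbols")

    @property
    def size(self) -> int:
        return len(self.gene_symbols)

    @property
    def normalized_symbols(self) -> tuple[str, ...]:
        return tuple(normalize_symbol(s) for s in self.gene_symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in set(self.normalized_symbols)

    def __len__(self) -> int:
        return self.size


@dataclass
class ScreenDataset:
    """A full screen: wells, the library they probe, and provenance."""

    wells: list[Well]
    library: KinaseLibrary
    metadata: dict = field(default_factory=dict)

    # ---- accessors -------------------------------------------------

    def wells_where(
        self,
        *,
        plate_id: str | None = None,
        role: WellRole | None = None,
        arm: str | None = None,
        replicate_index: int | None = None,
        gene: str | None = None,
    ) -> list[Well]:
        gene_key = normalize_symbol(gene) if gene else None
        out = []
        for w in self.wells:
            if plate_id is not None and w.plate_id != plate_id:
                continue
            if role is not None and w.role is not role:
                continue
            if arm is not None and w.arm != arm:
                continue
            if replicate_index is not None and w.replicate_index != replicate_index:
                continue
            if gene_key is not None and w.gene_key != gene_key:
                continue
            out.append(w)
        # canonical order: selections (and the float reductions computed
        # from them) are invariant to the dataset's well ordering
        out.sort(key=lambda w: w.sort_key)
        return out

    @property
    def plate_ids(self) -> list[str]:
        return sorted({w.plate_id for w in self.wells})

    def experimental_genes(self, arm: str | None = None) -> set[str]:
        return {
            w.gene_key
            for w in self.wells
            if w.role is WellRole.EXPERIMENTAL and (arm is None or w.arm == arm)
        }

    def replicate_wells(self) -> dict[tuple[str, str], list[Well]]:
        """Experimental wells grouped by (normalized gene, arm), replicate-sorted."""
        groups: dict[tuple[str, str], list[Well]] = defaultdict(list)
        for w in self.wells:
            if w.role is WellRole.EXPERIMENTAL:
                groups[(w.gene_key, w.arm)].append(w)
        for ws in groups.values():
            ws.sort(key=lambda w: w.replicate_index)
        return dict(groups)

    # ---- validation ------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty means valid)."""
        problems: list[str] = []
        seen: set[tuple[str, str]] = set()
        for w in self.wells:
            key = (w.plate_id, w.well_coordinate)
            if key in seen:
                problems.append(f"duplicate well {key}")
            seen.add(key)
        lib_keys = set(self.library.normalized_symbols)
        for (gene, arm), ws in self.replicate_wells().items():
            if len(ws) != 3:
                problems.append(
                    f"gene {gene} arm {arm}: expected 3 replicate wells, found {len(ws)}"
                )
            if gene not in lib_keys:
                problems.append(f"experimental gene {gene} not in library")
        exp_genes = self.experimental_genes()
        missing = lib_keys - exp_genes
        if self.wells and missing:
            problems.append(f"{len(missing)} library genes have no experimental wells")
        return problems


@dataclass(frozen=True)
class LayoutDeviation:
    plate_id: str
    role: WellRole
    expected: int
    observed: int

    def __str__(self) -> str:  # pragma: no cover - display helper
        return (
            f"plate {self.plate_id}: {self.role.value} expected "
            f"{self.expected}, observed {self.observed}"
        )


#: Per-library-plate role counts of the screen's two 384-well plates.
#: Plate 1 carries 288 experimental wells, plate 2 carries 283; each has
#: 32 GM negative-control and 32 DM+I positive-control wells, the remainder
#: being mock/universal/Kif11 transfection controls (32 vs. 37).
PAPER_PLATE_LAYOUTS: tuple[dict[WellRole, int], ...] = (
    {
        WellRole.GM_NEG_CONTROL: 32,
        WellRole.DM_I_POS_CONTROL: 32,
        WellRole.MOCK: 11,
        WellRole.UNIVERSAL_CONTROL: 11,
        WellRole.KIF11_CONTROL: 10,
        WellRole.EXPERIMENTAL: 288,
    },
    {
        WellRole.GM_NEG_CONTROL: 32,
        WellRole.DM_I_POS_CONTROL: 32,
        WellRole.MOCK: 13,
        WellRole.UNIVERSAL_CONTROL: 12,
        WellRole.KIF11_CONTROL: 12,
        WellRole.EXPERIMENTAL: 283,
    },
)


def validate_layout(
    dataset: ScreenDataset,
    layout_spec: Mapping[str, Mapping[WellRole, int]],
) -> list[LayoutDeviation]:
    """Compare observed per-plate role counts against a declared layout.

    ``layout_spec`` maps plate_id -> {role: expected count}. Every deviation
    is reported; an empty list means the dataset matches the layout exactly.
    """
    deviations: list[LayoutDeviation] = []
    by_plate: dict[str, Counter] = defaultdict(Counter)
    for w in dataset.wells:
        by_plate[w.plate_id][w.role] += 1
    for plate_id, expected_counts in layout_spec.items():
        observed = by_plate.get(plate_id, Counter())
        for role in WellRole:
            exp = expected_counts.get(role, 0)
            obs = observed.get(role, 0)
            if exp != obs:
                deviations.append(LayoutDeviation(plate_id, role, exp, obs))
    for plate_id in set(by_plate) - set(layout_spec):
        for role, obs in sorted(by_plate[plate_id].items(), key=lambda kv: kv[0].value):
            deviations.append(LayoutDeviation(plate_id, role, 0, obs))
    return deviations


# ---- CSV I/O -------------------------------------------------------

CSV_COLUMNS = (
    "plate_id",
    "well",
    "role",
    "target_gene",
    "arm",
    "replicate",
    "site_index",
    "total_nuclei",
    "myogenin_pos_nuclei",
)


def read_screen_csv(path: str | Path, library: KinaseLibrary) -> ScreenDataset:
    """Read a per-site screen CSV into a validated :class:`ScreenDataset`.

    One row per (well, site); row order does not affect the result.
    Raises :class:`ScreenFormatError` for structural problems (missing
    columns, unknown role labels) and :class:`ScreenValidationError` for
    count-invariant violations, citing plate/well/site.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise ScreenFormatError(f"{path}: missing required column(s) {missing}")
        per_well: dict[tuple, list[tuple[int, SiteMeasurement]]] = defaultdict(list)
        for lineno, row in enumerate(reader, start=2):
            try:
                role = WellRole(row["role"].strip())
            except ValueError as exc:
                raise ScreenFormatError(
                    f"{path}:{lineno}: unknown role label {row['role']!r}"
                ) from exc
            gene = row["target_gene"].strip() or None
            try:
                site = SiteMeasurement(
                    total_nuclei=int(row["total_nuclei"]),
                    myogenin_pos_nuclei=int(row["myogenin_pos_nuclei"]),
                )
            except ScreenValidationError as exc:
                raise ScreenValidationError(
                    f"{path}:{lineno}: plate {row['plate_id']} well {row['well']} "
                    f"site {row['site_index']}: {exc}"
                ) from exc
            key = (
                row["plate_id"],
                row["well"].strip().upper(),
                role,
                gene,
                row["arm"].strip(),
                int(row["replicate"]),
            )
            per_well[key].append((int(row["site_index"]), site))
    wells = []
    for (plate_id, coord, role, gene, arm, rep), sites in per_well.items():
        sites.sort(key=lambda t: t[0])
        wells.append(
            Well(
                plate_id=plate_id,
                well_coordinate=coord,
                role=role,
                arm=arm,
                replicate_index=rep,
                sites=tuple(s for _, s in sites),
                target_gene=gene,
            )
        )
    wells.sort(key=lambda w: w.sort_key)
    return ScreenDataset(wells=wells, library=library, metadata={"source_file": str(path)})


def write_screen_csv(dataset: ScreenDataset, path: str | Path) -> None:
    """Write one row per (well, site) with deterministic ordering.

    Rows are ordered by (plate, row letter, column, site index) so repeated
    writes of the same dataset are byte-identical.
    """
    path = Path(path)
    wells = sorted(dataset.wells, key=lambda w: w.sort_key)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for w in wells:
            for i, site in enumerate(w.sites, start=1):
                writer.writerow(
                    [
                        w.plate_id,
                        w.well_coordinate,
                        w.role.value,
                        w.target_gene or "",
                        w.arm,
                        w.replicate_index,
                        i,
                        site.total_nuclei,
                        site.myogenin_pos_nuclei,
                    ]
                )


def read_library_csv(path: str | Path) -> KinaseLibrary:
    """Read a 1-2 column library table (gene_symbol[, sirna_pool_id])."""
    path = Path(path)
    symbols: list[str] = []
    pools: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or not header or header[0].strip().lower() != "gene_symbol":
            raise ScreenFormatError(f"{path}: first column must be 'gene_symbol'")
        has_pool = len(header) > 1 and header[1].strip().lower() == "sirna_pool_id"
        for row in reader:
            if not row or not row[0].strip():
                continue
            symbols.append(row[0].strip())
            if has_pool:
                pools.append(row[1].strip() if len(row) > 1 else "")
    return KinaseLibrary(
        gene_symbols=tuple(symbols),
        sirna_pool_ids=tuple(pools) if pools else None,
    )


def write_library_csv(library: KinaseLibrary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if library.sirna_pool_ids is not None:
            writer.writerow(["gene_symbol", "sirna_pool_id"])
            for s, p in zip(library.gene_symbols, library.sirna_pool_ids):
                writer.writerow([s, p])
        else:
            writer.writerow(["gene_symbol"])
            for s in library.gene_symbols:
                writer.writerow([s])
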