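"""siRNA library manifests and multi-well plate layouts.

A genome-wide arrayed siRNA screen distributes one knockdown condition per
well: either all duplexes targeting a gene pooled into a single well
(primary screen) or each duplex in its own well (deconvolution rounds).
Every plate additionally carries a fixed block of control wells — scrambled
(non-targeting) negative controls, lethal "death" positive controls for
transfection efficiency, antiserum adhesion-block wells, and untreated
cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from string import ascii_uppercase

import pandas as pd

__all__ = [
    "CONTROL_CYCLE",
    "Gene",
    "LibraryManifest",
    "PlateLayout",
    "WellSpec",
    "build_library",
    "layout_plates",
    "layout_to_frame",
    "read_layout_csv",
    "write_layout_csv",
    "plates_needed",
    "sirna_final_concentration",
]

#: Control classes cycled through the control block, in fixed order.
CONTROL_CYCLE = (
    "neg_ctrl_scrambled",
    "pos_ctrl_death",
    "ab_block",
    "untreated",
)

CONTROL_CLASSES = frozenset(CONTROL_CYCLE)
SAMPLE_CLASSES = frozenset({"gene_pool", "gene_single"})

_FORMATS = {96: (8, 12), 384: (16, 24)}


@dataclass(frozen=True)
class Gene:
    """One library entry: a gene and the duplexes targeting it."""

    gene_id: str
    sirna_ids: tuple[str, ...]


@dataclass
class LibraryManifest:
    """An arrayed siRNA library: ``n_genes`` genes x ``d`` duplexes each."""

    genes: list[Gene]
    supplier_tag: str = "supplier-A"

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_duplexes(self) -> int:
        return sum(len(g.sirna_ids) for g in self.genes)

    @property
    def duplexes_per_gene(self) -> int:
        return len(self.genes[0].sirna_ids) if self.genes else 0

    def validate(self) -> None:
        d = self.duplexes_per_gene
        seen: set[str] = set()
        for g in self.genes:
            if len(g.sirna_ids) != d:
                raise ValueError(f"gene {g.gene_id} has {len(g.sirna_ids)} duplexes, expected {d}")
            for s in g.sirna_ids:
                if s in seen:
                    raise ValueError(f"duplicate duplex id {s!r}")
                seen.add(s)


@dataclass(frozen=True)
class WellSpec:
    """Content of one well."""

    content_class: str
    gene_id: str | None = None
    sirna_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.content_class in SAMPLE_CLASSES and self.gene_id is None:
            raise ValueError(f"{self.content_class} well requires a gene_id")
        if self.content_class not in SAMPLE_CLASSES and self.gene_id is not None:
            raise ValueError(f"{self.content_class} well must not carry a gene_id")
        if self.content_class == "gene_single" and len(self.sirna_ids) != 1:
            raise ValueError("gene_single wells carry exactly one duplex")


@dataclass
class PlateLayout:
    """Assignment of well coordinates to :class:`WellSpec` on one plate."""

    plate_id: str
    plate_format: int = 384
    well_map: dict[str, WellSpec] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return _FORMATS[self.plate_format]

    def wells(self, content_class: str | None = None):
        if content_class is None:
            return dict(self.well_map)
        return {w: s for w, s in self.well_map.items() if s.content_class == content_class}

    @property
    def n_sample_wells(self) -> int:
        return sum(1 for s in self.well_map.values() if s.content_class in SAMPLE_CLASSES)

    @property
    def n_control_wells(self) -> int:
        return sum(1 for s in self.well_map.values() if s.content_class in CONTROL_CLASSES)


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate coordinate such as ``'B03'``."""
    return f"{ascii_uppercase[row]}{col + 1:02d}"


def build_library(
    n_genes: int,
    duplexes_per_gene: int = 3,
    *,
    supplier_tag: str = "supplier-A",
    seed: int = 0,
) -> LibraryManifest:
    """Construct a deterministic arrayed siRNA library manifest.

    Gene and duplex identifiers are synthetic but stable for a given
    ``(n_genes, duplexes_per_gene, seed)``; the seed only varies the
    catalog-number suffixes so distinct "suppliers" get distinct duplex ids.
    """
    if n_genes < 0 or duplexes_per_gene < 1:
        raise ValueError("n_genes must be >= 0 and duplexes_per_gene >= 1")
    offset = (seed * 2_654_435_761) % 900_000  # catalog-number offset per supplier
    genes = []
    counter = 0
    for i in range(n_genes):
        gid = f"G{i + 1:05d}"
        sirnas = []
        for j in range(duplexes_per_gene):
            counter += 1
            sirnas.append(f"{gid}_s{j + 1}_{offset + counter:06d}")
        genes.append(Gene(gid, tuple(sirnas)))
    manifest = LibraryManifest(genes, supplier_tag=supplier_tag)
    manifest.validate()
    return manifest


def library_for_genes(
    gene_ids: list[str],
    duplexes_per_gene: int = 5,
    *,
    supplier_tag: str = "supplier-B",
    seed: int = 1,
) -> LibraryManifest:
    """A custom library targeting an explicit gene list with fresh duplex
    ids (e.g. a validation library from a second supplier)."""
    if duplexes_per_gene < 1:
        raise ValueError("duplexes_per_gene must be >= 1")
    offset = (seed * 2_654_435_761) % 900_000
    genes = []
    counter = 0
    for gid in gene_ids:
        sirnas = []
        for j in range(duplexes_per_gene):
            counter += 1
            sirnas.append(f"{gid}_{supplier_tag[:1]}{j + 1}_{offset + counter:06d}")
        genes.append(Gene(gid, tuple(sirnas)))
    manifest = LibraryManifest(genes, supplier_tag=supplier_tag)
    manifest.validate()
    return manifest


def plates_needed(total_wells: int, plate_format: int = 384) -> int:
    """Minimum number of plates addressing ``total_wells`` occupied wells."""
    if plate_format not in _FORMATS:
        raise ValueError(f"plate_format must be one of {sorted(_FORMATS)}")
    if total_wells < 0:
        raise ValueError("total_wells must be >= 0")
    return max(1, math.ceil(total_wells / plate_format))


def sirna_final_concentration(stock_conc: float, transfer_vol: float, final_vol: float) -> float:
    """Concentration after diluting ``transfer_vol`` of stock into ``final_vol``.

    Units are the caller's; the result carries the unit of ``stock_conc``
    provided both volumes share a unit.  E.g. 2.5 uM stock, 100 nL transfer,
    25 uL final -> 10 nM.
    """
    if final_vol <= 0 or transfer_vol <= 0:
        raise ValueError("volumes must be positive")
    return stock_conc * transfer_vol / final_vol


def _control_block(plate_format: int, controls_per_plate: int) -> dict[str, WellSpec]:
    """Fixed control pattern: left-most columns filled column-major,
    control classes alternating down each column."""
    n_rows, n_cols = _FORMATS[plate_format]
    n_ctrl_cols = math.ceil(controls_per_plate / n_rows)
    if n_ctrl_cols >= n_cols:
        raise ValueError("control block would fill the whole plate")
    block: dict[str, WellSpec] = {}
    k = 0
    for col in range(n_ctrl_cols):
        for row in range(n_rows):
            if k >= controls_per_plate:
                break
            block[well_name(row, col)] = WellSpec(CONTROL_CYCLE[k % len(CONTROL_CYCLE)])
            k += 1
    return block


def layout_plates(
    manifest: LibraryManifest,
    *,
    pooled: bool = True,
    controls_per_plate: int = 32,
    plate_format: int = 384,
    plate_prefix: str = "P",
) -> list[PlateLayout]:
    """Array a library onto plates.

    Pooled mode puts all of a gene's duplexes in one well (one well per
    gene); unpooled mode gives each duplex its own well.  Sample wells fill
    the non-control positions row-major in gene order; plates are appended
    until the library is exhausted, so the plate count is
    ``ceil(sample_wells / (plate_format - controls_per_plate))`` (at least
    one plate, controls only, for an empty manifest).
    """
    if plate_format not in _FORMATS:
        raise ValueError(f"plate_format must be one of {sorted(_FORMATS)}")
    if controls_per_plate < 16:
        raise ValueError("controls_per_plate must be >= 16")

    if pooled:
        samples = [WellSpec("gene_pool", g.gene_id, g.sirna_ids) for g in manifest.genes]
    else:
        samples = [
            WellSpec("gene_single", g.gene_id, (s,)) for g in manifest.genes for s in g.sirna_ids
        ]

    n_rows, n_cols = _FORMATS[plate_format]
    block = _control_block(plate_format, controls_per_plate)
    free = [
        well_name(r, c)
        for r in range(n_rows)
        for c in range(n_cols)
        if well_name(r, c) not in block
    ]
    per_plate = len(free)
    n_plates = max(1, math.ceil(len(samples) / per_plate))

    plates = []
    for p in range(n_plates):
        chunk = samples[p * per_plate : (p + 1) * per_plate]
        well_map = dict(block)
        for coord, spec in zip(free, chunk):
            well_map[coord] = spec
        plates.append(PlateLayout(f"{plate_prefix}{p + 1:03d}", plate_format, well_map))
    return plates


def layout_to_frame(plates: list[PlateLayout]) -> pd.DataFrame:
    rows = []
    for plate in plates:
        for coord in sorted(plate.well_map):
            spec = plate.well_map[coord]
            rows.append(
                {
                    "plate_id": plate.plate_id,
                    "well": coord,
                    "content_class": spec.content_class,
                    "gene_id": spec.gene_id if spec.gene_id is not None else "",
                    "sirna_ids": ";".join(spec.sirna_ids),
                }
            )
    return pd.DataFrame(rows, columns=["plate_id", "well", "content_class", "gene_id", "sirna_ids"])


def write_layout_csv(plates: list[PlateLayout], path: str | Path) -> None:
    layout_to_frame(plates).to_csv(path, index=False)


def read_layout_csv(path: str | Path) -> list[PlateLayout]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    plates = []
    for plate_id, grp in df.groupby("plate_id", sort=True):
        beyond_96 = (grp["well"].str[0] > "H") | (grp["well"].str[1:].astype(int) > 12)
        fmt = 384 if beyond_96.any() else 96
        well_map = {}
        for _, row in grp.iterrows():
            sirnas = tuple(s for s in row["sirna_ids"].split(";") if s)
            gene = row["gene_id"] or None
            well_map[row["well"]] = WellSpec(row["content_class"], gene, sirnas)
        plates.append(PlateLayout(str(plate_id), fmt, well_map))
    return plates
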