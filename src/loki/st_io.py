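"""Reading, writing and filtering spot-level spatial transcriptomics data.

The on-disk layout follows the 10x Genomics convention: a Matrix Market
sparse count matrix (``matrix.mtx``) with ``features.tsv`` / ``barcodes.tsv``
sidecars, plus a spot-position table (``positions.csv``) with columns
``barcode, in_tissue, array_row, array_col, x, y``.  The in-memory container
is :class:`SpotMatrix`: a sparse genes-by-spots count matrix aligned with
gene identifiers, spot barcodes and planar spot coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("loki")

__all__ = [
    "SpotMatrix",
    "GeneMap",
    "HousekeepingList",
    "InputError",
    "FormatError",
    "read_spot_matrix",
    "write_spot_matrix",
    "read_gene_map",
    "read_housekeeping_list",
    "map_gene_ids",
    "qc_filter_spots",
    "remove_housekeeping",
]


class InputError(ValueError):
    """Raised when inputs are structurally valid but semantically unusable."""


class FormatError(InputError):
    """Raised when an on-disk artifact is missing or malformed."""


@dataclass
class SpotMatrix:
    """Sparse genes-by-spots counts with coordinates and identifiers.

    Parameters
    ----------
    counts
        Non-negative sparse matrix, genes as rows, spots as columns.
    gene_ids
        One identifier per row, unique.
    barcodes
        One barcode per column, unique.
    coords
        ``(n_spots, 2)`` planar spot positions in the dataset's native
        units (pixels or micrometres); geometry downstream is unit-agnostic.
    spot_diameter
        Optional spot diameter in the same units as ``coords``.
    meta
        Free-form annotations.  ``meta["units"] in {"TPM", "FPKM"}`` marks
        profiles that must pass through normalization unchanged.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]
    coords: np.ndarray
    spot_diameter: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.barcodes = list(self.barcodes)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_spots = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise InputError(
                f"counts has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_spots != len(self.barcodes):
            raise InputError(
                f"counts has {n_spots} columns but {len(self.barcodes)} barcodes"
            )
        if self.coords.shape != (n_spots, 2):
            raise InputError(
                f"coords shape {self.coords.shape} != ({n_spots}, 2)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError("gene ids are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise InputError("barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise InputError("counts contain negative values")
        if self.spot_diameter is not None and self.spot_diameter <= 0:
            raise InputError("spot_diameter must be positive")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, index: np.ndarray) -> "SpotMatrix":
        """Return a copy restricted to the spot columns in ``index`` (order kept)."""
        index = np.asarray(index)
        return replace(
            self,
            counts=sp.csr_matrix(self.counts[:, index]),
            barcodes=[self.barcodes[i] for i in index],
            coords=self.coords[index],
            meta=dict(self.meta),
        )

    def subset_genes(self, index: np.ndarray) -> "SpotMatrix":
        """Return a copy restricted to the gene rows in ``index`` (order kept)."""
        index = np.asarray(index)
        return replace(
            self,
            counts=sp.csr_matrix(self.counts[index]),
            gene_ids=[self.gene_ids[i] for i in index],
            meta=dict(self.meta),
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class GeneMap:
    """Identifier-to-symbol mapping (for example Ensembl ID to HGNC symbol)."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        self.pairs = dict(self.pairs)


@dataclass
class HousekeepingList:
    """A set of housekeeping gene symbols to drop before sentence building."""

    symbols: set[str]

    def __post_init__(self) -> None:
        self.symbols = set(self.symbols)
        if not self.symbols:
            raise InputError("housekeeping list supplied but empty")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "x", "y"]


def read_spot_matrix(path: str | Path, keep_out_of_tissue: bool = False) -> SpotMatrix:
    """Read a 10x-style directory into a :class:`SpotMatrix`.

    Expects ``matrix.mtx``, ``features.tsv``, ``barcodes.tsv`` and
    ``positions.csv`` under ``path``.  Spots absent from the position table
    are dropped (the dropped count is logged); spots flagged out-of-tissue
    (``in_tissue == 0``) are excluded unless ``keep_out_of_tissue``.
    """
    path = Path(path)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv", "positions.csv"):
        if not (path / name).exists():
            raise FormatError(f"missing {name} under {path}")
    counts = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    pos = pd.read_csv(path / "positions.csv")
    missing = [c for c in _POSITION_COLUMNS if c not in pos.columns]
    if missing:
        raise FormatError(f"positions.csv lacks columns {missing}")
    pos = pos.set_index("barcode")
    if not keep_out_of_tissue:
        pos = pos[pos["in_tissue"] != 0]

    keep = [i for i, b in enumerate(barcodes) if b in pos.index]
    if not keep:
        raise InputError("no overlap between matrix barcodes and position table")
    dropped = len(barcodes) - len(keep)
    if dropped:
        logger.warning("dropping %d spot(s) absent from the position table", dropped)
    kept_barcodes = [barcodes[i] for i in keep]
    coords = pos.loc[kept_barcodes, ["x", "y"]].to_numpy(dtype=float)

    meta = {}
    manifest = path / "manifest.json"
    spot_diameter = None
    if manifest.exists():
        info = json.loads(manifest.read_text())
        meta = info.get("meta", {})
        spot_diameter = info.get("spot_diameter")
    return SpotMatrix(
        counts=counts[:, keep],
        gene_ids=genes,
        barcodes=kept_barcodes,
        coords=coords,
        spot_diameter=spot_diameter,
        meta=meta,
    )


def write_spot_matrix(m: SpotMatrix, path: str | Path) -> None:
    """Write ``m`` as matrix.mtx + features/barcodes TSV + positions.csv + manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.counts))
    pd.Series(m.gene_ids).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.barcodes).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame(
        {
            "barcode": m.barcodes,
            "in_tissue": 1,
            "array_row": np.arange(m.n_spots),
            "array_col": np.arange(m.n_spots),
            "x": np.asarray(m.coords[:, 0], dtype=float),
            "y": np.asarray(m.coords[:, 1], dtype=float),
        }
    ).to_csv(path / "positions.csv", index=False, float_format="%.12g")
    (path / "manifest.json").write_text(
        json.dumps(
            {
                "n_genes": m.n_genes,
                "n_spots": m.n_spots,
                "spot_diameter": m.spot_diameter,
                "meta": m.meta,
            },
            indent=2,
        )
    )


def read_gene_map(path: str | Path) -> GeneMap:
    """Read a two-column (identifier, symbol) TSV into a :class:`GeneMap`."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "symbol"])
    if df["id"].duplicated().any():
        raise FormatError("gene map contains duplicate source identifiers")
    return GeneMap(pairs=dict(zip(df["id"], df["symbol"])))


def read_housekeeping_list(path: str | Path) -> HousekeepingList:
    """Read a one-symbol-per-line housekeeping gene list."""
    symbols = {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }
    return HousekeepingList(symbols=symbols)


# ---------------------------------------------------------------------------
# corpus-level filters
# ---------------------------------------------------------------------------


def map_gene_ids(m: SpotMatrix, gm: GeneMap) -> SpotMatrix:
    """Rename gene rows to symbols, dropping unmapped rows.

    Rows whose identifiers map to the same symbol are summed, which conserves
    per-spot library size over the mappable genes.
    """
    mapped = [(i, gm.pairs[g]) for i, g in enumerate(m.gene_ids) if g in gm.pairs]
    if not mapped:
        raise InputError("no gene identifier in the matrix has a mapping")
    symbols: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sym in mapped:
        if sym not in groups:
            groups[sym] = []
            symbols.append(sym)
        groups[sym].append(i)
    rows = []
    for sym in symbols:
        idx = groups[sym]
        row = m.counts[idx[0]]
        for j in idx[1:]:
            row = row + m.counts[j]
        rows.append(sp.csr_matrix(row))
    dropped = m.n_genes - len(mapped)
    if dropped:
        logger.info("map_gene_ids: %d unmapped gene row(s) dropped", dropped)
    return replace(m, counts=sp.vstack(rows, format="csr"), gene_ids=symbols, meta=dict(m.meta))


def qc_filter_spots(m: SpotMatrix, min_genes: int = 200) -> SpotMatrix:
    """Keep spots expressing strictly more than ``min_genes`` genes.

    A gene counts as expressed in a spot when its count is > 0.  Spot order
    is preserved.  The default reproduces the "over 200 expressed genes"
    quality-control rule, read as a strict inequality.
    """
    expressed = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    keep = np.flatnonzero(expressed > min_genes)
    if keep.size == 0:
        raise InputError(
            f"quality control removed every spot (threshold: >{min_genes} expressed genes)"
        )
    if keep.size < m.n_spots:
        logger.info("qc_filter_spots: removed %d spot(s)", m.n_spots - keep.size)
    return m.subset_spots(keep)


def remove_housekeeping(m: SpotMatrix, hk: HousekeepingList) -> SpotMatrix:
    """Drop gene rows whose symbol is in the housekeeping list."""
    keep = np.array([g not in hk.symbols for g in m.gene_ids])
    if keep.all():
        logger.info("remove_housekeeping: no housekeeping gene present, no-op")
        return m.subset_genes(np.arange(m.n_genes))
    return m.subset_genes(np.flatnonzero(keep))
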