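"""Readers and writers for every on-disk artifact.

Count matrices are genes x cells on disk (CellRanger MTX triplet convention:
``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``) with a dense CSV/TSV
alternative. Cell metadata, LR databases and result tables are delimited text
with a header row; the network export is JSON. Gene identity is the symbol
string, case-sensitive, with no alias resolution; duplicated symbols are
suffix-disambiguated with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger(__name__)

REQUIRED_META_COLUMNS = ("cell_id", "sample_id", "patient_id", "timepoint", "cell_type")
OPTIONAL_META_COLUMNS = ("cell_subtype", "clonotype_id")
TIMEPOINTS = ("pre", "post")

#: float format that round-trips IEEE doubles exactly through text
FLOAT_FORMAT = "%.17g"


class FormatError(ValueError):
    """A file does not satisfy the documented on-disk contract."""


def _dedupe_symbols(symbols: Sequence[str]) -> list[str]:
    """Suffix-disambiguate duplicated gene symbols (``SYM``, ``SYM.1``, ...)."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            new = f"{s}.{seen[s]}"
            log.warning("duplicated gene symbol %r renamed to %r", s, new)
            out.append(new)
        else:
            seen[s] = 0
            out.append(s)
    return out


@dataclass
class CellMatrix:
    """Sparse gene-by-cell counts plus per-cell metadata.

    Invariants: counts are non-negative, ``len(gene_ids)`` rows and
    ``len(cell_ids) == len(meta)`` columns, and each (patient_id, timepoint)
    maps to exactly one sample_id.
    """

    counts: sp.csr_matrix  # genes x cells
    gene_ids: list[str]
    cell_ids: list[str]
    meta: pd.DataFrame  # one row per cell, aligned with cell_ids

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts matrix has negative entries")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells or len(self.meta) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} barcodes / {len(self.meta)} metadata rows "
                f"for {n_cells} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell barcodes")
        self.gene_ids = _dedupe_symbols(list(self.gene_ids))
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise FormatError(f"metadata missing required column(s): {missing}")
        bad_tp = set(self.meta["timepoint"].unique()) - set(TIMEPOINTS)
        if bad_tp:
            raise FormatError(f"timepoint values outside {TIMEPOINTS}: {sorted(bad_tp)}")
        if list(self.meta["cell_id"]) != list(self.cell_ids):
            raise FormatError("metadata rows are not aligned with barcodes")
        n_samples = self.meta.groupby(["patient_id", "timepoint"], observed=True)[
            "sample_id"
        ].nunique()
        if (n_samples > 1).any():
            raise FormatError(
                "a (patient_id, timepoint) combination maps to more than one sample_id"
            )
        self.meta = self.meta.reset_index(drop=True)

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, symbol: str) -> int:
        try:
            return self.gene_ids.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not in matrix") from None

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask, dtype=bool)
        return CellMatrix(
            counts=self.counts[:, mask],
            gene_ids=list(self.gene_ids),
            cell_ids=[c for c, m in zip(self.cell_ids, mask) if m],
            meta=self.meta.loc[mask].reset_index(drop=True),
        )

    def equals(self, other: "CellMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and (self.counts != other.counts).nnz == 0
            and self.meta.equals(other.meta)
        )


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor pair; the receptor may be a multi-subunit complex."""

    ligand: str
    receptor: tuple[str, ...]  # ordered subunits
    source: str = ""

    @property
    def receptor_name(self) -> str:
        return "_".join(self.receptor)

    @property
    def key(self) -> tuple[str, tuple[str, ...]]:
        return (self.ligand, self.receptor)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.ligand}->{self.receptor_name}"


def parse_receptor(text: str) -> tuple[str, ...]:
    """Split a receptor field into subunits ('_' separator, '/' accepted)."""
    return tuple(s for s in text.replace("/", "_").split("_") if s)


# ---------------------------------------------------------------------------
# cell matrix I/O
# ---------------------------------------------------------------------------

def _infer_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cell_meta(meta_path: str | Path) -> pd.DataFrame:
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path, sep=_infer_sep(meta_path), dtype=str)
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(
            f"metadata file {meta_path} missing required column(s): {missing}"
        )
    keep = [c for c in (*REQUIRED_META_COLUMNS, *OPTIONAL_META_COLUMNS) if c in meta.columns]
    return meta[keep]


def read_cell_matrix(path: str | Path, meta_path: str | Path) -> CellMatrix:
    """Read counts (MTX triplet directory or dense delimited table) + metadata.

    Cells present in the counts but absent from the metadata are rejected;
    metadata rows without a matching barcode are dropped with a warning.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        barcodes_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise FormatError(f"MTX triplet member missing: {f}")
        counts = sp.csr_matrix(mmread(mtx))
        gene_ids = [l.split("\t")[0] for l in genes_f.read_text().splitlines() if l]
        cell_ids = [l.strip() for l in barcodes_f.read_text().splitlines() if l.strip()]
    else:
        table = pd.read_csv(path, sep=_infer_sep(path), index_col=0)
        counts = sp.csr_matrix(table.to_numpy())
        gene_ids = [str(g) for g in table.index]
        cell_ids = [str(c) for c in table.columns]

    meta = read_cell_meta(meta_path)
    if meta["cell_id"].duplicated().any():
        raise FormatError("duplicate cell_id rows in metadata")
    meta_idx = meta.set_index("cell_id", drop=False)
    unknown = [c for c in cell_ids if c not in meta_idx.index]
    if unknown:
        raise FormatError(
            f"{len(unknown)} cell(s) in counts absent from metadata, "
            f"e.g. {unknown[:3]}"
        )
    extra = len(meta_idx) - len(cell_ids)
    if extra:
        log.warning("dropping %d metadata row(s) without a matching barcode", extra)
    meta = meta_idx.loc[cell_ids].reset_index(drop=True)
    return CellMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, meta=meta)


def write_cell_matrix(cm: CellMatrix, outdir: str | Path) -> None:
    """Write an MTX triplet plus ``meta.tsv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(cm.counts)
    field_kind = "integer" if np.issubdtype(mat.dtype, np.integer) else "real"
    mmwrite(outdir / "matrix.mtx", mat, field=field_kind)
    (outdir / "genes.tsv").write_text("".join(f"{g}\t{g}\n" for g in cm.gene_ids))
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cm.cell_ids))
    write_table(cm.meta, outdir / "meta.tsv")


# ---------------------------------------------------------------------------
# ligand-receptor database
# ---------------------------------------------------------------------------

def read_lr_database(paths: Iterable[str | Path]) -> list[LRPair]:
    """Union of one or more LR tables, deduplicated on (ligand, receptor).

    Each file must carry columns ``ligand``, ``receptor``, ``source``;
    receptor complexes are encoded as subunits joined by '_' ('/' accepted).
    Rows with an empty ligand or receptor are rejected with a logged warning.
    """
    pairs: dict[tuple[str, tuple[str, ...]], LRPair] = {}
    for p in paths:
        p = Path(p)
        df = pd.read_csv(p, sep=_infer_sep(p), dtype=str)
        missing = [c for c in ("ligand", "receptor", "source") if c not in df.columns]
        if missing:
            raise FormatError(f"LR database {p} missing column(s): {missing}")
        n_bad = 0
        for row in df.itertuples(index=False):
            lig = "" if pd.isna(row.ligand) else str(row.ligand).strip()
            rec = parse_receptor("" if pd.isna(row.receptor) else str(row.receptor).strip())
            if not lig or not rec:
                n_bad += 1
                continue
            pair = LRPair(ligand=lig, receptor=rec, source=str(row.source))
            pairs.setdefault(pair.key, pair)
        if n_bad:
            log.warning("%s: rejected %d row(s) with empty ligand/receptor", p, n_bad)
    return list(pairs.values())


def write_lr_database(pairs: Iterable[LRPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.ligand, p.receptor_name, p.source) for p in pairs],
        columns=["ligand", "receptor", "source"],
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated with header; floats serialized so they round-trip exactly."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# network JSON
# ---------------------------------------------------------------------------

def write_network(network, path: str | Path) -> None:
    """Structured JSON export of a CCC network (see :mod:`scivccc.network`)."""
    path = Path(path)
    path.write_text(json.dumps(network.to_dict(), indent=2, sort_keys=True) + "\n")


def read_network(path: str | Path):
    from .network import CCCNetwork

    with open(path) as fh:
        payload = json.load(fh)
    return CCCNetwork.from_dict(payload)
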