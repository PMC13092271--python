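"""Cell QC, pseudo-bulk aggregation, paired differential expression, and
patient-level clonal-expansion classification.

Pseudo-bulk profiles are built per cell type by summing raw counts over the
cells of each sample, scaling to counts-per-million, and applying a
log2(x + 1) transform. "TPM" is implemented as counts-per-million without
gene-length correction: UMI-based droplet data carry no length bias, so
length normalization would be inappropriate. Differential expression is a
paired t-test on per-patient (post - pre) pseudo-bulk values, with
significance defined as p < alpha and |log2 fold-change| > fc_min on raw
p-values (Benjamini-Hochberg is available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .data_io import CellMatrix

log = logging.getLogger(__name__)

#: p-value assigned to degenerate zero-variance, nonzero-mean contrasts
P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class QCParams:
    """Cell-level quality-control thresholds.

    Bounds on detected genes and total UMIs are inclusive (a cell with
    exactly ``min_genes`` detected genes is kept: "fewer than"/"more than"
    are exclusive removals); the mitochondrial filter removes cells with a
    fraction strictly greater than ``max_mito_frac``.
    """

    min_genes: int = 500
    max_genes: int = 5000
    min_umi: int = 400
    max_umi: int = 25000
    max_mito_frac: float = 0.20

    def __post_init__(self) -> None:
        if not (self.min_genes < self.max_genes and self.min_umi < self.max_umi):
            raise ValueError("QC ranges must satisfy min < max")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must lie in [0, 1]")


@dataclass
class PseudoBulkTable:
    """Per-cell-type sample-by-gene matrix on the log2(CPM + 1) scale.

    ``Z`` is the binary treatment indicator per sample (0 = pre, 1 = post).
    """

    values: pd.DataFrame  # samples x genes
    patient_ids: list[str]
    Z: np.ndarray
    cell_type: str

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=int)
        if not set(np.unique(self.Z)) <= {0, 1}:
            raise ValueError("Z must be binary")
        if len(self.values) != len(self.patient_ids) or len(self.values) != len(self.Z):
            raise ValueError("misaligned pseudo-bulk table")
        per = pd.DataFrame({"patient": self.patient_ids, "z": self.Z})
        if (per.groupby(["patient", "z"]).size() > 1).any():
            raise ValueError("a patient contributes more than one row per timepoint")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("pseudo-bulk values must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DEGRecord:
    gene: str
    cell_type: str
    log2fc: float
    t_stat: float
    p_value: float
    n_pairs: int
    significant: bool
    degenerate: bool = False


def qc_filter(matrix: CellMatrix, params: QCParams | None = None,
              mito_prefix: str = "MT-") -> CellMatrix:
    """Remove low-quality cells; logs per-criterion removal counts."""
    params = params or QCParams()
    counts = matrix.counts.tocsc()
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    umi = np.asarray(counts.sum(axis=0)).ravel()
    mito_mask = np.array([g.startswith(mito_prefix) for g in matrix.gene_ids])
    mito_umi = (
        np.asarray(counts[mito_mask].sum(axis=0)).ravel()
        if mito_mask.any()
        else np.zeros_like(umi, dtype=float)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, mito_umi / np.maximum(umi, 1), 0.0)

    ok_genes = (detected >= params.min_genes) & (detected <= params.max_genes)
    ok_umi = (umi >= params.min_umi) & (umi <= params.max_umi)
    ok_mito = mito_frac <= params.max_mito_frac
    keep = ok_genes & ok_umi & ok_mito
    breakdown = {
        "detected_genes": int((~ok_genes).sum()),
        "total_umi": int((~ok_umi).sum()),
        "mito_fraction": int((~ok_mito).sum()),
    }
    log.info(
        "QC: keeping %d/%d cells (removed by criterion: %s)",
        int(keep.sum()), matrix.n_cells, breakdown,
    )
    if not keep.any():
        raise ValueError(f"QC removed every cell; per-criterion removals: {breakdown}")
    return matrix.subset_cells(keep)


def pseudobulk(matrix: CellMatrix, cell_type: str,
               gene_lengths: dict[str, float] | None = None) -> PseudoBulkTable:
    """Sum counts per sample for one cell type, then CPM and log2(x + 1).

    Samples with zero cells of the type are dropped with a warning. UMI data
    need no length correction; passing ``gene_lengths`` (symbol -> length in
    bases) divides summed counts by length before scaling, giving true TPM
    for full-length protocols.
    """
    type_mask = (matrix.meta["cell_type"] == cell_type).to_numpy()
    if not type_mask.any():
        raise ValueError(f"no cells of type {cell_type!r} in the matrix")

    meta = matrix.meta
    sample_info = (
        meta[["sample_id", "patient_id", "timepoint"]]
        .drop_duplicates()
        .sort_values(["patient_id", "timepoint"], ascending=[True, False])
        # 'pre' < 'post' lexically reversed: descending puts pre before post
        .reset_index(drop=True)
    )
    counts = matrix.counts.tocsc()
    rows, samples, patients, z = [], [], [], []
    for rec in sample_info.itertuples(index=False):
        cell_sel = type_mask & (meta["sample_id"] == rec.sample_id).to_numpy()
        if not cell_sel.any():
            log.warning(
                "sample %s has no %s cells; dropped from pseudo-bulk",
                rec.sample_id, cell_type,
            )
            continue
        rows.append(np.asarray(counts[:, cell_sel].sum(axis=1)).ravel())
        samples.append(rec.sample_id)
        patients.append(rec.patient_id)
        z.append(0 if rec.timepoint == "pre" else 1)

    raw = np.vstack(rows).astype(float)
    if gene_lengths is not None:
        missing = [g for g in matrix.gene_ids if g not in gene_lengths]
        if missing:
            raise ValueError(
                f"gene_lengths missing {len(missing)} gene(s), e.g. {missing[:3]}")
        lengths = np.array([gene_lengths[g] for g in matrix.gene_ids], dtype=float)
        if (lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        raw = raw / lengths[None, :]
    totals = raw.sum(axis=1, keepdims=True)
    cpm = np.divide(raw * 1e6, totals, out=np.zeros_like(raw), where=totals > 0)
    values = pd.DataFrame(np.log2(cpm + 1.0), index=samples, columns=matrix.gene_ids)
    return PseudoBulkTable(values=values, patient_ids=patients,
                           Z=np.array(z), cell_type=cell_type)


def _paired_diffs(table: PseudoBulkTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(post - pre) matrix over patients with both timepoints, plus means."""
    df = table.values
    patients = np.array(table.patient_ids)
    pre = {p: i for i, (p, z) in enumerate(zip(patients, table.Z)) if z == 0}
    post = {p: i for i, (p, z) in enumerate(zip(patients, table.Z)) if z == 1}
    complete = sorted(set(pre) & set(post))
    if len(complete) < 2:
        raise ValueError(
            f"paired test needs >=2 patients with both timepoints, got {len(complete)}"
        )
    vals = df.to_numpy()
    pre_m = vals[[pre[p] for p in complete]]
    post_m = vals[[post[p] for p in complete]]
    return post_m, pre_m, complete


def paired_deg(table: PseudoBulkTable, alpha: float = 0.05, fc_min: float = 0.5,
               bh_correction: bool = False) -> list[DEGRecord]:
    """Paired t-test per gene on per-patient (post - pre) pseudo-bulk values.

    Genes with zero counts in every sample are excluded (their statistics are
    undefined). Zero-variance differences with nonzero mean are flagged
    degenerate and assigned the floor p-value rather than dropped.
    """
    post_m, pre_m, complete = _paired_diffs(table)
    genes = np.array(table.genes)
    expressed = (table.values.to_numpy() > 0).any(axis=0)
    n_excluded = int((~expressed).sum())
    if n_excluded:
        log.info("excluding %d gene(s) with zero counts in every sample", n_excluded)

    diffs = post_m[:, expressed] - pre_m[:, expressed]
    n_pairs = diffs.shape[0]
    mean_d = diffs.mean(axis=0)
    sd_d = diffs.std(axis=0, ddof=1)

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance genes warn inside scipy; they are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_rel(post_m[:, expressed], pre_m[:, expressed], axis=0)
        t_stat = np.asarray(t_res.statistic, dtype=float)
        p_val = np.asarray(t_res.pvalue, dtype=float)

    degenerate = sd_d == 0
    zero_mean = degenerate & (mean_d == 0)
    nonzero_mean = degenerate & (mean_d != 0)
    t_stat[zero_mean], p_val[zero_mean] = 0.0, 1.0
    t_stat[nonzero_mean] = np.sign(mean_d[nonzero_mean]) * np.inf
    p_val[nonzero_mean] = P_FLOOR
    if nonzero_mean.any():
        log.warning(
            "%d gene(s) with zero-variance nonzero paired differences; "
            "p set to the smallest representable value",
            int(nonzero_mean.sum()),
        )

    p_for_call = p_val
    if bh_correction:
        p_for_call = stats.false_discovery_control(p_val, method="bh")

    significant = (p_for_call < alpha) & (np.abs(mean_d) > fc_min)
    return [
        DEGRecord(
            gene=g, cell_type=table.cell_type, log2fc=float(fc), t_stat=float(t),
            p_value=float(p), n_pairs=n_pairs, significant=bool(s), degenerate=bool(d),
        )
        for g, fc, t, p, s, d in zip(
            genes[expressed], mean_d, t_stat, p_for_call, significant, degenerate
        )
    ]


def degs_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene, r.cell_type, r.log2fc, r.t_stat, r.p_value, r.n_pairs,
             r.significant, r.degenerate)
            for r in records
        ],
        columns=["gene", "cell_type", "log2fc", "t_stat", "p_value", "n_pairs",
                 "significant", "degenerate"],
    )


def classify_expansion(meta: pd.DataFrame, min_clonotypes: int = 50,
                       min_cells: int = 2) -> dict[str, str]:
    """Patient-level clonal-expansion labels from per-cell clonotype calls.

    A patient is labelled ``E`` (expanded) if the number of clonotypes each
    carried by more than ``min_cells`` cells exceeds ``min_clonotypes``,
    ``NE`` otherwise, and ``unknown`` when no clonotype data are present.
    """
    labels: dict[str, str] = {}
    has_col = "clonotype_id" in meta.columns
    for patient, grp in meta.groupby("patient_id"):
        clono = grp["clonotype_id"].dropna() if has_col else pd.Series(dtype=str)
        clono = clono[clono.astype(str).str.len() > 0]
        if clono.empty:
            labels[str(patient)] = "unknown"
            continue
        n_expanded = int((clono.value_counts() > min_cells).sum())
        labels[str(patient)] = "E" if n_expanded > min_clonotypes else "NE"
    return labels
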