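"""Fisher-z conditional independence testing of IV-passing (X, Y) pairs,
conditioned on ligand-receptor interaction intensity, plus the single-cell
co-expression constraints.

For each candidate LR pair the conditioning variable M is the elementwise
product of the sender pseudo-bulk ligand level and the receiver pseudo-bulk
receptor level (multi-subunit receptors score as the minimum over subunit
levels: limiting-subunit logic, configurable to the geometric mean). The
partial correlation r of X and Y given M is Fisher-transformed,
w = atanh(r), and compared to a normal null with sigma = 1/sqrt(n - |S| - 3)
(the standard Fisher-z CIT convention; a strict flag restores the plain
1/sqrt(n - 3)). Mediation additionally requires the marginal X-Y dependence
to be significant, so that "independence given M" reflects mediation rather
than absent association, and ligand-X / receptor-Y single-cell Pearson
co-expression of at least ``rho_min`` in the sender / receiver cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CellMatrix, LRPair
from .preprocess import PseudoBulkTable

log = logging.getLogger(__name__)

_SATURATION_EPS = 1e-12


@dataclass
class FisherZResult:
    r_partial: float
    w: float
    sigma: float
    z_score: float
    p_value: float
    n: int
    cond_size: int
    saturated: bool = False


@dataclass
class CITResult:
    x_gene: str
    y_gene: str
    sender_type: str
    receiver_type: str
    lr: LRPair
    fisher: FisherZResult
    marginal_p: float
    coexpr_ligand_x: float
    coexpr_receptor_y: float
    mediates: bool


def fisher_from_r(r: float, n: int, cond_size: int,
                  strict_paper_sigma: bool = False) -> FisherZResult:
    """Fisher-z test statistics from a (partial) correlation coefficient."""
    dof = (n - 3) if strict_paper_sigma else (n - cond_size - 3)
    if dof < 1:
        raise ValueError(f"sample size {n} too small for |S| = {cond_size}")
    sigma = 1.0 / np.sqrt(dof)
    if abs(r) >= 1.0 - _SATURATION_EPS:
        return FisherZResult(
            r_partial=float(np.sign(r)), w=float(np.sign(r) * np.inf),
            sigma=float(sigma), z_score=float(np.sign(r) * np.inf), p_value=0.0,
            n=n, cond_size=cond_size, saturated=True,
        )
    w = float(np.arctanh(r))
    z = w / sigma  # null mean mu = 0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return FisherZResult(
        r_partial=float(r), w=w, sigma=float(sigma), z_score=float(z),
        p_value=p, n=n, cond_size=cond_size,
    )


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def fisher_z_test(X, Y, M=None, strict_paper_sigma: bool = False) -> FisherZResult:
    """Test X independent of Y given the conditioning set M.

    ``M`` is a sequence of real vectors (empty or None for a marginal test).
    The partial correlation is computed as the Pearson correlation of the
    residuals of X and Y after OLS on [1, M] — equivalent to the recursive
    partial-correlation formula.
    """
    X = np.asarray(X, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    n = len(X)
    if len(Y) != n:
        raise ValueError("X and Y must have equal length")
    conds = [np.asarray(m, dtype=float).ravel() for m in (M or [])]
    if any(len(m) != n for m in conds):
        raise ValueError("conditioning vectors must match the sample size")
    if n < len(conds) + 4:
        raise ValueError(f"need n >= |S| + 4, got n = {n}, |S| = {len(conds)}")
    for name, v in (("X", X), ("Y", Y), *((f"M[{i}]", m) for i, m in enumerate(conds))):
        if np.std(v) == 0:
            raise ValueError(f"zero-variance input {name}")

    design = np.column_stack([np.ones(n), *conds]) if conds else np.ones((n, 1))
    rx = _residualize(X, design)
    ry = _residualize(Y, design)
    denom = float(np.linalg.norm(rx) * np.linalg.norm(ry))
    if denom == 0:
        # conditioning set explains X or Y exactly
        return fisher_from_r(1.0, n, len(conds), strict_paper_sigma)
    r = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    return fisher_from_r(r, n, len(conds), strict_paper_sigma)


def partial_corr_single(r_xy: float, r_xm: float, r_ym: float) -> float:
    """Recursive partial-correlation formula for one conditioning variable."""
    denom = np.sqrt((1.0 - r_xm ** 2) * (1.0 - r_ym ** 2))
    if denom == 0:
        return 1.0 if abs(r_xy) >= 1 else np.sign(r_xy - r_xm * r_ym) * 1.0
    return float(np.clip((r_xy - r_xm * r_ym) / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# single-cell co-expression
# ---------------------------------------------------------------------------

class CoexpressionCache:
    """Per-cell-type cache of log-normalized single-cell expression.

    Normalization is per-cell log2(CPM + 1) (library-size scaled within each
    cell), pooled over all samples of the given cell type.
    """

    def __init__(self, matrix: CellMatrix, cell_type: str, min_cells: int = 10):
        mask = (matrix.meta["cell_type"] == cell_type).to_numpy()
        if int(mask.sum()) < min_cells:
            raise ValueError(
                f"need >= {min_cells} cells of type {cell_type!r}, got {int(mask.sum())}"
            )
        self.cell_type = cell_type
        self._counts = matrix.counts[:, mask].tocsr()
        totals = np.asarray(self._counts.sum(axis=0)).ravel()
        self._scale = np.divide(1e6, totals, out=np.zeros_like(totals, dtype=float),
                                where=totals > 0)
        self._gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
        self._norm_rows: dict[str, np.ndarray] = {}
        self._corr: dict[tuple[str, str], float] = {}

    def _norm_row(self, gene: str) -> np.ndarray:
        if gene not in self._norm_rows:
            if gene not in self._gene_pos:
                raise KeyError(f"gene {gene!r} not in matrix")
            row = np.asarray(
                self._counts[self._gene_pos[gene]].todense()
            ).ravel()
            self._norm_rows[gene] = np.log2(row * self._scale + 1.0)
        return self._norm_rows[gene]

    def expression(self, genes: tuple[str, ...] | str) -> np.ndarray:
        """Normalized per-cell expression; complexes take the subunit minimum."""
        if isinstance(genes, str):
            return self._norm_row(genes)
        stacked = np.vstack([self._norm_row(g) for g in genes])
        return stacked.min(axis=0)

    def corr(self, genes_a: tuple[str, ...] | str, genes_b: tuple[str, ...] | str) -> float:
        key_a = genes_a if isinstance(genes_a, str) else "_".join(genes_a)
        key_b = genes_b if isinstance(genes_b, str) else "_".join(genes_b)
        key = (key_a, key_b) if key_a <= key_b else (key_b, key_a)
        if key not in self._corr:
            a = self.expression(genes_a)
            b = self.expression(genes_b)
            if np.std(a) == 0 or np.std(b) == 0:
                log.warning(
                    "zero-variance expression for %s or %s in %s cells; "
                    "co-expression set to 0", key_a, key_b, self.cell_type,
                )
                self._corr[key] = 0.0
            else:
                self._corr[key] = float(np.corrcoef(a, b)[0, 1])
        return self._corr[key]


def coexpression(matrix: CellMatrix, gene_a, gene_b, cell_type: str,
                 min_cells: int = 10) -> float:
    """Pearson co-expression of two genes across single cells of one type."""
    cache = CoexpressionCache(matrix, cell_type, min_cells=min_cells)
    return cache.corr(gene_a, gene_b)


# ---------------------------------------------------------------------------
# LR screening
# ---------------------------------------------------------------------------

def lr_conditioning_variable(pb_sender: PseudoBulkTable, pb_receiver: PseudoBulkTable,
                             lr: LRPair, complex_mode: str = "min") -> np.ndarray | None:
    """Per-sample LR interaction intensity M = ligand level x receptor level.

    Returns None (and logs) when the ligand is not measured in the sender
    table or any receptor subunit is missing from the receiver table.
    """
    if lr.ligand not in pb_sender.values.columns:
        log.info("LR %s: ligand not measured in sender pseudo-bulk; skipped", lr)
        return None
    if any(sub not in pb_receiver.values.columns for sub in lr.receptor):
        log.info("LR %s: receptor subunit(s) missing in receiver pseudo-bulk; skipped", lr)
        return None
    lig = pb_sender.values[lr.ligand].to_numpy()
    subs = pb_receiver.values[list(lr.receptor)].to_numpy()
    if complex_mode == "min":
        rec = subs.min(axis=1)
    elif complex_mode == "geometric_mean":
        rec = np.exp(np.log(np.maximum(subs, 1e-12)).mean(axis=1))
    else:
        raise ValueError(f"unknown complex_mode {complex_mode!r}")
    return lig * rec


def screen_lr(iv_pass, lr_db: list[LRPair], pb_sender: PseudoBulkTable,
              pb_receiver: PseudoBulkTable, cells: CellMatrix,
              alpha_cit: float = 0.05, rho_min: float = 0.3,
              strict_paper_sigma: bool = False, complex_mode: str = "min",
              ) -> list[CITResult]:
    """Fisher-z CIT of every IV-passing (X, Y) pair against every LR pair.

    ``mediates`` requires: conditional-independence p > alpha_cit, marginal
    X-Y dependence p < alpha_cit, and both single-cell co-expression
    constraints (ligand-X in sender cells, receptor-Y in receiver cells) at
    ``rho_min``.
    """
    if not lr_db:
        raise ValueError("empty LR database")
    n = len(pb_sender.sample_ids)
    results: list[CITResult] = []
    if not iv_pass:
        return results

    sender_cache = CoexpressionCache(cells, pb_sender.cell_type)
    receiver_cache = CoexpressionCache(cells, pb_receiver.cell_type)

    # precompute conditioning vectors once per LR pair
    m_vectors: list[tuple[LRPair, np.ndarray]] = []
    for lr in lr_db:
        m = lr_conditioning_variable(pb_sender, pb_receiver, lr, complex_mode)
        if m is None:
            continue
        if np.std(m) == 0:
            log.warning("LR %s: zero-variance conditioning variable; skipped", lr)
            continue
        m_vectors.append((lr, m))

    for fit in iv_pass:
        x = pb_sender.values[fit.x_gene].to_numpy()
        y = pb_receiver.values[fit.y_gene].to_numpy()
        marginal = fisher_z_test(x, y, None, strict_paper_sigma=strict_paper_sigma)
        for lr, m in m_vectors:
            fisher = fisher_z_test(x, y, [m], strict_paper_sigma=strict_paper_sigma)
            co_lx = sender_cache.corr(lr.ligand, fit.x_gene)
            co_ry = receiver_cache.corr(lr.receptor, fit.y_gene)
            mediates = bool(
                fisher.p_value > alpha_cit
                and marginal.p_value < alpha_cit
                and co_lx >= rho_min
                and co_ry >= rho_min
            )
            results.append(
                CITResult(
                    x_gene=fit.x_gene, y_gene=fit.y_gene,
                    sender_type=pb_sender.cell_type,
                    receiver_type=pb_receiver.cell_type,
                    lr=lr, fisher=fisher, marginal_p=float(marginal.p_value),
                    coexpr_ligand_x=float(co_lx), coexpr_receptor_y=float(co_ry),
                    mediates=mediates,
                )
            )
    return results


def cit_results_to_frame(results: list[CITResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.x_gene, r.y_gene, r.sender_type, r.receiver_type, r.lr.ligand,
             r.lr.receptor_name, r.fisher.r_partial, r.fisher.w, r.fisher.z_score,
             r.fisher.p_value, r.marginal_p, r.coexpr_ligand_x, r.coexpr_receptor_y,
             r.mediates)
            for r in results
        ],
        columns=["x_gene", "y_gene", "sender_type", "receiver_type", "ligand",
                 "receptor", "r_partial", "w", "z_score", "p_value", "marginal_p",
                 "coexpr_ligand_x", "coexpr_receptor_y", "mediates"],
    )
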