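"""Two-stage least-squares screening of sender/receiver DEG pairs with the
treatment indicator as a single binary instrument.

The direction convention is fixed: X comes from the treatment-targeted
(sender) cell type and Y from a non-targeted (receiver) type; the reverse
direction is never fitted. Both stages include an intercept. Standard errors
follow the 2SLS convention: the residuals entering the error variance use the
original X, not the first-stage fit. A pair is retained when the slope is
significant (p <= alpha_iv) and the exclusion-restriction check fails to
reject (p_exclusion > alpha_excl), i.e. the instrument is uncorrelated with
the residuals of Y given X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import DEGRecord, PseudoBulkTable

log = logging.getLogger(__name__)

#: relative tolerance below which the first stage is declared uninformative
WEAK_INSTRUMENT_TOL = 1e-8


class WeakInstrumentError(RuntimeError):
    """The instrument carries (numerically) no information about X."""


@dataclass
class IVFitResult:
    x_gene: str = ""
    y_gene: str = ""
    sender_type: str = ""
    receiver_type: str = ""
    delta_hat: float = np.nan  # first-stage slope
    beta0: float = np.nan
    beta1: float = np.nan
    se_beta1: float = np.nan
    p_beta1: float = np.nan
    p_exclusion: float = np.nan
    n: int = 0
    passes: bool = False
    exclusion_degenerate: bool = False


def _as_vec(v) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty vector")
    return v


def fit_2sls(Z, X, Y) -> IVFitResult:
    """2SLS fit of Y on X instrumented by binary Z; statistics only.

    First stage: X on [1, Z], giving fitted values X-hat. Second stage: OLS of
    Y on [1, X-hat]. The slope p-value uses a t distribution with n - 2
    degrees of freedom and the 2SLS residual convention (Y - b0 - b1*X).
    """
    Z, X, Y = _as_vec(Z), _as_vec(X), _as_vec(Y)
    n = len(Z)
    if not (len(X) == len(Y) == n):
        raise ValueError("Z, X, Y must have equal length")
    if n < 4:
        raise ValueError(f"need n >= 4 samples, got {n}")
    zc = Z - Z.mean()
    szz = zc @ zc
    if szz == 0:
        raise WeakInstrumentError("instrument is constant")
    szx = zc @ X
    scale = max(1.0, float(np.std(X) * np.std(Z) * n))
    if abs(szx) < WEAK_INSTRUMENT_TOL * scale:
        raise WeakInstrumentError(
            f"first-stage covariance {szx / n:.3e} below tolerance"
        )
    delta = szx / szz
    xhat = X.mean() + delta * zc  # first-stage fit (with intercept)

    hc = xhat - xhat.mean()
    shh = hc @ hc
    beta1 = (hc @ Y) / shh
    beta0 = Y.mean() - beta1 * xhat.mean()

    resid = Y - beta0 - beta1 * X  # original X: the 2SLS error convention
    sigma2 = (resid @ resid) / (n - 2)
    se_beta1 = float(np.sqrt(sigma2 / shh))
    if se_beta1 == 0:
        p_beta1 = 0.0 if beta1 != 0 else 1.0
    else:
        t = beta1 / se_beta1
        p_beta1 = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return IVFitResult(
        delta_hat=float(delta), beta0=float(beta0), beta1=float(beta1),
        se_beta1=se_beta1, p_beta1=p_beta1, n=n,
    )


def exclusion_test(Z, X, Y) -> tuple[float, bool]:
    """Exclusion-restriction check: is Z correlated with residuals of Y | X?

    OLS-regress Y on [1, X], correlate the residuals with Z, and return the
    two-sided p-value of that Pearson correlation (t test, n - 2 df) together
    with a degeneracy flag. A LARGE p supports the exclusion restriction.
    Zero-variance residuals (perfect mediation by X) give p = 1, flagged.
    """
    Z, X, Y = _as_vec(Z), _as_vec(X), _as_vec(Y)
    n = len(Z)
    xc = X - X.mean()
    sxx = xc @ xc
    if sxx == 0:
        resid = Y - Y.mean()
    else:
        b = (xc @ Y) / sxx
        resid = Y - Y.mean() - b * xc
    sr = float(np.sqrt(resid @ resid))
    sz = float(np.sqrt((Z - Z.mean()) @ (Z - Z.mean())))
    if sr <= 1e-12 * max(1.0, float(np.abs(Y).max())) or sz == 0:
        return 1.0, True
    r = float((Z - Z.mean()) @ resid / (sz * sr))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return 0.0, False
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2)), False


def align_tables(pb_sender: PseudoBulkTable, pb_receiver: PseudoBulkTable
                 ) -> tuple[PseudoBulkTable, PseudoBulkTable]:
    """Inner-join two pseudo-bulk tables on sample_id (order from sender)."""
    shared = [s for s in pb_sender.sample_ids if s in set(pb_receiver.sample_ids)]
    dropped = (len(pb_sender.sample_ids) - len(shared)) + (
        len(pb_receiver.sample_ids) - len(shared)
    )
    if dropped:
        log.warning("dropping %d sample row(s) present in only one table", dropped)

    def _subset(tb: PseudoBulkTable) -> PseudoBulkTable:
        pos = [tb.sample_ids.index(s) for s in shared]
        return PseudoBulkTable(
            values=tb.values.iloc[pos],
            patient_ids=[tb.patient_ids[i] for i in pos],
            Z=tb.Z[pos],
            cell_type=tb.cell_type,
        )

    return _subset(pb_sender), _subset(pb_receiver)


def screen_pairs(sender_degs: list[DEGRecord], receiver_degs: list[DEGRecord],
                 pb_sender: PseudoBulkTable, pb_receiver: PseudoBulkTable,
                 alpha_iv: float = 0.05, alpha_excl: float = 0.05,
                 bh_correction: bool = False) -> list[IVFitResult]:
    """Run 2SLS + the exclusion check on every significant (X, Y) DEG pair.

    Returns a result for every pair in the cross product (the ``passes``
    flag marks the retained ones); pairs whose instrument is numerically
    uninformative are skipped with a warning. There is no multiplicity
    correction across the cross product by default (pairs are filtered on
    raw p <= alpha_iv); ``bh_correction`` applies Benjamini-Hochberg to the
    slope p-values for the retention decision, leaving the reported raw
    p-values untouched.
    """
    pb_s, pb_r = align_tables(pb_sender, pb_receiver)
    if len(pb_s.sample_ids) < 4:
        raise ValueError("fewer than 4 aligned samples across the two tables")
    if not np.array_equal(pb_s.Z, pb_r.Z):
        raise ValueError("aligned samples disagree on treatment status")
    Z = pb_s.Z.astype(float)

    x_genes = [d.gene for d in sender_degs if d.significant and d.gene in pb_s.values.columns]
    y_genes = [d.gene for d in receiver_degs if d.significant and d.gene in pb_r.values.columns]
    results: list[IVFitResult] = []
    xs = pb_s.values
    ys = pb_r.values
    for xg in x_genes:
        xv = xs[xg].to_numpy()
        for yg in y_genes:
            yv = ys[yg].to_numpy()
            try:
                res = fit_2sls(Z, xv, yv)
            except WeakInstrumentError as err:
                log.warning("skipping pair (%s, %s): %s", xg, yg, err)
                continue
            res.x_gene, res.y_gene = xg, yg
            res.sender_type, res.receiver_type = pb_s.cell_type, pb_r.cell_type
            res.p_exclusion, res.exclusion_degenerate = exclusion_test(Z, xv, yv)
            results.append(res)

    p_for_call = np.array([r.p_beta1 for r in results])
    if bh_correction and len(results):
        p_for_call = stats.false_discovery_control(p_for_call, method="bh")
    for r, p in zip(results, p_for_call):
        r.passes = bool(p <= alpha_iv and r.p_exclusion > alpha_excl)
    return results


def iv_results_to_frame(results: list[IVFitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.x_gene, r.y_gene, r.sender_type, r.receiver_type, r.delta_hat,
             r.beta1, r.se_beta1, r.p_beta1, r.p_exclusion, r.n, r.passes)
            for r in results
        ],
        columns=["x_gene", "y_gene", "sender_type", "receiver_type", "delta_hat",
                 "beta1", "se_beta1", "p_beta1", "p_exclusion", "n", "passes"],
    )
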