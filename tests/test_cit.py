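"""Fisher-z CIT: transform arithmetic, dual-route partial correlation,
co-expression constraints, and the LR screen."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import scivccc as sv
from scivccc.cit import (CoexpressionCache, fisher_from_r,
                         lr_conditioning_variable, partial_corr_single)


def _orthogonal_pair(n=40, seed=0):
    """Two vectors with sample correlation exactly 0 (up to fp)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    x = x - x.mean()
    y = y - y.mean()
    y = y - (x @ y) / (x @ x) * x  # project out x
    return x, y


class TestFisherZ:
    def test_zero_correlation_gives_p_one(self):
        x, y = _orthogonal_pair()
        res = sv.fisher_z_test(x, y)
        assert res.r_partial == pytest.approx(0.0, abs=1e-12)
        assert res.w == pytest.approx(0.0, abs=1e-12)
        assert res.z_score == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_recursive_formula_worked_example(self):
        # r_xy=0.5, r_xm=0.6, r_ym=0.6: r = (0.5-0.36)/(1-0.36) = 0.21875
        r = partial_corr_single(0.5, 0.6, 0.6)
        assert r == pytest.approx(0.21875, abs=1e-12)
        res = fisher_from_r(r, n=30, cond_size=1)
        # w = 0.5 * ln((1 + 0.21875)/(1 - 0.21875)) = 0.5 * ln(1.56)
        assert res.w == pytest.approx(0.5 * np.log(1.21875 / 0.78125), abs=1e-12)
        assert res.w == pytest.approx(0.22234, abs=1e-5)

    def test_sigma_convention_default_and_strict(self):
        res = fisher_from_r(0.3, n=62, cond_size=1)
        assert res.sigma == pytest.approx(1 / np.sqrt(62 - 1 - 3))
        strict = fisher_from_r(0.3, n=62, cond_size=1, strict_paper_sigma=True)
        assert strict.sigma == pytest.approx(1 / np.sqrt(62 - 3))

    def test_p_from_standard_normal(self):
        from scipy import stats

        res = fisher_from_r(0.4, n=40, cond_size=0)
        assert res.p_value == pytest.approx(
            2 * (1 - stats.norm.cdf(abs(res.z_score))), rel=1e-12)

    def test_symmetry_in_x_and_y(self):
        rng = np.random.default_rng(5)
        x, y, m = rng.standard_normal((3, 30))
        a = sv.fisher_z_test(x, y, [m])
        b = sv.fisher_z_test(y, x, [m])
        assert a.r_partial == b.r_partial
        assert a.p_value == b.p_value

    def test_empty_conditioning_equals_pearson(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x, y = rng.standard_normal((2, 25))
            res = sv.fisher_z_test(x, y)
            assert abs(res.r_partial - np.corrcoef(x, y)[0, 1]) < 1e-12

    def test_residual_route_equals_recursive_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x, y, m = rng.standard_normal((3, 30))
            res = sv.fisher_z_test(x, y, [m])
            r_xy = np.corrcoef(x, y)[0, 1]
            r_xm = np.corrcoef(x, m)[0, 1]
            r_ym = np.corrcoef(y, m)[0, 1]
            assert abs(res.r_partial - partial_corr_single(r_xy, r_xm, r_ym)) < 1e-10

    def test_matches_pingouin_partial_correlation(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        x, y, m = rng.standard_normal((3, 50))
        df = pd.DataFrame({"x": x, "y": y, "m": m})
        ref = pg.partial_corr(df, x="x", y="y", covar="m")
        res = sv.fisher_z_test(x, y, [m])
        assert res.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_saturated_correlation(self):
        x = np.arange(10.0)
        res = sv.fisher_z_test(x, 2 * x + 1)
        assert res.saturated and res.p_value == 0.0

    def test_zero_variance_input_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sv.fisher_z_test(np.ones(10), np.arange(10.0))

    def test_sample_size_guard(self):
        with pytest.raises(ValueError, match="n >= "):
            sv.fisher_z_test(np.arange(4.0), np.arange(4.0) ** 2,
                             [np.random.default_rng(0).standard_normal(4)])


def _sc_matrix(rows: dict[str, np.ndarray], cell_type="T"):
    genes = list(rows)
    counts = np.vstack(list(rows.values()))
    n = counts.shape[1]
    meta = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "sample_id": ["s-pre"] * n, "patient_id": ["p"] * n,
        "timepoint": ["pre"] * n, "cell_type": [cell_type] * n,
    })
    return sv.CellMatrix(counts=sp.csr_matrix(counts), gene_ids=genes,
                         cell_ids=[f"c{i}" for i in range(n)], meta=meta)


class TestCoexpression:
    def test_gene_with_itself_is_one(self):
        rng = np.random.default_rng(0)
        cm = _sc_matrix({"GA": rng.poisson(5, 30), "GB": rng.poisson(5, 30)})
        assert sv.coexpression(cm, "GA", "GA", "T") == pytest.approx(1.0)

    def test_zero_variance_gene_returns_zero(self):
        rng = np.random.default_rng(1)
        cm = _sc_matrix({"GA": np.zeros(30, dtype=int), "GB": rng.poisson(5, 30)})
        assert sv.coexpression(cm, "GA", "GB", "T") == 0.0

    def test_min_cells_guard(self):
        cm = _sc_matrix({"GA": np.arange(5), "GB": np.arange(5)})
        with pytest.raises(ValueError, match="cells"):
            sv.coexpression(cm, "GA", "GB", "T")

    def test_complex_uses_subunit_minimum(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(8, 40)
        b = rng.poisson(8, 40)
        y = rng.poisson(8, 40)
        cm = _sc_matrix({"SU1": a, "SU2": b, "GY": y})
        cache = CoexpressionCache(cm, "T")
        expr = cache.expression(("SU1", "SU2"))
        assert np.all(expr <= cache.expression("SU1") + 1e-12)
        assert np.all(expr <= cache.expression("SU2") + 1e-12)

    def test_planted_ligand_module_coexpression(self, recovery_study):
        """Ligand and its module co-express above 0.3 in sender cells."""
        assert np.median(recovery_study.lig_x_coexpr_ok) >= 0.9


class TestLRConditioning:
    def _pb(self, data: dict[str, np.ndarray], ct):
        n = len(next(iter(data.values())))
        samples = [f"p{i}-{tp}" for i in range(n // 2) for tp in ("pre", "post")]
        return sv.PseudoBulkTable(
            values=pd.DataFrame(data, index=samples),
            patient_ids=[f"p{i}" for i in range(n // 2) for _ in range(2)],
            Z=np.array([0, 1] * (n // 2)), cell_type=ct)

    def test_product_of_ligand_and_receptor(self):
        lig = np.array([1.0, 2, 3, 4])
        rec = np.array([2.0, 2, 2, 2])
        pb_s = self._pb({"L": lig}, "T")
        pb_r = self._pb({"R": rec}, "M")
        m = lr_conditioning_variable(pb_s, pb_r, sv.LRPair("L", ("R",)))
        assert np.allclose(m, lig * rec)

    def test_complex_receptor_subunit_min(self):
        pb_s = self._pb({"L": np.array([1.0, 2, 3, 4])}, "T")
        pb_r = self._pb({"R1": np.array([2.0, 5, 2, 5]),
                         "R2": np.array([3.0, 1, 3, 1])}, "M")
        m = lr_conditioning_variable(pb_s, pb_r, sv.LRPair("L", ("R1", "R2")))
        assert np.allclose(m, np.array([1, 2, 3, 4.0]) * np.array([2, 1, 2, 1.0]))

    def test_unmeasured_gene_skipped(self):
        pb_s = self._pb({"L": np.array([1.0, 2, 3, 4])}, "T")
        pb_r = self._pb({"R": np.array([2.0, 2, 2, 2])}, "M")
        assert lr_conditioning_variable(pb_s, pb_r, sv.LRPair("NOPE", ("R",))) is None
        assert lr_conditioning_variable(pb_s, pb_r, sv.LRPair("L", ("NOPE",))) is None


class TestScreenLR:
    def test_empty_database_raises(self, smoke_sim):
        cm, truth, cfg = smoke_sim
        pb_s = sv.pseudobulk(cm, cfg.sender_type)
        pb_r = sv.pseudobulk(cm, cfg.receiver_types[0])
        fit = sv.IVFitResult(x_gene="GX1_1", y_gene="GY1_1", passes=True)
        with pytest.raises(ValueError, match="empty LR database"):
            sv.screen_lr([fit], [], pb_s, pb_r, cm)

    def test_marginal_independence_blocks_mediation(self, smoke_sim):
        """X-Y pairs with no marginal association are never called mediated."""
        cm, truth, cfg = smoke_sim
        pb_s = sv.pseudobulk(cm, cfg.sender_type)
        pb_r = sv.pseudobulk(cm, cfg.receiver_types[0])
        # background sender gene vs background receiver gene: independent
        fit = sv.IVFitResult(x_gene="BG1", y_gene="BG2", passes=True)
        out = sv.screen_lr([fit], truth.lr_pairs(), pb_s, pb_r, cm)
        marg = [r.marginal_p for r in out]
        assert len(set(marg)) == 1  # one marginal test per (X, Y) pair
        if marg[0] >= 0.05:
            assert not any(r.mediates for r in out)

    def test_planted_channels_mediate(self, recovery_study):
        """Most planted (GEM X, GEM Y) triples are called mediated by their LR."""
        assert np.median(recovery_study.planted_mediation_rate) >= 0.8

    def test_decoy_lr_rarely_mediates(self, recovery_study):
        assert np.mean(recovery_study.decoy_mediation_rate) <= 0.10
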