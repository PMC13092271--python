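"""QC, pseudo-bulk arithmetic, paired differential expression, expansion."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import scivccc as sv
from scivccc.preprocess import P_FLOOR


def _matrix_from_cells(cells: dict[str, np.ndarray], gene_ids, meta=None):
    """cells: cell_id -> count vector (one column per cell)."""
    counts = np.column_stack(list(cells.values()))
    ids = list(cells)
    if meta is None:
        meta = pd.DataFrame({
            "cell_id": ids,
            "sample_id": ["s-pre"] * len(ids),
            "patient_id": ["p"] * len(ids),
            "timepoint": ["pre"] * len(ids),
            "cell_type": ["T"] * len(ids),
        })
    return sv.CellMatrix(counts=sp.csr_matrix(counts), gene_ids=list(gene_ids),
                         cell_ids=ids, meta=meta)


class TestQCFilter:
    def _make(self, n_detected, total_umi, mito_frac, n_genes=700):
        """One cell column with the requested QC statistics."""
        v = np.zeros(n_genes, dtype=int)
        mito_umi = int(round(total_umi * mito_frac))
        body = total_umi - mito_umi
        # gene 0 is mitochondrial; fill n_detected-1 body genes
        v[0] = mito_umi
        k = n_detected - (1 if mito_umi > 0 else 0)
        v[1:1 + k] = 1
        v[1] += body - k
        return v

    def test_paper_boundaries(self):
        genes = ["MT-1"] + [f"G{i}" for i in range(699)]
        cells = {
            "ok": self._make(600, 1000, 0.10),
            "few_genes": self._make(499, 1000, 0.10),
            "boundary_genes": self._make(500, 1000, 0.10),
            "high_mito": self._make(600, 1000, 0.21),
            "boundary_mito": self._make(600, 1000, 0.20),
            "high_umi": self._make(600, 25001, 0.0),
            "boundary_umi": self._make(600, 25000, 0.0),
        }
        cm = _matrix_from_cells(cells, genes)
        kept = sv.qc_filter(cm, sv.QCParams(), mito_prefix="MT-")
        assert set(kept.cell_ids) == {"ok", "boundary_genes", "boundary_mito",
                                      "boundary_umi"}

    def test_hand_built_fixture_exact_retained_set(self):
        # 10 cells with hand-computed (detected, umi, mito%) against
        # thresholds (genes in [3, 6], umi in [10, 100], mito <= 0.2)
        genes = ["MT-A", "GA", "GB", "GC", "GD", "GE", "GF"]
        cases = {
            "c1": ([0, 5, 5, 5, 0, 0, 0], True),    # 3 genes, 15 umi, 0% mito
            "c2": ([0, 5, 5, 0, 0, 0, 0], False),   # 2 genes: too few
            "c3": ([2, 4, 2, 2, 0, 0, 0], True),    # mito 20% exactly: kept
            "c4": ([3, 4, 2, 2, 0, 0, 0], False),   # mito 27%: removed
            "c5": ([0, 3, 3, 3, 0, 0, 0], False),   # 9 umi: too few
            "c6": ([0, 4, 3, 3, 0, 0, 0], True),    # 10 umi boundary: kept
            "c7": ([0, 50, 30, 20, 0, 0, 0], True), # 100 umi boundary: kept
            "c8": ([0, 51, 30, 20, 0, 0, 0], False),# 101 umi: removed
            "c9": ([1, 2, 2, 2, 2, 2, 2], False),   # 7 genes: too many
            "c10": ([0, 2, 2, 2, 2, 2, 0], True),   # 6 genes boundary
        }
        cm = _matrix_from_cells({k: np.array(v) for k, (v, _) in cases.items()}, genes)
        params = sv.QCParams(min_genes=3, max_genes=6, min_umi=10, max_umi=100,
                             max_mito_frac=0.2)
        kept = sv.qc_filter(cm, params, mito_prefix="MT-")
        assert set(kept.cell_ids) == {k for k, (_, keep) in cases.items() if keep}

    def test_all_cells_removed_reports_breakdown(self):
        genes = [f"G{i}" for i in range(5)]
        cm = _matrix_from_cells({"c1": np.array([1, 0, 0, 0, 0])}, genes)
        with pytest.raises(ValueError, match="criterion"):
            sv.qc_filter(cm, sv.QCParams(min_genes=3, max_genes=5,
                                         min_umi=10, max_umi=100))


class TestPseudobulk:
    def test_cpm_log2_hand_arithmetic(self):
        cm = _matrix_from_cells({"c1": np.array([1, 3])}, ["GA", "GB"])
        tb = sv.pseudobulk(cm, "T")
        expected = [np.log2(250_000 + 1), np.log2(750_000 + 1)]
        assert np.allclose(tb.values.to_numpy().ravel(), expected, rtol=1e-12)

    def test_all_zero_sample_gives_zero_row(self):
        cm = _matrix_from_cells({"c1": np.array([0, 0])}, ["GA", "GB"])
        tb = sv.pseudobulk(cm, "T")
        assert np.array_equal(tb.values.to_numpy().ravel(), [0.0, 0.0])

    def test_counts_summed_before_scaling(self):
        one = _matrix_from_cells({"c1": np.array([1, 1])}, ["GA", "GB"])
        two = _matrix_from_cells(
            {"c1": np.array([1, 0]), "c2": np.array([0, 1])}, ["GA", "GB"])
        assert np.allclose(sv.pseudobulk(one, "T").values.to_numpy(),
                           sv.pseudobulk(two, "T").values.to_numpy())

    def test_absent_cell_type_errors(self):
        cm = _matrix_from_cells({"c1": np.array([1, 1])}, ["GA", "GB"])
        with pytest.raises(ValueError, match="no cells of type"):
            sv.pseudobulk(cm, "B")

    def test_gene_length_correction(self):
        # counts [2, 2] with lengths [1000, 500]: length-corrected abundances
        # 0.002 and 0.004 scale to TPM [1e6/3, 2e6/3]
        cm = _matrix_from_cells({"c1": np.array([2, 2])}, ["GA", "GB"])
        tb = sv.pseudobulk(cm, "T", gene_lengths={"GA": 1000.0, "GB": 500.0})
        expected = [np.log2(1e6 / 3 + 1), np.log2(2e6 / 3 + 1)]
        assert np.allclose(tb.values.to_numpy().ravel(), expected, rtol=1e-12)

    def test_gene_length_missing_symbol_errors(self):
        cm = _matrix_from_cells({"c1": np.array([2, 2])}, ["GA", "GB"])
        with pytest.raises(ValueError, match="gene_lengths missing"):
            sv.pseudobulk(cm, "T", gene_lengths={"GA": 1000.0})


def _pb_table(values_pre: np.ndarray, values_post: np.ndarray, genes=None):
    """PseudoBulkTable from per-patient pre/post matrices (patients x genes)."""
    n, g = values_pre.shape
    genes = genes or [f"G{i}" for i in range(g)]
    rows = np.vstack([values_pre, values_post])
    samples = [f"p{i}-pre" for i in range(n)] + [f"p{i}-post" for i in range(n)]
    return sv.PseudoBulkTable(
        values=pd.DataFrame(rows, index=samples, columns=genes),
        patient_ids=[f"p{i}" for i in range(n)] * 2,
        Z=np.array([0] * n + [1] * n),
        cell_type="T",
    )


class TestPairedDEG:
    def test_identical_pre_post_not_significant(self):
        vals = np.abs(np.random.default_rng(0).standard_normal((4, 3))) + 1
        recs = sv.paired_deg(_pb_table(vals, vals))
        assert all(r.log2fc == 0 and not r.significant for r in recs)

    def test_textbook_t_statistic(self):
        # per-patient differences [1, 2, 3]: t = 2 / (1/sqrt(3)) = 3.4641
        pre = np.array([[1.0], [1.0], [1.0]])
        post = pre + np.array([[1.0], [2.0], [3.0]])
        (rec,) = sv.paired_deg(_pb_table(pre, post))
        assert rec.t_stat == pytest.approx(3.4641, abs=1e-4)
        assert rec.p_value == pytest.approx(2 * stats.t.sf(3.4641016, df=2), abs=1e-6)
        assert rec.p_value == pytest.approx(0.0742, abs=2e-4)
        assert rec.log2fc == pytest.approx(2.0)
        assert rec.n_pairs == 3

    def test_zero_variance_nonzero_differences_flagged(self):
        pre = np.ones((3, 1))
        post = pre + 1.0
        (rec,) = sv.paired_deg(_pb_table(pre, post))
        assert rec.degenerate
        assert rec.p_value == P_FLOOR
        assert rec.significant  # |lfc| = 1 > 0.5 and p below any alpha

    def test_all_zero_gene_excluded(self):
        pre = np.column_stack([np.ones(3), np.zeros(3)])
        post = np.column_stack([np.ones(3) * 2, np.zeros(3)])
        recs = sv.paired_deg(_pb_table(pre, post))
        assert [r.gene for r in recs] == ["G0"]

    def test_requires_two_complete_pairs(self):
        tb = _pb_table(np.ones((1, 2)), np.ones((1, 2)) * 2)
        with pytest.raises(ValueError, match=">=2 patients"):
            sv.paired_deg(tb)

    def test_invariant_to_patient_and_gene_order(self):
        rng = np.random.default_rng(1)
        pre = rng.random((5, 4)) + 1
        post = pre + rng.standard_normal((5, 4)) * 0.3
        base = sv.paired_deg(_pb_table(pre, post))
        perm_p = [3, 1, 4, 0, 2]
        perm_g = [2, 0, 3, 1]
        tb = _pb_table(pre[perm_p][:, perm_g], post[perm_p][:, perm_g],
                       genes=[f"G{i}" for i in perm_g])
        # patient relabeling must follow the permutation for a paired design
        tb.patient_ids = [f"p{perm_p[i]}" for i in range(5)] * 2
        shuffled = {r.gene: r for r in sv.paired_deg(tb)}
        for r in base:
            assert shuffled[r.gene].p_value == pytest.approx(r.p_value, rel=1e-12)
            assert shuffled[r.gene].log2fc == pytest.approx(r.log2fc, rel=1e-12)

    def test_label_swap_flips_log2fc_keeps_p(self):
        rng = np.random.default_rng(2)
        pre = rng.random((5, 3)) + 1
        post = pre + rng.standard_normal((5, 3)) * 0.5 + 0.4
        fwd = sv.paired_deg(_pb_table(pre, post))
        rev = sv.paired_deg(_pb_table(post, pre))
        for a, b in zip(fwd, rev):
            assert b.log2fc == pytest.approx(-a.log2fc, rel=1e-12)
            assert b.p_value == pytest.approx(a.p_value, rel=1e-12)


class TestClassifyExpansion:
    def _meta(self, clono_counts: dict[str, int], patient="p1"):
        rows = []
        i = 0
        for clono, n in clono_counts.items():
            for _ in range(n):
                rows.append((f"c{i}", f"{patient}-pre", patient, "pre", "T", clono))
                i += 1
        return pd.DataFrame(rows, columns=["cell_id", "sample_id", "patient_id",
                                           "timepoint", "cell_type", "clonotype_id"])

    def test_51_expanded_clonotypes_is_expanded(self):
        meta = self._meta({f"cl{i}": 3 for i in range(51)})
        assert sv.classify_expansion(meta) == {"p1": "E"}

    def test_50_expanded_clonotypes_is_not(self):
        meta = self._meta({f"cl{i}": 3 for i in range(50)})
        assert sv.classify_expansion(meta) == {"p1": "NE"}

    def test_clonotypes_with_two_cells_do_not_count(self):
        meta = self._meta({f"cl{i}": 2 for i in range(80)})
        assert sv.classify_expansion(meta) == {"p1": "NE"}

    def test_missing_clonotype_data_is_unknown(self):
        meta = self._meta({f"cl{i}": 3 for i in range(51)})
        meta["clonotype_id"] = None
        assert sv.classify_expansion(meta) == {"p1": "unknown"}
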