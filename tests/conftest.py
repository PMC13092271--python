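"""Shared fixtures: tiny hand-built matrices and the full-scale recovery study.

The 20-seed full-scale study is expensive, so it runs once per session and
every test that needs planted-channel statistics consumes the summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import scivccc as sv


@pytest.fixture()
def tiny_matrix() -> sv.CellMatrix:
    """3 genes x 4 cells, 2 patients x pre/post, known counts."""
    counts = np.array(
        [
            [1, 0, 3, 2],
            [0, 2, 1, 0],
            [5, 1, 0, 4],
        ]
    )
    meta = pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3", "c4"],
            "sample_id": ["p1-pre", "p1-post", "p2-pre", "p2-post"],
            "patient_id": ["p1", "p1", "p2", "p2"],
            "timepoint": ["pre", "post", "pre", "post"],
            "cell_type": ["T", "T", "T", "T"],
        }
    )
    return sv.CellMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=["GA", "GB", "MT-CO1"],
        cell_ids=["c1", "c2", "c3", "c4"],
        meta=meta,
    )


@pytest.fixture(scope="session")
def smoke_sim() -> tuple[sv.CellMatrix, sv.GroundTruth, sv.SimConfig]:
    cfg = sv.default_config("smoke", seed=7)
    cm, truth = sv.simulate(cfg)
    return cm, truth, cfg


@dataclass
class RecoveryStudy:
    """Per-seed summaries of the full-scale planted-channel study."""

    seeds: list[int]
    n_recovered: list[int]
    n_false: list[int]
    decoy_mediation_rate: list[float]
    conf_iv_pass_rate: list[float]
    planted_iv_pass_rate: list[float]
    planted_mediation_rate: list[float]  # per-channel fraction, pooled per seed
    lig_x_coexpr_ok: list[float]  # fraction of planted ligand-GEM X pairs >= 0.3
    n_channels_total: int
    example_result: sv.StudyResult  # first seed, for round-trip/inspection tests
    example_truth: sv.GroundTruth
    example_config: sv.SimConfig


def _run_recovery_study(seeds: list[int]) -> RecoveryStudy:
    out = RecoveryStudy(
        seeds=seeds, n_recovered=[], n_false=[], decoy_mediation_rate=[],
        conf_iv_pass_rate=[], planted_iv_pass_rate=[], planted_mediation_rate=[],
        lig_x_coexpr_ok=[], n_channels_total=0, example_result=None,
        example_truth=None, example_config=None,
    )
    for seed in seeds:
        cfg = sv.default_config("full", seed=seed)
        cm, truth = sv.simulate(cfg)
        res = sv.run_study(cm, truth.lr_pairs(), cfg.sender_type,
                           list(cfg.receiver_types), skip_qc=True)
        got = set(res.network.channel_keys())
        want = {c.key for c in truth.channels}
        out.n_recovered.append(len(got & want))
        out.n_false.append(len(got - want))
        out.n_channels_total = len(want)

        decoy_ligs = {p.ligand for p in truth.decoy_lr}
        decoy = [r for r in res.cit_results if r.lr.ligand in decoy_ligs]
        out.decoy_mediation_rate.append(
            float(np.mean([r.mediates for r in decoy])) if decoy else 0.0)

        conf = set(truth.confounded_pairs)
        cf = [r for r in res.iv_results if (r.x_gene, r.y_gene) in conf]
        out.conf_iv_pass_rate.append(
            float(np.mean([r.passes for r in cf])) if cf else 0.0)

        planted_pairs = {
            (x, y) for ch in truth.channels for x in ch.gem_x for y in ch.gem_y
        }
        pl = [r for r in res.iv_results if (r.x_gene, r.y_gene) in planted_pairs]
        out.planted_iv_pass_rate.append(
            float(np.mean([r.passes for r in pl])) if pl else 0.0)

        med_rates = []
        for ch in truth.channels:
            trips = [
                r for r in res.cit_results
                if r.lr.ligand == ch.ligand
                and (r.x_gene, r.y_gene) in {(x, y) for x in ch.gem_x for y in ch.gem_y}
            ]
            if trips:
                med_rates.append(float(np.mean([r.mediates for r in trips])))
        out.planted_mediation_rate.append(
            float(np.mean(med_rates)) if med_rates else 0.0)

        from scivccc.cit import CoexpressionCache

        cache = CoexpressionCache(cm, cfg.sender_type)
        co = [
            cache.corr(ch.ligand, g) >= 0.3
            for ch in truth.channels for g in ch.gem_x
        ]
        out.lig_x_coexpr_ok.append(float(np.mean(co)))

        if out.example_result is None:
            out.example_result = res
            out.example_truth = truth
            out.example_config = cfg
    return out


@pytest.fixture(scope="session")
def recovery_study() -> RecoveryStudy:
    """Full-scale study: 31 patients, 5 channels, 50 decoy LR, 20 seeds."""
    return _run_recovery_study(list(range(1, 21)))
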