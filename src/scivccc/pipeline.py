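"""End-to-end orchestration: QC -> pseudo-bulk -> paired DEGs -> IV screen ->
LR conditional-independence screen -> GEM filter/grouping -> CCC network.

``run_study`` is the in-memory engine (CellMatrix + LR list in, network and
every intermediate out); ``run_all`` wraps it with file I/O, a YAML config,
and a run manifest. Outputs are deterministic: identical inputs and config
produce byte-identical files (the manifest carries a config hash and stage
counts, no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import cit as cit_mod
from . import iv as iv_mod
from . import network as net_mod
from . import preprocess as pp
from .data_io import (CellMatrix, LRPair, read_cell_matrix, read_lr_database,
                      write_network, write_table)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisParams:
    """Every screening threshold and mode flag, in pipeline order."""

    alpha_deg: float = 0.05
    fc_min: float = 0.5
    alpha_iv: float = 0.05
    alpha_excl: float = 0.05
    alpha_cit: float = 0.05
    rho_min: float = 0.3   # single-cell co-expression requirement
    rho_max: float = 0.3   # anti-direct-co-expression ceiling
    strict_paper_sigma: bool = False
    gem_filter_mode: str = "residual"  # or "literal"
    bh_correction: bool = False
    complex_mode: str = "min"
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        for name in ("alpha_deg", "alpha_iv", "alpha_excl", "alpha_cit"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class PipelineConfig:
    counts: str
    meta: str
    lr_db: list[str]
    outdir: str
    sender_cell_type: str
    receiver_cell_types: list[str]
    params: AnalysisParams = field(default_factory=AnalysisParams)
    qc: pp.QCParams = field(default_factory=pp.QCParams)
    skip_qc: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["params"] = AnalysisParams(**raw.get("params", {}))
        raw["qc"] = pp.QCParams(**raw.get("qc", {}))
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StudyResult:
    matrix: CellMatrix
    pseudobulk: dict[str, pp.PseudoBulkTable]
    degs: dict[str, list[pp.DEGRecord]]
    iv_results: list[iv_mod.IVFitResult]
    cit_results: list[cit_mod.CITResult]
    filtered_triples: list[cit_mod.CITResult]
    gem_pairs: list[net_mod.GemPair]
    network: net_mod.CCCNetwork
    stage_counts: dict[str, int]


def run_study(matrix: CellMatrix, lr_pairs: list[LRPair],
              sender_cell_type: str, receiver_cell_types: list[str],
              params: AnalysisParams | None = None,
              qc: pp.QCParams | None = None, skip_qc: bool = False) -> StudyResult:
    """Run every stage on in-memory inputs; raises StageError on failure."""
    params = params or AnalysisParams()

    def stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as err:  # noqa: BLE001 - reported with stage name
            raise StageError(name, err) from err

    if skip_qc:
        cells = matrix
    else:
        cells = stage("qc", lambda: pp.qc_filter(matrix, qc, params.mito_prefix))

    cell_types = [sender_cell_type, *receiver_cell_types]
    pb = {
        ct: stage("pseudobulk", lambda ct=ct: pp.pseudobulk(cells, ct))
        for ct in cell_types
    }
    degs = {
        ct: stage("paired_deg", lambda ct=ct: pp.paired_deg(
            pb[ct], alpha=params.alpha_deg, fc_min=params.fc_min,
            bh_correction=params.bh_correction))
        for ct in cell_types
    }

    iv_results: list[iv_mod.IVFitResult] = []
    cit_results: list[cit_mod.CITResult] = []
    n_deg_pairs = 0
    for receiver in receiver_cell_types:
        pb_s, pb_r = iv_mod.align_tables(pb[sender_cell_type], pb[receiver])
        n_deg_pairs += (
            sum(d.significant for d in degs[sender_cell_type])
            * sum(d.significant for d in degs[receiver])
        )
        fits = stage("iv_screen", lambda: iv_mod.screen_pairs(
            degs[sender_cell_type], degs[receiver], pb_s, pb_r,
            alpha_iv=params.alpha_iv, alpha_excl=params.alpha_excl,
            bh_correction=params.bh_correction))
        iv_results.extend(fits)
        passing = [f for f in fits if f.passes]
        if passing:
            cit_results.extend(stage("lr_cit", lambda: cit_mod.screen_lr(
                passing, lr_pairs, pb_s, pb_r, cells,
                alpha_cit=params.alpha_cit, rho_min=params.rho_min,
                strict_paper_sigma=params.strict_paper_sigma,
                complex_mode=params.complex_mode)))

    mediating = [r for r in cit_results if r.mediates]
    filtered: list[cit_mod.CITResult] = []
    for receiver in receiver_cell_types:
        sub = [r for r in mediating if r.receiver_type == receiver]
        if not sub:
            continue
        pb_s, pb_r = iv_mod.align_tables(pb[sender_cell_type], pb[receiver])
        filtered.extend(stage("gem_filter", lambda: net_mod.filter_direct_coexpression(
            sub, pb_s, pb_r, rho_max=params.rho_max,
            mode=params.gem_filter_mode, complex_mode=params.complex_mode)))

    gem_pairs = stage("group_gems", lambda: net_mod.group_gems(filtered))
    network = stage("build_network", lambda: net_mod.build_network(gem_pairs))

    stage_counts = {
        "cells_after_qc": cells.n_cells,
        "deg_pairs": n_deg_pairs,
        "iv_pairs_tested": len(iv_results),
        "iv_pairs_passing": sum(r.passes for r in iv_results),
        "cit_triples_tested": len(cit_results),
        "mediating_pairs": len({(r.x_gene, r.y_gene) for r in mediating}),
        "filtered_triples": len(filtered),
        "channels": len(network.channels),
    }
    for ct in cell_types:
        stage_counts[f"degs_{ct}"] = sum(d.significant for d in degs[ct])
    log.info("pipeline stage counts: %s", stage_counts)
    return StudyResult(
        matrix=cells, pseudobulk=pb, degs=degs, iv_results=iv_results,
        cit_results=cit_results, filtered_triples=filtered,
        gem_pairs=gem_pairs, network=network, stage_counts=stage_counts,
    )


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_all(config: PipelineConfig) -> StudyResult:
    """File-based pipeline run: read inputs, run all stages, write artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = read_cell_matrix(config.counts, config.meta)
    lr_pairs = read_lr_database(config.lr_db)

    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "scivccc_version": _version(),
    }
    try:
        result = run_study(
            matrix, lr_pairs, config.sender_cell_type,
            config.receiver_cell_types, params=config.params, qc=config.qc,
            skip_qc=config.skip_qc,
        )
    except StageError as err:
        manifest["failed_stage"] = err.stage
        manifest["error"] = str(err.cause)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise

    for ct, recs in result.degs.items():
        write_table(pp.degs_to_frame(recs), outdir / f"deg_{ct}.tsv")
    write_table(iv_mod.iv_results_to_frame(result.iv_results), outdir / "iv_pairs.tsv")
    write_table(cit_mod.cit_results_to_frame(result.cit_results),
                outdir / "cit_results.tsv")
    write_table(net_mod.gems_to_frame(result.gem_pairs), outdir / "gems.tsv")
    write_network(result.network, outdir / "network.json")
    manifest["stage_counts"] = result.stage_counts
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return result


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("scivccc")
    except Exception:  # pragma: no cover - editable-install edge
        return "unknown"
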