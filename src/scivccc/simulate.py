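"""Synthetic paired pre/post-treatment single-cell data with planted
cell-cell communication channels and a ground-truth manifest.

The generator emulates the causal chain the pipeline is designed to detect:
treatment z directly activates a latent pathway in the sender cell type
(A = a1*z + u + noise, with u a patient-level confounder shared by both
timepoints and both cell types), pathway activity drives a module of sender
genes (GEM X) and a secreted ligand, the population ligand level multiplied
by the receiver's receptor level forms the transmitted signal, and the
signal drives a receiver pathway whose targets (GEM Y) respond. Alongside
the planted channels it plants (i) confounded decoy gene pairs - a sender
gene and a receiver gene that both respond to treatment directly and share
the patient confounder, with no ligand path between them, so the
exclusion-restriction check should reject them - and (ii) decoy LR pairs
that are expressed but causally inert. Background genes are i.i.d. noise.

Gene expression is log-linear in the latent activities with Poisson counts
and per-cell library-size factors (negative-binomial overdispersion is a
config option, default off). Cells of one sample share the sample-level
latents and additionally carry per-cell pathway activity noise, which is
what creates single-cell co-expression between a ligand and its module
within samples. Ligand-to-receiver transmission uses the population
(sample-level) ligand latent, not single-cell pairing, because the
inference operates on pseudo-bulk.

Randomness is organized as one master seed plus per-patient streams derived
by fixed offsets, so changing the patient count does not reshuffle earlier
patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_io import CellMatrix, LRPair, write_cell_matrix, write_lr_database

__all__ = ["SimConfig", "ChannelTruth", "GroundTruth", "simulate",
           "default_config", "write_simulation"]


@dataclass
class SimConfig:
    """Generator configuration; the seed fully determines the output."""

    n_patients: int = 31
    cells_per_sample_per_type: int = 200
    sender_type: str = "T"
    receiver_types: tuple[str, ...] = ("myeloid",)
    n_channels: int = 5
    genes_per_gem: int = 3
    n_decoy_lr: int = 50
    n_confounded_pairs: int = 20
    n_background: int = 20

    # treatment -> sender pathway
    a1: float = 1.0            # treatment effect on pathway activity (log scale)
    sigma_u: float = 0.25      # patient confounder scale
    sigma_pathway: float = 0.2 # sample-level pathway noise (sender and receiver)

    # loadings (log-linear, natural-log scale)
    lambda_x: float = 0.8      # pathway A -> GEM X gene
    theta_lig: float = 0.8     # pathway A -> ligand
    theta_y: float = 0.8       # pathway B -> GEM Y gene
    b1: float = 1.0            # transmitted signal -> pathway B
    c_u: float = 0.1           # patient confounder -> pathway B (residual confounding)
    rho0: float = 1.0          # constitutive receptor activity
    sigma_receptor: float = 0.015  # receptor sample-level variation
    gamma_rec_cell: float = 0.55   # receptor loading on per-cell pathway B activity
    sigma_lig: float = 0.1     # ligand sample-level noise (part of the transmitted signal)
    lr_base_boost: float = 2.0 # extra log-rate for ligand/receptor genes (incl. decoys)
    bg_base_boost: float = 3.0 # background genes carry most of the library mass

    # per-gene / per-cell noise
    sigma_gene: float = 0.2   # per-gene per-sample noise (GEM genes)
    sigma_cell: float = 0.9    # per-cell pathway activity noise
    sigma_lib: float = 0.3     # log-normal library size factor scale
    sigma_background: float = 0.2  # background per-gene per-sample noise
    sigma_decoy: float = 0.4   # decoy ligand/receptor sample-level variation

    # confounded decoy pairs: direct treatment effects + shared confounder
    conf_zx: float = 0.7
    conf_zy: float = 0.9
    conf_u: float = 1.2
    sigma_conf_x: float = 0.6  # large: X' is a poor proxy of the treatment signal
    sigma_conf_y: float = 0.15

    base_log_rate: float = float(np.log(2.5))  # mean per-cell count scale
    base_spread: float = 0.4
    nb_dispersion: float | None = None  # gamma-Poisson overdispersion, off by default
    expected: bool = False  # debug: return expected counts instead of Poisson draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("need n_patients >= 4")
        if not self.receiver_types:
            raise ValueError("degenerate config: no receiver cell types")
        if self.sender_type in self.receiver_types:
            raise ValueError("sender type cannot also be a receiver")
        for name in ("sigma_u", "sigma_pathway", "sigma_gene", "sigma_cell",
                     "sigma_lib", "sigma_background", "sigma_decoy",
                     "sigma_conf_x", "sigma_conf_y", "sigma_receptor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return (self.sender_type, *self.receiver_types)

    def noiseless(self) -> "SimConfig":
        """Copy with every noise scale zeroed and expected-count output."""
        return replace(
            self, sigma_u=0.0, sigma_pathway=0.0, sigma_gene=0.0, sigma_cell=0.0,
            sigma_lib=0.0, sigma_background=0.0, sigma_decoy=0.0,
            sigma_conf_x=0.0, sigma_conf_y=0.0, sigma_receptor=0.0,
            sigma_lig=0.0, base_spread=0.0, expected=True,
        )


@dataclass(frozen=True)
class ChannelTruth:
    sender_type: str
    receiver_type: str
    ligand: str
    receptor: tuple[str, ...]
    gem_x: tuple[str, ...]
    gem_y: tuple[str, ...]

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.sender_type, self.receiver_type, self.ligand,
                "_".join(self.receptor))


@dataclass
class GroundTruth:
    channels: list[ChannelTruth]
    confounded_pairs: list[tuple[str, str]]  # (sender gene X', receiver gene Y')
    decoy_lr: list[LRPair]

    def __post_init__(self) -> None:
        channel_genes = set()
        for ch in self.channels:
            channel_genes |= {ch.ligand, *ch.receptor, *ch.gem_x, *ch.gem_y}
        other = {g for pair in self.confounded_pairs for g in pair}
        other |= {p.ligand for p in self.decoy_lr}
        other |= {s for p in self.decoy_lr for s in p.receptor}
        if channel_genes & other:
            raise ValueError("channel genes overlap decoy/confounded genes")

    def lr_pairs(self) -> list[LRPair]:
        """Planted plus decoy LR pairs, sorted - the screening database."""
        planted = [
            LRPair(ligand=ch.ligand, receptor=ch.receptor, source="synthetic")
            for ch in self.channels
        ]
        return sorted(planted + list(self.decoy_lr), key=lambda p: p.key)

    def to_dict(self) -> dict:
        return {
            "channels": [
                {
                    "sender_type": c.sender_type, "receiver_type": c.receiver_type,
                    "ligand": c.ligand, "receptor": list(c.receptor),
                    "gem_x": list(c.gem_x), "gem_y": list(c.gem_y),
                }
                for c in self.channels
            ],
            "confounded_pairs": [list(p) for p in self.confounded_pairs],
            "decoy_lr": [
                {"ligand": p.ligand, "receptor": list(p.receptor), "source": p.source}
                for p in self.decoy_lr
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GroundTruth":
        return cls(
            channels=[
                ChannelTruth(
                    sender_type=c["sender_type"], receiver_type=c["receiver_type"],
                    ligand=c["ligand"], receptor=tuple(c["receptor"]),
                    gem_x=tuple(c["gem_x"]), gem_y=tuple(c["gem_y"]),
                )
                for c in payload["channels"]
            ],
            confounded_pairs=[tuple(p) for p in payload["confounded_pairs"]],
            decoy_lr=[
                LRPair(ligand=p["ligand"], receptor=tuple(p["receptor"]),
                       source=p.get("source", "synthetic"))
                for p in payload["decoy_lr"]
            ],
        )


# ---------------------------------------------------------------------------
# gene panel layout
# ---------------------------------------------------------------------------

@dataclass
class _Panel:
    genes: list[str]
    pos: dict[str, int]
    truth: GroundTruth
    channel_receiver: list[str]  # receiver type per channel


def _build_panel(cfg: SimConfig) -> _Panel:
    genes: list[str] = []
    channels = []
    channel_receiver = []
    for k in range(cfg.n_channels):
        receiver = cfg.receiver_types[k % len(cfg.receiver_types)]
        lig, rec = f"LIG{k + 1}", f"REC{k + 1}"
        gem_x = tuple(f"GX{k + 1}_{i + 1}" for i in range(cfg.genes_per_gem))
        gem_y = tuple(f"GY{k + 1}_{j + 1}" for j in range(cfg.genes_per_gem))
        genes += [lig, rec, *gem_x, *gem_y]
        channels.append(ChannelTruth(
            sender_type=cfg.sender_type, receiver_type=receiver,
            ligand=lig, receptor=(rec,), gem_x=gem_x, gem_y=gem_y,
        ))
        channel_receiver.append(receiver)
    confounded = []
    for j in range(cfg.n_confounded_pairs):
        cx, cy = f"CX{j + 1}", f"CY{j + 1}"
        genes += [cx, cy]
        confounded.append((cx, cy))
    decoys = []
    for j in range(cfg.n_decoy_lr):
        dl, dr = f"DL{j + 1}", f"DR{j + 1}"
        genes += [dl, dr]
        decoys.append(LRPair(ligand=dl, receptor=(dr,), source="synthetic_decoy"))
    genes += [f"BG{i + 1}" for i in range(cfg.n_background)]
    truth = GroundTruth(channels=channels, confounded_pairs=confounded,
                        decoy_lr=decoys)
    return _Panel(genes=genes, pos={g: i for i, g in enumerate(genes)},
                  truth=truth, channel_receiver=channel_receiver)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _patient_rng(seed: int, patient: int) -> np.random.Generator:
    # fixed offset per patient: earlier patients are unaffected by n_patients
    return np.random.default_rng([seed, 7001 + patient])


def simulate(cfg: SimConfig) -> tuple[CellMatrix, GroundTruth]:
    """Draw one paired pre/post dataset; returns (CellMatrix, GroundTruth)."""
    panel = _build_panel(cfg)
    n_genes = len(panel.genes)
    struct_rng = np.random.default_rng([cfg.seed, 1])
    base = cfg.base_log_rate + cfg.base_spread * struct_rng.standard_normal(n_genes)
    # ligand/receptor genes (planted and decoy) are highly expressed so their
    # pseudo-bulk levels - the conditioning variable - are well measured
    for c in panel.truth.channels:
        base[panel.pos[c.ligand]] += cfg.lr_base_boost
        base[panel.pos[c.receptor[0]]] += cfg.lr_base_boost
    for p in panel.truth.decoy_lr:
        base[panel.pos[p.ligand]] += cfg.lr_base_boost
        base[panel.pos[p.receptor[0]]] += cfg.lr_base_boost
    # background/housekeeping genes dominate the library, so per-sample CPM
    # denominators stay stable when the responsive modules shift
    for i in range(cfg.n_background):
        base[panel.pos[f"BG{i + 1}"]] += cfg.bg_base_boost

    K = cfg.n_channels
    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    meta_rows: list[tuple] = []

    # index arrays per role (gene panel positions)
    lig_idx = np.array([panel.pos[c.ligand] for c in panel.truth.channels], dtype=int)
    rec_idx = np.array([panel.pos[c.receptor[0]] for c in panel.truth.channels], dtype=int)
    gemx_idx = [np.array([panel.pos[g] for g in c.gem_x]) for c in panel.truth.channels]
    gemy_idx = [np.array([panel.pos[g] for g in c.gem_y]) for c in panel.truth.channels]
    cx_idx = np.array([panel.pos[x] for x, _ in panel.truth.confounded_pairs], dtype=int)
    cy_idx = np.array([panel.pos[y] for _, y in panel.truth.confounded_pairs], dtype=int)
    dl_idx = np.array([panel.pos[p.ligand] for p in panel.truth.decoy_lr], dtype=int)
    dr_idx = np.array([panel.pos[p.receptor[0]] for p in panel.truth.decoy_lr], dtype=int)
    bg_idx = np.array([panel.pos[f"BG{i + 1}"] for i in range(cfg.n_background)], dtype=int)

    n_cells = cfg.cells_per_sample_per_type
    for i in range(cfg.n_patients):
        rng = _patient_rng(cfg.seed, i)
        patient = f"P{i + 1:02d}"
        u = cfg.sigma_u * rng.standard_normal()
        for z, tp in ((0, "pre"), (1, "post")):
            sample = f"{patient}-{tp}"
            # --- sample-level latents (fixed draw order) ------------------
            eps_a = cfg.sigma_pathway * rng.standard_normal(K)
            eps_lig = cfg.sigma_lig * rng.standard_normal(K)
            eps_rec = cfg.sigma_receptor * rng.standard_normal(K)
            eps_b = cfg.sigma_pathway * rng.standard_normal(K)
            eps_cx = cfg.sigma_conf_x * rng.standard_normal(len(cx_idx))
            eps_cy = cfg.sigma_conf_y * rng.standard_normal(len(cy_idx))
            eps_dl = cfg.sigma_decoy * rng.standard_normal(len(dl_idx))
            eps_dr = cfg.sigma_decoy * rng.standard_normal(len(dr_idx))
            eps_gx = cfg.sigma_gene * rng.standard_normal((K, cfg.genes_per_gem))
            eps_gy = cfg.sigma_gene * rng.standard_normal((K, cfg.genes_per_gem))
            eps_bg = {
                ct: cfg.sigma_background * rng.standard_normal(len(bg_idx))
                for ct in cfg.cell_types
            }

            A = cfg.a1 * z + u + eps_a                    # sender pathway, per channel
            ell = cfg.theta_lig * A + eps_lig             # transmitted ligand latent
            rho = cfg.rho0 + eps_rec                      # receptor activity
            S = ell * rho                                 # transmitted signal
            B = cfg.b1 * S + cfg.c_u * u + eps_b          # receiver pathway, per channel

            for ctype in cfg.cell_types:
                lib = np.exp(cfg.sigma_lib * rng.standard_normal(n_cells))
                eta = cfg.sigma_cell * rng.standard_normal((K, n_cells))

                lograte = np.repeat(base[:, None], n_cells, axis=1)
                if ctype == cfg.sender_type:
                    for k in range(K):
                        lograte[gemx_idx[k]] += (
                            cfg.lambda_x * (A[k] + eta[k])[None, :]
                            + eps_gx[k][:, None]
                        )
                        lograte[lig_idx[k]] += cfg.theta_lig * (A[k] + eta[k])
                    if len(cx_idx):
                        lograte[cx_idx] += (
                            cfg.conf_zx * z + cfg.conf_u * u + eps_cx
                        )[:, None]
                    if len(dl_idx):
                        lograte[dl_idx] += eps_dl[:, None]
                else:
                    for k in range(K):
                        if panel.channel_receiver[k] != ctype:
                            continue
                        lograte[gemy_idx[k]] += (
                            cfg.theta_y * (B[k] + eta[k])[None, :]
                            + eps_gy[k][:, None]
                        )
                        lograte[rec_idx[k]] += (
                            eps_rec[k] + cfg.gamma_rec_cell * eta[k]
                        )
                    if len(cy_idx):
                        lograte[cy_idx] += (
                            cfg.conf_zy * z + cfg.conf_u * u + eps_cy
                        )[:, None]
                    if len(dr_idx):
                        lograte[dr_idx] += eps_dr[:, None]
                if len(bg_idx):
                    lograte[bg_idx] += eps_bg[ctype][:, None]

                lam = np.exp(lograte) * lib[None, :]
                if cfg.nb_dispersion:
                    shape = 1.0 / cfg.nb_dispersion
                    lam = lam * rng.gamma(shape, cfg.nb_dispersion, size=lam.shape)
                counts = lam if cfg.expected else rng.poisson(lam).astype(np.int64)
                blocks.append(counts)
                for j in range(n_cells):
                    cell_ids.append(f"{sample}_{ctype}_{j + 1}")
                    meta_rows.append((cell_ids[-1], sample, patient, tp, ctype))

    counts = sp.csr_matrix(np.hstack(blocks))
    meta = pd.DataFrame(
        meta_rows,
        columns=["cell_id", "sample_id", "patient_id", "timepoint", "cell_type"],
    )
    cm = CellMatrix(counts=counts, gene_ids=list(panel.genes),
                    cell_ids=cell_ids, meta=meta)
    return cm, panel.truth


def default_config(scale: str, seed: int = 0) -> SimConfig:
    """Preset study scales: ``smoke`` (desk test) or ``full`` (31 patients)."""
    if scale == "smoke":
        return SimConfig(
            n_patients=8, cells_per_sample_per_type=50, n_channels=1,
            genes_per_gem=3, n_decoy_lr=4, n_confounded_pairs=2,
            n_background=20, seed=seed,
        )
    if scale == "full":
        return SimConfig(
            n_patients=31, cells_per_sample_per_type=200, n_channels=5,
            genes_per_gem=3, n_decoy_lr=50, n_confounded_pairs=20,
            n_background=20, seed=seed,
        )
    raise ValueError(f"unknown scale {scale!r} (expected 'smoke' or 'full')")


def write_simulation(cfg: SimConfig, outdir: str | Path) -> tuple[CellMatrix, GroundTruth]:
    """Simulate and write MTX triplet + meta.tsv + lr_db.tsv + ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate(cfg)
    write_cell_matrix(cm, outdir)
    write_lr_database(truth.lr_pairs(), outdir / "lr_db.tsv")
    payload = {"config": asdict(cfg), "ground_truth": truth.to_dict()}
    payload["config"]["receiver_types"] = list(cfg.receiver_types)
    (outdir / "ground_truth.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return cm, truth
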