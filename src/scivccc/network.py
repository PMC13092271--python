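"""Grouping of mediating (X, Y, LR) triples into gene expression modules and
assembly of the cell-cell communication network.

Triples first pass an anti-direct-co-expression filter: the association
pattern around each triple must vanish once the LR interaction intensity M is
conditioned out. In the default ``residual`` mode each of the five
comparisons (X-Y, X-ligand, X-M, receptor-Y, M-Y) is evaluated on residuals
given M, so a triple is removed when any post-conditioning |Pearson r|
reaches ``rho_max`` — e.g. an "X" that simply duplicates the ligand keeps a
residual correlation of 1 with it and is dropped. A ``literal`` mode instead
applies the threshold to the raw pseudo-bulk correlations; note that raw
|r(X, M)| and |r(M, Y)| below 0.3 jointly cap the marginal X-Y association
near 0.09, below any detectable dependence at these sample sizes, so the
literal mode is expected to return empty results under genuine mediation
(see docs/methods.md).

Surviving triples are partitioned by (sender type, receiver type, LR pair);
each group's X genes form the sender GEM and Y genes the receiver GEM, and
each group becomes one channel of the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cit import CITResult, lr_conditioning_variable
from .data_io import LRPair
from .preprocess import PseudoBulkTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GEModule:
    gem_id: str
    side: str  # "sender" | "receiver"
    cell_type: str
    members: tuple[str, ...]  # sorted gene symbols
    lr: LRPair

    def __post_init__(self) -> None:
        if self.side not in ("sender", "receiver"):
            raise ValueError(f"invalid side {self.side!r}")
        if not self.members:
            raise ValueError("GEM must have at least one member")


@dataclass(frozen=True)
class Channel:
    sender_gem: GEModule
    receiver_gem: GEModule
    lr: LRPair
    n_pairs: int
    median_p_cond: float
    median_r_partial: float

    def __post_init__(self) -> None:
        if self.sender_gem.lr != self.lr or self.receiver_gem.lr != self.lr:
            raise ValueError("channel and GEM LR pairs disagree")
        if self.n_pairs > len(self.sender_gem.members) * len(self.receiver_gem.members):
            raise ValueError("n_pairs exceeds |sender GEM| x |receiver GEM|")


@dataclass
class CCCNetwork:
    channels: list[Channel] = field(default_factory=list)

    def __eq__(self, other) -> bool:
        return isinstance(other, CCCNetwork) and self.channels == other.channels

    def channel_keys(self) -> list[tuple[str, str, str, str]]:
        return [
            (c.sender_gem.cell_type, c.receiver_gem.cell_type,
             c.lr.ligand, c.lr.receptor_name)
            for c in self.channels
        ]

    def to_graph(self):
        """Bipartite GEM graph with one LR edge per channel (networkx)."""
        import networkx as nx

        g = nx.DiGraph()
        for ch in self.channels:
            for gem in (ch.sender_gem, ch.receiver_gem):
                g.add_node(gem.gem_id, side=gem.side, cell_type=gem.cell_type,
                           members=list(gem.members))
            g.add_edge(
                ch.sender_gem.gem_id, ch.receiver_gem.gem_id,
                ligand=ch.lr.ligand, receptor=ch.lr.receptor_name,
                n_pairs=ch.n_pairs, median_p_cond=ch.median_p_cond,
            )
        return g

    # -- JSON plumbing -----------------------------------------------------
    def to_dict(self) -> dict:
        def gem_dict(gem: GEModule) -> dict:
            return {
                "gem_id": gem.gem_id, "side": gem.side,
                "cell_type": gem.cell_type, "members": list(gem.members),
            }

        return {
            "channels": [
                {
                    "sender_type": ch.sender_gem.cell_type,
                    "receiver_type": ch.receiver_gem.cell_type,
                    "ligand": ch.lr.ligand,
                    "receptor": list(ch.lr.receptor),
                    "lr_source": ch.lr.source,
                    "sender_gem": gem_dict(ch.sender_gem),
                    "receiver_gem": gem_dict(ch.receiver_gem),
                    "n_pairs": ch.n_pairs,
                    "stats": {
                        "median_p_cond": ch.median_p_cond,
                        "median_r_partial": ch.median_r_partial,
                    },
                }
                for ch in self.channels
            ]
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CCCNetwork":
        channels = []
        for ch in payload["channels"]:
            lr = LRPair(ligand=ch["ligand"], receptor=tuple(ch["receptor"]),
                        source=ch.get("lr_source", ""))

            def gem(d: dict) -> GEModule:
                return GEModule(
                    gem_id=d["gem_id"], side=d["side"], cell_type=d["cell_type"],
                    members=tuple(d["members"]), lr=lr,
                )

            channels.append(
                Channel(
                    sender_gem=gem(ch["sender_gem"]),
                    receiver_gem=gem(ch["receiver_gem"]), lr=lr,
                    n_pairs=int(ch["n_pairs"]),
                    median_p_cond=float(ch["stats"]["median_p_cond"]),
                    median_r_partial=float(ch["stats"]["median_r_partial"]),
                )
            )
        return cls(channels=channels)


# ---------------------------------------------------------------------------
# anti-direct-co-expression filter
# ---------------------------------------------------------------------------

def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _residual(v: np.ndarray, m: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(m)), m])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def filter_direct_coexpression(triples: list[CITResult],
                               pb_sender: PseudoBulkTable,
                               pb_receiver: PseudoBulkTable,
                               rho_max: float = 0.3,
                               mode: str = "residual",
                               complex_mode: str = "min") -> list[CITResult]:
    """Retain triples whose five diagnostic correlations stay below rho_max.

    ``mode='residual'`` (default) evaluates each comparison on residuals
    given M; ``mode='literal'`` uses raw pseudo-bulk correlations.
    """
    if mode not in ("residual", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    kept: list[CITResult] = []
    for tr in triples:
        m = lr_conditioning_variable(pb_sender, pb_receiver, tr.lr, complex_mode)
        if m is None or np.std(m) == 0:
            log.warning("triple (%s, %s, %s): unusable conditioning variable; dropped",
                        tr.x_gene, tr.y_gene, tr.lr)
            continue
        x = pb_sender.values[tr.x_gene].to_numpy()
        y = pb_receiver.values[tr.y_gene].to_numpy()
        lig = pb_sender.values[tr.lr.ligand].to_numpy()
        subs = pb_receiver.values[list(tr.lr.receptor)].to_numpy()
        rec = subs.min(axis=1) if complex_mode == "min" else np.exp(
            np.log(np.maximum(subs, 1e-12)).mean(axis=1))

        if mode == "residual":
            xr, yr = _residual(x, m), _residual(y, m)
            ligr, recr = _residual(lig, m), _residual(rec, m)
            checks = {
                "x_vs_y": _safe_corr(xr, yr),
                "x_vs_ligand": _safe_corr(xr, ligr),
                "x_vs_lr_product": _safe_corr(xr, m),
                "receptor_vs_y": _safe_corr(recr, yr),
                "lr_product_vs_y": _safe_corr(m, yr),
            }
        else:
            checks = {
                "x_vs_y": _safe_corr(x, y),
                "x_vs_ligand": _safe_corr(x, lig),
                "x_vs_lr_product": _safe_corr(x, m),
                "receptor_vs_y": _safe_corr(rec, y),
                "lr_product_vs_y": _safe_corr(m, y),
            }
        failed = [name for name, r in checks.items() if abs(r) >= rho_max]
        if failed:
            log.info("triple (%s, %s, %s) removed by: %s",
                     tr.x_gene, tr.y_gene, tr.lr, ", ".join(failed))
        else:
            kept.append(tr)
    return kept


# ---------------------------------------------------------------------------
# GEM grouping and network assembly
# ---------------------------------------------------------------------------

@dataclass
class GemPair:
    sender_gem: GEModule
    receiver_gem: GEModule
    lr: LRPair
    triples: list[CITResult]


def group_gems(triples: list[CITResult]) -> list[GemPair]:
    """Partition triples by (sender type, receiver type, LR pair) into GEMs.

    GEM ids are deterministic: groups are sorted by (sender_type,
    receiver_type, ligand, receptor) and numbered 1..K within each cell type.
    """
    groups: dict[tuple, list[CITResult]] = {}
    for tr in triples:
        key = (tr.sender_type, tr.receiver_type, tr.lr.ligand, tr.lr.receptor)
        groups.setdefault(key, []).append(tr)

    pairs: list[GemPair] = []
    for k, key in enumerate(sorted(groups), start=1):
        members = groups[key]
        sender_type, receiver_type = key[0], key[1]
        lr = members[0].lr
        x_genes = tuple(sorted({t.x_gene for t in members}))
        y_genes = tuple(sorted({t.y_gene for t in members}))
        pairs.append(
            GemPair(
                sender_gem=GEModule(
                    gem_id=f"GEM_{sender_type}_{k}", side="sender",
                    cell_type=sender_type, members=x_genes, lr=lr,
                ),
                receiver_gem=GEModule(
                    gem_id=f"GEM_{receiver_type}_{k}", side="receiver",
                    cell_type=receiver_type, members=y_genes, lr=lr,
                ),
                lr=lr,
                triples=members,
            )
        )
    return pairs


def build_network(gem_pairs: list[GemPair]) -> CCCNetwork:
    """Assemble channels with per-channel summaries, deterministically ordered."""
    channels = []
    for gp in gem_pairs:
        distinct = {(t.x_gene, t.y_gene) for t in gp.triples}
        p_conds = [t.fisher.p_value for t in gp.triples]
        r_parts = [t.fisher.r_partial for t in gp.triples]
        channels.append(
            Channel(
                sender_gem=gp.sender_gem, receiver_gem=gp.receiver_gem, lr=gp.lr,
                n_pairs=len(distinct),
                median_p_cond=float(np.median(p_conds)),
                median_r_partial=float(np.median(r_parts)),
            )
        )
    channels.sort(key=lambda c: (c.sender_gem.cell_type, c.receiver_gem.cell_type,
                                 c.lr.ligand, c.lr.receptor))
    return CCCNetwork(channels=channels)


def gems_to_frame(gem_pairs: list[GemPair]) -> pd.DataFrame:
    rows = []
    for gp in gem_pairs:
        for gem in (gp.sender_gem, gp.receiver_gem):
            rows.append(
                (gem.gem_id, gem.side, gem.cell_type,
                 f"{gem.lr.ligand}->{gem.lr.receptor_name}", ",".join(gem.members))
            )
    return pd.DataFrame(rows, columns=["gem_id", "side", "cell_type", "lr", "members"])
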