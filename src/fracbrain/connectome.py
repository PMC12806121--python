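"""Connectome data model: fiber-weighted adjacency, per-species Laplacians,
brain-ID/region metadata, and region averaging.

Nodes are gray-matter regions of interest; an edge (i, j) carries the mean
fiber count ``n_ij`` and the mean fiber length ``l_ij`` (mm) of the axon
bundle linking them.  Connection strength is ``A_ij = n_ij / l_ij**2`` and
each diffusing species s propagates through its own Laplacian
``L^s = rho_s (D - A)`` with ``D`` the weighted degree matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParameters

logger = logging.getLogger(__name__)

#: The seven cortical/subcortical territories used for region-wise summaries.
REGIONS: tuple[str, ...] = (
    "limbic",
    "frontal",
    "parietal",
    "basal ganglia",
    "brain stem",
    "occipital",
    "temporal",
)

#: Catalogue of the 49 brain IDs (anatomical parcels) per region.
BRAIN_ID_CATALOG: dict[str, tuple[str, ...]] = {
    "limbic": (
        "rostralanteriorcingulate", "posteriorcingulate", "caudalanteriorcingulate",
        "parahippocampal", "isthmuscingulate", "entorhinal",
    ),
    "frontal": (
        "frontalpole", "lateralorbitofrontal", "parsorbitalis", "medialorbitofrontal",
        "precentral", "parstriangularis", "parsopercularis", "rostralmiddlefrontal",
        "caudalmiddlefrontal", "superiorfrontal",
    ),
    "parietal": (
        "postcentral", "supramarginal", "superiorparietal", "inferiorparietal",
        "precuneus", "paracentral",
    ),
    "basal ganglia": (
        "left-thalamus-proper", "left-putamen", "left-caudate", "left-accumbens-area",
        "left-pallidum", "left-amygdala", "right-thalamus-proper", "right-putamen",
        "right-caudate", "right-accumbens-area", "right-pallidum", "right-amygdala",
    ),
    "brain stem": ("brain-stem",),
    "occipital": ("cuneus", "pericalcarine", "lateraloccipital", "lingual"),
    "temporal": (
        "middletemporal", "left-hippocampus", "right-hippocampus", "temporalpole",
        "inferiortemporal", "bankssts", "superiortemporal", "transversetemporal",
        "insula", "fusiform",
    ),
}

#: brain ID -> region, inverted from the catalogue.
BRAIN_ID_REGION: dict[str, str] = {
    bid: region for region, ids in BRAIN_ID_CATALOG.items() for bid in ids
}

NODE_COLUMNS = ("id", "x", "y", "z", "brain_id", "region")
EDGE_COLUMNS = ("source", "target", "n_fibers", "length_mm")


@dataclass
class Connectome:
    """Validated node/edge tables plus named toxic-seeding node sets.

    ``nodes``: columns id, x, y, z, brain_id, region (ids 0..N-1 contiguous).
    ``edges``: columns source, target, n_fibers, length_mm; undirected, each
    unordered pair stored once with source < target.
    ``seed_sets``: e.g. ``{"abeta": array of node ids, "tau": ...}``.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    seed_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = self.nodes.reset_index(drop=True)
        self.edges = self.edges.reset_index(drop=True)
        self.seed_sets = {
            k: np.asarray(v, dtype=int) for k, v in self.seed_sets.items()
        }
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def validate(self) -> None:
        for col in NODE_COLUMNS:
            if col not in self.nodes.columns:
                raise ValueError(f"node table missing column {col!r}")
        for col in EDGE_COLUMNS:
            if col not in self.edges.columns:
                raise ValueError(f"edge table missing column {col!r}")
        ids = self.nodes["id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("node ids must be contiguous 0..N-1")
        bad_region = self.nodes.index[~self.nodes["region"].isin(REGIONS)]
        if len(bad_region):
            raise ValueError(f"unknown region label at node rows {list(bad_region[:5])}")
        known = self.nodes["brain_id"].str.lower().map(BRAIN_ID_REGION)
        mism = self.nodes.index[known.notna() & (known != self.nodes["region"])]
        if len(mism):
            raise ValueError(
                f"brain_id/region mismatch at node rows {list(mism[:5])}"
            )
        s = self.edges["source"].to_numpy()
        t = self.edges["target"].to_numpy()
        loops = np.nonzero(s == t)[0]
        if len(loops):
            raise ValueError(f"self-loop at edge rows {[int(i) for i in loops[:5]]}")
        if s.min(initial=0) < 0 or max(s.max(initial=0), t.max(initial=0)) >= len(ids):
            raise ValueError("edge endpoint outside node id range")
        lo, hi = np.minimum(s, t), np.maximum(s, t)
        pair = lo.astype(np.int64) * len(ids) + hi
        dup = np.nonzero(pd.Series(pair).duplicated().to_numpy())[0]
        if len(dup):
            raise ValueError(f"duplicate undirected edge at rows {list(dup[:5])}")
        if np.any(self.edges["n_fibers"].to_numpy() <= 0):
            raise ValueError("n_fibers must be > 0")
        if np.any(self.edges["length_mm"].to_numpy() <= 0):
            raise ValueError("length_mm must be > 0")
        for name, members in self.seed_sets.items():
            if len(members) and (members.min() < 0 or members.max() >= len(ids)):
                raise ValueError(f"seed set {name!r} references unknown node ids")

    def summary(self) -> dict:
        nf = self.edges["n_fibers"]
        lm = self.edges["length_mm"]
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "fiber_count_mean": float(nf.mean()) if len(nf) else float("nan"),
            "fiber_count_range": [float(nf.min()), float(nf.max())] if len(nf) else None,
            "length_mm_mean": float(lm.mean()) if len(lm) else float("nan"),
            "length_mm_range": [float(lm.min()), float(lm.max())] if len(lm) else None,
            "regions": self.nodes["region"].value_counts().to_dict(),
        }


@dataclass
class LaplacianSet:
    """One dense N x N Laplacian per diffusing species."""

    u: np.ndarray
    u_tilde: np.ndarray
    v: np.ndarray
    v_tilde: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"u": self.u, "u_tilde": self.u_tilde, "v": self.v, "v_tilde": self.v_tilde}


def build_adjacency(connectome: Connectome) -> np.ndarray:
    """Symmetric fiber-weighted adjacency ``A_ij = n_ij / l_ij**2``."""
    n = connectome.n_nodes
    A = np.zeros((n, n))
    s = connectome.edges["source"].to_numpy(dtype=int)
    t = connectome.edges["target"].to_numpy(dtype=int)
    w = (
        connectome.edges["n_fibers"].to_numpy(dtype=float)
        / connectome.edges["length_mm"].to_numpy(dtype=float) ** 2
    )
    A[s, t] = w
    A[t, s] = w
    return A


def build_laplacians(A: np.ndarray, params: ModelParameters) -> LaplacianSet:
    """Per-species Laplacians ``L^s = rho_s (D - A)``; rows sum to zero."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(A < 0) or np.max(np.abs(np.diag(A))) > 0:
        raise ValueError("adjacency must be nonnegative with zero diagonal")
    rhos = {
        "u": params.rho_u,
        "u_tilde": params.rho_u_tilde,
        "v": params.rho_v,
        "v_tilde": params.rho_v_tilde,
    }
    for name, rho in rhos.items():
        if rho < 0:
            raise ValueError(f"diffusion coefficient for {name} must be >= 0")
    L0 = np.diag(A.sum(axis=1)) - A
    return LaplacianSet(**{name: rho * L0 for name, rho in rhos.items()})


def region_average(values, grouping) -> pd.Series:
    """Group means ``M_d = (1/n_d) sum_{k in R_d} value_k``.

    ``grouping`` maps each node to its group (an array/Series aligned with
    ``values``, e.g. the connectome's ``brain_id`` or ``region`` column).
    ``values`` may be 1-D (one snapshot) or 2-D ``(time, node)``, in which
    case a DataFrame of per-group time series is returned.
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(np.asarray(grouping))
    if values.shape[-1] != len(groups):
        raise ValueError("values and grouping length mismatch")
    if values.ndim == 1:
        return pd.Series(values).groupby(groups.values).mean()
    return pd.DataFrame(values).T.groupby(groups.values).mean().T


def read_connectome(
    node_file: str | Path, edge_file: str | Path, *, seed_sets: dict | None = None
) -> Connectome:
    """Load and validate CSV node/edge tables.

    Optional boolean node columns ``seed_abeta`` / ``seed_tau`` define the
    toxic seeding sets (the synthetic generator writes them); an explicit
    ``seed_sets`` argument overrides.  Logs N, E and fiber statistics at INFO
    so a load of the real data can be compared against published summaries.
    """
    nodes = pd.read_csv(node_file)
    edges = pd.read_csv(edge_file)
    sets = dict(seed_sets or {})
    for name, col in (("abeta", "seed_abeta"), ("tau", "seed_tau")):
        if name not in sets and col in nodes.columns:
            sets[name] = nodes.index[nodes[col].astype(bool)].to_numpy()
    conn = Connectome(nodes, edges, sets)
    s = conn.summary()
    logger.info(
        "connectome: N=%d nodes, E=%d edges; fibers mean %.2f range %s; "
        "length mean %.3f mm range %s",
        s["n_nodes"], s["n_edges"], s["fiber_count_mean"], s["fiber_count_range"],
        s["length_mm_mean"], s["length_mm_range"],
    )
    return conn


def write_connectome(conn: Connectome, node_file: str | Path, edge_file: str | Path) -> None:
    """Write the CSV dialect read by :func:`read_connectome` (round-trip safe)."""
    nodes = conn.nodes.copy()
    for name, col in (("abeta", "seed_abeta"), ("tau", "seed_tau")):
        flags = np.zeros(len(nodes), dtype=bool)
        flags[conn.seed_sets.get(name, np.empty(0, int))] = True
        nodes[col] = flags
    nodes.to_csv(node_file, index=False)
    conn.edges.to_csv(edge_file, index=False)


def read_graphml(path: str | Path) -> Connectome:
    """Import a GraphML connectome with node attributes x, y, z, brain_id,
    region and edge attributes n_fibers, length_mm."""
    import networkx as nx

    g = nx.read_graphml(path)
    order = sorted(g.nodes, key=lambda k: int(k))
    index = {k: i for i, k in enumerate(order)}
    nodes = pd.DataFrame(
        {
            "id": range(len(order)),
            **{
                col: [g.nodes[k][col] for k in order]
                for col in ("x", "y", "z", "brain_id", "region")
            },
        }
    )
    edges = pd.DataFrame(
        [
            {
                "source": min(index[a], index[b]),
                "target": max(index[a], index[b]),
                "n_fibers": float(d["n_fibers"]),
                "length_mm": float(d["length_mm"]),
            }
            for a, b, d in g.edges(data=True)
        ]
    )
    return Connectome(nodes, edges)
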