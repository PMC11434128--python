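"""Network construction: populations, topographic projections, geometry.

The four populations (PY, INH, TC, RE) are laid out on 1-D index lines.  A
projection connects presynaptic cell i to every target j within ``radius``
of the index-mapped centre round(i·n_post/n_pre); indices are clipped at the
array bounds (finite slab, no wraparound).  Construction is fully
deterministic — identical configs give identical edge lists.

Spatial coordinates (µm) place each population on its own line at the
configured pitch; cortical dendritic compartments sit a fixed offset above
the somata, giving each PY/INH cell a vertical dipole for the biophysical
LFP forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PROJECTION_NAMES, ProjectionConfig, SimulationConfig

#: source/target populations per projection name
PROJECTION_TOPOLOGY = {name: tuple(name.split("_")) for name in PROJECTION_NAMES}


@dataclass
class Projection:
    """One projection's edge list plus per-edge conductances (µS)."""

    name: str
    source: str
    target: str
    pre: np.ndarray  # int32 source indices
    post: np.ndarray  # int32 target indices
    params: ProjectionConfig
    g_ampa: np.ndarray = field(default_factory=lambda: np.empty(0))
    g_nmda: np.ndarray = field(default_factory=lambda: np.empty(0))
    g_gabaa: np.ndarray = field(default_factory=lambda: np.empty(0))
    g_gabab: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_edges(self) -> int:
        return int(self.pre.size)


@dataclass
class Network:
    """Populations, projections and compartment coordinates for one run."""

    counts: dict[str, int]
    projections: list[Projection]
    soma_xyz: dict[str, np.ndarray]  # (n, 3) µm per population
    dend_xyz: dict[str, np.ndarray]  # cortical populations only

    def projection(self, name: str) -> Projection:
        for p in self.projections:
            if p.name == name:
                return p
        raise KeyError(f"no projection named {name!r}")


def build_projection(n_pre: int, n_post: int, radius: int,
                     allow_self: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Edge list (pre, post) of the radius-based topographic rule.

    Cell i connects to all j with |j − round(i·n_post/n_pre)| ≤ radius,
    clipped to [0, n_post); self-edges (same population, same index) are
    excluded unless ``allow_self``.
    """
    if n_pre < 1 or n_post < 1:
        raise ValueError("population counts must be >= 1")
    pre_list: list[int] = []
    post_list: list[int] = []
    same_pop = n_pre == n_post
    for i in range(n_pre):
        centre = int(round(i * n_post / n_pre))
        lo = max(0, centre - radius)
        hi = min(n_post - 1, centre + radius)
        for j in range(lo, hi + 1):
            if same_pop and not allow_self and j == i:
                continue
            pre_list.append(i)
            post_list.append(j)
    return (np.asarray(pre_list, dtype=np.int32),
            np.asarray(post_list, dtype=np.int32))


def _edge_conductances(post: np.ndarray, n_post: int, g_total: float,
                       normalize: bool) -> np.ndarray:
    """Per-edge conductance; with normalisation, g_total is split over the
    actual in-degree of each target so boundary cells get comparable drive."""
    if post.size == 0:
        return np.empty(0)
    if not normalize:
        return np.full(post.size, g_total)
    indeg = np.bincount(post, minlength=n_post).astype(float)
    indeg[indeg == 0] = 1.0
    return g_total / indeg[post]


def build_network(cfg: SimulationConfig) -> Network:
    """Instantiate all populations and the thalamocortical projection set."""
    counts = dict(cfg.populations)
    projections: list[Projection] = []
    normalize = cfg.connectivity.normalize_by_indegree
    for name in PROJECTION_NAMES:
        spec = cfg.connectivity.projections.get(name)
        if spec is None:
            continue
        src, tgt = PROJECTION_TOPOLOGY[name]
        if src not in counts or tgt not in counts:
            raise ValueError(f"projection {name} references unknown population")
        pre, post = build_projection(counts[src], counts[tgt], spec.radius,
                                     allow_self=spec.allow_self and src == tgt)
        proj = Projection(name=name, source=src, target=tgt, pre=pre, post=post,
                          params=spec)
        n_post = counts[tgt]
        proj.g_ampa = _edge_conductances(post, n_post, spec.g_ampa, normalize)
        proj.g_nmda = _edge_conductances(post, n_post, spec.g_nmda, normalize)
        proj.g_gabaa = _edge_conductances(post, n_post, spec.g_gabaa, normalize)
        proj.g_gabab = _edge_conductances(post, n_post, spec.g_gabab, normalize)
        projections.append(proj)

    soma_xyz: dict[str, np.ndarray] = {}
    dend_xyz: dict[str, np.ndarray] = {}
    pitch = cfg.lfp.pitch_um
    # y layers: cortex at 0 (somata) with dendrites above; thalamus far below.
    layer_y = {"PY": 0.0, "INH": -100.0, "TC": -5000.0, "RE": -5500.0}
    for pop, n in counts.items():
        x = (np.arange(n) - (n - 1) / 2.0) * pitch
        xyz = np.column_stack([x, np.full(n, layer_y[pop]), np.zeros(n)])
        soma_xyz[pop] = xyz
        if pop in ("PY", "INH"):
            d = xyz.copy()
            d[:, 1] += cfg.lfp.dend_offset_um
            dend_xyz[pop] = d
    return Network(counts=counts, projections=projections,
                   soma_xyz=soma_xyz, dend_xyz=dend_xyz)


def export_edge_list(net: Network, path: str) -> None:
    """Plain-text edge dump (one line per edge: projection, src, tgt, receptor, µS)."""
    with open(path, "w") as fh:
        fh.write("# projection\tsource\ttarget\treceptor\tweight_uS\n")
        for proj in net.projections:
            for rec in ("ampa", "nmda", "gabaa", "gabab"):
                g = getattr(proj, f"g_{rec}")
                if g.size == 0 or not np.any(g):
                    continue
                for i in range(proj.n_edges):
                    fh.write(f"{proj.name}\t{proj.pre[i]}\t{proj.post[i]}\t{rec}\t{g[i]:.6g}\n")
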