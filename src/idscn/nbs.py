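"""Network-based statistics on stacks of individualized network matrices.

Edge-level one-sample t tests of the patients' Z values against zero,
thresholding at an uncorrected edge p, extraction of connected components
of the suprathreshold graph, and permutation family-wise-error inference on
component size.  Under the symmetric one-sample null the patient matrices
are exchangeable with their negations, so the null is generated by random
sign flips of whole patient matrices; each permutation records the maximal
component size, and a component's FWE p-value is the plus-one-corrected
fraction of permutations whose maximum reaches the observed size.

A two-sample design (patients vs pseudo-patient control networks, group
label permutation) is also provided, since either formulation is defensible
for "average deviation from the norm" questions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

Edge = tuple[int, int]


@dataclass
class NBSConfig:
    n_perm: int = 1000
    edge_alpha: float = 0.001       # uncorrected edge threshold, strict <
    fwe_alpha: float = 0.05         # component-level threshold
    design: str = "one_sample_vs_zero"   # or "two_sample"
    sign_separated: bool = False    # form components per sign instead of jointly
    exhaustive: bool = False        # enumerate all sign patterns (one-sample)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.edge_alpha < 1:
            raise ValueError("edge_alpha must be in (0, 1)")
        if self.n_perm < 100 and not self.exhaustive:
            raise ValueError("n_perm must be >= 100")
        if self.design not in ("one_sample_vs_zero", "two_sample"):
            raise ValueError(f"unknown design {self.design!r}")


@dataclass
class EdgeStatMap:
    t: np.ndarray
    p: np.ndarray
    df: int


@dataclass
class Component:
    edges: list[Edge]
    nodes: list[int]
    size: int            # edge count
    fwe_p: float = 1.0


@dataclass
class NBSResult:
    components: list[Component]
    null_max_sizes: np.ndarray
    edge_stats: EdgeStatMap
    mean_z: np.ndarray
    significant_edges: list[dict] = field(default_factory=list)
    config: NBSConfig | None = None

    @property
    def significant_components(self) -> list[Component]:
        alpha = self.config.fwe_alpha if self.config else 0.05
        return [c for c in self.components if c.fwe_p < alpha]


def _upper(R: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(R, k=1)


def stack_to_edges(z_stack: np.ndarray) -> np.ndarray:
    """(m, R, R) symmetric stack -> (m, E) upper-triangle edge values."""
    z_stack = np.asarray(z_stack, dtype=float)
    iu, ju = _upper(z_stack.shape[1])
    return z_stack[:, iu, ju]


def _onesample_t_from_edges(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized one-sample t of columns vs 0; zero-variance columns get p=1
    when their mean is 0, and raise otherwise."""
    m = vals.shape[0]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    dead = sd < 1e-300
    if np.any(dead & (np.abs(mean) > 0)):
        raise ValueError("zero-variance edge with nonzero mean")
    sd_safe = np.where(dead, 1.0, sd)
    t = mean / (sd_safe / np.sqrt(m))
    t[dead] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=m - 1)
    p = np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0)
    p[dead] = 1.0
    return t, p, m - 1


def edge_onesample_t(z_stack: np.ndarray) -> EdgeStatMap:
    """Per-edge one-sample t of the patients' Z values against zero."""
    z_stack = np.asarray(z_stack, dtype=float)
    if z_stack.ndim != 3:
        raise ValueError("z_stack must be (patients, R, R)")
    if z_stack.shape[0] < 3:
        raise ValueError("need at least 3 patients")
    if not np.isfinite(z_stack).all():
        raise ValueError("z_stack contains non-finite values")
    R = z_stack.shape[1]
    t_e, p_e, df = _onesample_t_from_edges(stack_to_edges(z_stack))
    t = np.zeros((R, R))
    p = np.ones((R, R))
    iu, ju = _upper(R)
    t[iu, ju] = t[ju, iu] = t_e
    p[iu, ju] = p[ju, iu] = p_e
    np.fill_diagonal(p, 1.0)
    return EdgeStatMap(t=t, p=p, df=df)


def threshold_edges(stat: EdgeStatMap, edge_alpha: float) -> list[Edge]:
    """Edges with p strictly below the threshold, canonical (i<j) order."""
    iu, ju = _upper(stat.p.shape[0])
    keep = stat.p[iu, ju] < edge_alpha
    return [(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])]


def connected_components(edges: list[Edge], R: int) -> list[Component]:
    """Components of the suprathreshold graph, descending edge count then
    smallest node id; isolated (edge-free) nodes never form components."""
    for (i, j) in edges:
        if not (0 <= i < R and 0 <= j < R):
            raise ValueError(f"edge ({i},{j}) references region outside 0..{R - 1}")
    g = nx.Graph()
    g.add_edges_from(edges)
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        comp_edges = sorted((min(a, b), max(a, b)) for a, b in sub.edges)
        comps.append(
            Component(edges=comp_edges, nodes=sorted(nodes), size=sub.number_of_edges())
        )
    comps.sort(key=lambda c: (-c.size, c.nodes[0]))
    return comps


def _max_component_size(p_edges: np.ndarray, edge_alpha: float, R: int,
                        iu: np.ndarray, ju: np.ndarray) -> int:
    keep = p_edges < edge_alpha
    if not keep.any():
        return 0
    comps = connected_components(
        [(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])], R
    )
    return comps[0].size if comps else 0


def nbs_run(
    z_stack: np.ndarray,
    config: NBSConfig | None = None,
    control_stack: np.ndarray | None = None,
) -> NBSResult:
    """Full NBS: observed components plus a permutation max-size null.

    One-sample design: random whole-matrix sign flips per patient (or
    exhaustive enumeration of all 2^m patterns when ``config.exhaustive``).
    Two-sample design: group-label permutation against ``control_stack``.
    """
    config = config or NBSConfig()
    z_stack = np.asarray(z_stack, dtype=float)
    m, R = z_stack.shape[0], z_stack.shape[1]
    iu, ju = _upper(R)
    vals = stack_to_edges(z_stack)

    if config.design == "two_sample":
        if control_stack is None:
            raise ValueError("two_sample design requires control_stack")
        cvals = stack_to_edges(np.asarray(control_stack, dtype=float))
        stat = _two_sample_stats(vals, cvals, R, iu, ju)
    else:
        stat = edge_onesample_t(z_stack)

    mean_z = np.zeros((R, R))
    mean_z[iu, ju] = mean_z[ju, iu] = vals.mean(axis=0)

    obs_edges = threshold_edges(stat, config.edge_alpha)
    if config.sign_separated:
        pos = [e for e in obs_edges if mean_z[e] > 0]
        neg = [e for e in obs_edges if mean_z[e] <= 0]
        comps = connected_components(pos, R) + connected_components(neg, R)
        comps.sort(key=lambda c: (-c.size, c.nodes[0]))
    else:
        comps = connected_components(obs_edges, R)

    null_max = _null_max_sizes(vals, config, R, iu, ju, control_stack)
    n_eff = len(null_max)
    for c in comps:
        c.fwe_p = (1.0 + np.sum(null_max >= c.size)) / (n_eff + 1.0)

    sig_edges = []
    for ci, c in enumerate(comps):
        if c.fwe_p < config.fwe_alpha:
            for (i, j) in c.edges:
                sig_edges.append(
                    {
                        "region_i": i,
                        "region_j": j,
                        "t": float(stat.t[i, j]),
                        "p": float(stat.p[i, j]),
                        "mean_z": float(mean_z[i, j]),
                        "sign": "positive" if mean_z[i, j] > 0 else "negative",
                        "component_id": ci,
                        "fwe_p": float(c.fwe_p),
                    }
                )
    return NBSResult(
        components=comps,
        null_max_sizes=np.asarray(null_max),
        edge_stats=stat,
        mean_z=mean_z,
        significant_edges=sig_edges,
        config=config,
    )


def _two_sample_stats(vals, cvals, R, iu, ju) -> EdgeStatMap:
    t_e, p_e = stats.ttest_ind(vals, cvals, axis=0, equal_var=True)
    p_e = np.nan_to_num(p_e, nan=1.0)
    t_e = np.nan_to_num(t_e, nan=0.0)
    t = np.zeros((R, R))
    p = np.ones((R, R))
    t[iu, ju] = t[ju, iu] = t_e
    p[iu, ju] = p[ju, iu] = p_e
    return EdgeStatMap(t=t, p=p, df=vals.shape[0] + cvals.shape[0] - 2)


def _null_max_sizes(vals, config, R, iu, ju, control_stack) -> np.ndarray:
    m = vals.shape[0]
    if config.design == "two_sample":
        cvals = stack_to_edges(np.asarray(control_stack, dtype=float))
        pooled = np.vstack([vals, cvals])
        rng = np.random.default_rng(config.seed)
        sizes = np.empty(config.n_perm, dtype=int)
        for b in range(config.n_perm):
            order = rng.permutation(pooled.shape[0])
            s = _two_sample_stats(pooled[order[:m]], pooled[order[m:]], R, iu, ju)
            sizes[b] = _max_from_stat(s, config, R, iu, ju)
        return sizes

    # one-sample: sign flips; |x| is invariant so only the mean moves
    ss = (vals**2).sum(axis=0)
    if config.exhaustive:
        patterns = np.array(list(itertools.product([-1.0, 1.0], repeat=m)))
    else:
        rng = np.random.default_rng(config.seed)
        patterns = rng.choice([-1.0, 1.0], size=(config.n_perm, m))
    sizes = np.empty(patterns.shape[0], dtype=int)
    dead = vals.std(axis=0, ddof=1) < 1e-300
    for b, signs in enumerate(patterns):
        mean = signs @ vals / m
        var = np.maximum(ss / m - mean**2, 0.0) * (m / (m - 1))
        sd_safe = np.where(dead | (var <= 0), 1.0, np.sqrt(var))
        t_e = mean / (sd_safe / np.sqrt(m))
        t_e[dead] = 0.0
        p_e = 2.0 * stats.t.sf(np.abs(t_e), df=m - 1)
        p_e[dead] = 1.0
        sizes[b] = _max_component_size(p_e, config.edge_alpha, R, iu, ju)
    return sizes


def _max_from_stat(stat: EdgeStatMap, config, R, iu, ju) -> int:
    return _max_component_size(stat.p[iu, ju], config.edge_alpha, R, iu, ju)
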