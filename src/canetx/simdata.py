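"""Synthetic case/control omics data with known ground truth.

The generator emulates the latent structure the pipeline assumes: each
group's features follow a multivariate normal with a sparse precision
matrix (an Erdos-Renyi conditional-independence skeleton with partial
correlations of magnitude U(0.2, 0.4)), exponentiated to log-normal
abundances.  Planted effects:

- differential connectivity: edges incident to a chosen node subset are
  rewired to new random partners in the cancer precision matrix;
- differential abundance: a log-scale mean shift delta on a chosen feature
  subset in the cancer group;
- MCAR missingness at a configurable rate;
- toy pathway sets with enriched pathways over-sampled from a hit list.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .dataio import OmicsMatrix
from .pathways import PathwaySet

__all__ = ["SyntheticTruth", "make_ggm_pair", "inject_missing", "make_pathway_fixtures"]

MIN_EIGENVALUE = 0.1


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated case/control pair."""

    precision_cancer: np.ndarray
    precision_control: np.ndarray
    dc_nodes: frozenset
    de_features: frozenset
    delta: float
    edges_control: frozenset
    edges_cancer: frozenset

    def __post_init__(self):
        for om in (self.precision_cancer, self.precision_control):
            if np.linalg.eigvalsh(om).min() <= 0:
                raise ValueError("precision matrices must be positive definite")


def _repair_pd(omega: np.ndarray) -> np.ndarray:
    """Diagonal loading to minimum eigenvalue >= 0.1, then renormalisation
    to unit diagonal (partial-correlation scale)."""
    w = np.linalg.eigvalsh(omega).min()
    if w < MIN_EIGENVALUE:
        omega = omega + (MIN_EIGENVALUE - w) * np.eye(omega.shape[0])
    d = np.sqrt(np.diag(omega))
    return omega / np.outer(d, d)


def _skeleton_precision(p, edges, pcorrs):
    omega = np.eye(p)
    for (i, j), rho in zip(edges, pcorrs):
        omega[i, j] = omega[j, i] = -rho
    return _repair_pd(omega)


def make_ggm_pair(
    p: int,
    n: int,
    *,
    dc_frac: float = 0.0,
    de_frac: float = 0.0,
    delta: float = 1.0,
    edge_prob: float = 0.15,
    seed: int = 0,
    feature_prefix: str = "m",
) -> tuple[OmicsMatrix, OmicsMatrix, SyntheticTruth]:
    """Simulate a matched cancer/control pair from planted sparse GGMs.

    Returns log-normal abundance matrices (``n`` samples per group, ``p``
    features) plus the :class:`SyntheticTruth`.  ``dc_frac * p`` nodes have
    all incident edges rewired to new partners in the cancer precision
    (planting differential connectivity); ``de_frac * p`` features receive
    a log-scale mean shift ``delta`` in the cancer group.
    """
    if p < 5:
        raise ValueError("p must be >= 5")
    if n < 10:
        raise ValueError("n must be >= 10")
    if not 0 <= dc_frac <= 1 or not 0 <= de_frac <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    # control skeleton: Erdos-Renyi over unordered pairs
    edges = [
        (i, j) for i in range(p) for j in range(i + 1, p) if rng.random() < edge_prob
    ]
    signs = rng.choice([-1.0, 1.0], size=len(edges))
    mags = rng.uniform(0.2, 0.4, size=len(edges))
    omega_co = _skeleton_precision(p, edges, signs * mags)

    # cancer skeleton: every edge incident to the planted nodes is rewired
    # to a new random pair elsewhere, so planted nodes lose their
    # connectivity.  Planted nodes are the highest-degree (hub) nodes of
    # the control skeleton, which makes the connectivity change large.
    n_dc = int(round(dc_frac * p))
    if n_dc:
        degree = np.zeros(p, dtype=int)
        for i, j in edges:
            degree[i] += 1
            degree[j] += 1
        jitter = rng.random(p)  # random tie-break among equal degrees
        order = np.lexsort((jitter, -degree))
        dc_nodes = set(order[:n_dc].tolist())
    else:
        dc_nodes = set()
    kept = [e for e in edges if e[0] not in dc_nodes and e[1] not in dc_nodes]
    removed = [e for e in edges if e[0] in dc_nodes or e[1] in dc_nodes]
    new_edges = list(kept)
    new_set = set(kept)
    others = [v for v in range(p) if v not in dc_nodes]
    for _ in removed:
        for _attempt in range(1000):
            a, b = rng.choice(others, size=2, replace=False)
            e = (min(int(a), int(b)), max(int(a), int(b)))
            if e in new_set:
                continue
            new_edges.append(e)
            new_set.add(e)
            break
    signs_ca = rng.choice([-1.0, 1.0], size=len(new_edges))
    mags_ca = rng.uniform(0.2, 0.4, size=len(new_edges))
    omega_ca = (
        _skeleton_precision(p, new_edges, signs_ca * mags_ca) if dc_nodes else omega_co
    )

    n_de = int(round(de_frac * p))
    de_idx = set(rng.choice(p, size=n_de, replace=False).tolist()) if n_de else set()
    shift = np.zeros(p)
    for j in de_idx:
        shift[j] = delta

    def draw(omega, mean_shift):
        # unit marginal variances: partial correlations are scale-invariant,
        # and delta then has Cohen's-d units on the log scale
        cov = np.linalg.inv(omega)
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        z = rng.multivariate_normal(mean_shift, cov, size=n, method="cholesky")
        return np.exp(z)

    features = tuple(f"{feature_prefix}{j}" for j in range(p))
    x_ca = draw(omega_ca, shift)
    x_co = draw(omega_co, np.zeros(p))
    m_ca = OmicsMatrix(
        values=x_ca,
        sample_ids=tuple(f"ca{i}" for i in range(n)),
        feature_ids=features,
        group=("cancer",) * n,
    )
    m_co = OmicsMatrix(
        values=x_co,
        sample_ids=tuple(f"co{i}" for i in range(n)),
        feature_ids=features,
        group=("control",) * n,
    )
    truth = SyntheticTruth(
        precision_cancer=omega_ca,
        precision_control=omega_co,
        dc_nodes=frozenset(features[j] for j in dc_nodes),
        de_features=frozenset(features[j] for j in de_idx),
        delta=float(delta),
        edges_control=frozenset(edges),
        edges_cancer=frozenset(new_edges),
    )
    return m_ca, m_co, truth


def inject_missing(m: OmicsMatrix, rate: float, seed: int = 0) -> OmicsMatrix:
    """Mask cells missing-completely-at-random at the given rate."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return m
    rng = np.random.default_rng(seed)
    mask = rng.random(m.values.shape) < rate
    v = m.values.copy()
    v[mask] = np.nan
    return replace(m, values=v)


def make_pathway_fixtures(
    features,
    n_pathways: int,
    *,
    enriched=(),
    hits=frozenset(),
    size_range: tuple[int, int] = (6, 12),
    seed: int = 0,
) -> PathwaySet:
    """Toy pathway set: random memberships, with the ``enriched`` pathways
    over-sampled from ``hits``; each pathway carries a small connected
    graph over its members (random spanning tree plus chords)."""
    features = list(features)
    hits = set(hits)
    rng = np.random.default_rng(seed)
    names = [f"pathway_{k}" for k in range(n_pathways)]
    unknown = set(enriched) - set(names)
    if unknown:
        raise ValueError(f"enriched names not generated: {sorted(unknown)}")
    pathways, graphs = {}, {}
    non_hits = [f for f in features if f not in hits]
    for name in names:
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(features))
        if name in enriched and hits:
            n_hit = min(len(hits), max(1, int(round(0.8 * size))))
            members = list(rng.choice(sorted(hits), size=n_hit, replace=False))
            pool = [f for f in non_hits if f not in members]
            members += list(rng.choice(pool, size=min(size - n_hit, len(pool)), replace=False))
        else:
            members = list(rng.choice(features, size=size, replace=False))
        pathways[name] = frozenset(members)
        g = nx.Graph()
        order = list(members)
        rng.shuffle(order)
        g.add_nodes_from(order)
        for i in range(1, len(order)):  # random spanning tree
            g.add_edge(order[i], order[int(rng.integers(i))])
        for _ in range(len(order) // 3):  # a few chords
            a, b = rng.choice(order, size=2, replace=False)
            if a != b:
                g.add_edge(a, b)
        graphs[name] = g
    return PathwaySet(pathways=pathways, graphs=graphs)
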