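"""PCLRC association-network inference on shrinkage partial correlations.

The Probabilistic Context Likelihood of Relatedness on Correlations (PCLRC)
wraps the GGM estimator in a resampling loop: at each iteration a fraction
of the samples is drawn without replacement, partial correlations are
estimated, CLR background correction scores every feature pair, and the top
``rank_thr`` fraction of pairs is marked.  Marking frequencies over
``niter`` iterations form the probability matrix P; the association network
keeps the full-data partial correlation r_ij wherever p_ij >= prob_thr
(inclusive boundary) and zero elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import partial_correlations

__all__ = [
    "PCLRCConfig",
    "GENE_DEFAULTS",
    "ProbabilityMatrix",
    "AssociationNetwork",
    "clr_scores",
    "pclrc_probabilities",
    "threshold_network",
    "PCLRC",
    "write_edge_list",
    "read_edge_list",
]


@dataclass(frozen=True)
class PCLRCConfig:
    """Resampling configuration.

    niter : resampling iterations (1000 for metabolite networks, 100 for
        gene networks).
    frac : fraction of samples drawn (without replacement) per iteration.
    rank_thr : fraction of off-diagonal pairs, ranked by CLR score, marked
        per iteration.
    prob_thr : probability cutoff for keeping an edge (0.95 metabolites,
        0.99 genes).
    seed : RNG seed for the subsampling stream.
    """

    niter: int = 1000
    frac: float = 0.75
    rank_thr: float = 0.3
    prob_thr: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.niter < 1:
            raise ValueError("niter must be >= 1")
        if not 0 < self.frac <= 1:
            raise ValueError("frac must lie in (0, 1]")
        if not 0 < self.rank_thr <= 1:
            raise ValueError("rank_thr must lie in (0, 1]")
        if not 0 < self.prob_thr <= 1:
            raise ValueError("prob_thr must lie in (0, 1]")


GENE_DEFAULTS = PCLRCConfig(niter=100, prob_thr=0.99)


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Symmetric matrix of per-pair selection frequencies in [0, 1]."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("p must be square")
        if not np.allclose(p, p.T):
            raise ValueError("p must be symmetric")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("entries must lie in [0, 1]")
        if np.any(np.diag(p) != 0):
            raise ValueError("diagonal must be zero")


@dataclass(frozen=True)
class AssociationNetwork:
    """Thresholded partial-correlation network.

    ``weights[i, j]`` is the full-data partial correlation where the edge
    probability reached the cutoff, zero otherwise; ``prob`` the probability
    matrix; ``config`` the PCLRC configuration used.
    """

    weights: np.ndarray
    node_ids: tuple[str, ...]
    prob: ProbabilityMatrix | None = None
    config: PCLRCConfig | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != len(self.node_ids):
            raise ValueError("one node id per row required")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.size and np.max(np.abs(w)) > 1 + 1e-8:
            raise ValueError("|weights| must be <= 1")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        iu, ju = np.nonzero(np.triu(self.weights, 1))
        for i, j in zip(iu, ju):
            g.add_edge(self.node_ids[i], self.node_ids[j], weight=float(self.weights[i, j]))
        return g


def clr_scores(s: np.ndarray) -> np.ndarray:
    """Context-Likelihood-of-Relatedness background correction.

    Per row i of |s| (off-diagonal entries), z_i(j) = max(0, (|s_ij| -
    mu_i)/sigma_i); the pair score is sqrt(z_i(j)^2 + z_j(i)^2).  Rows with
    zero spread contribute zero.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    a = np.abs(s)
    p = a.shape[0]
    off = ~np.eye(p, dtype=bool)
    mu = np.array([a[i, off[i]].mean() for i in range(p)])
    sd = np.array([a[i, off[i]].std(ddof=0) for i in range(p)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (a - mu[:, None]) / sd[:, None]
    z[~np.isfinite(z)] = 0.0
    z = np.maximum(z, 0.0)
    score = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(score, 0.0)
    return score


def _top_pairs_mask(score: np.ndarray, rank_thr: float) -> np.ndarray:
    """Boolean mask of the top ``rank_thr`` fraction of off-diagonal pairs.

    Pairs tied with the cutoff score are all included (deterministic).
    """
    p = score.shape[0]
    iu, ju = np.triu_indices(p, 1)
    vals = score[iu, ju]
    n_keep = max(1, math.ceil(rank_thr * vals.size))
    if n_keep >= vals.size:
        cutoff = -np.inf
    else:
        cutoff = np.partition(vals, vals.size - n_keep)[vals.size - n_keep]
    keep = vals >= cutoff
    mask = np.zeros((p, p), dtype=bool)
    mask[iu[keep], ju[keep]] = True
    return mask | mask.T


def pclrc_probabilities(x: np.ndarray, cfg: PCLRCConfig) -> ProbabilityMatrix:
    """Edge-selection frequencies over the PCLRC resampling loop."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    m = math.floor(cfg.frac * n)
    if m < 3:
        raise ValueError(f"frac*n = {m} samples per iteration; need >= 3")
    rng = np.random.default_rng(cfg.seed)
    counts = np.zeros((p, p), dtype=float)
    for _ in range(cfg.niter):
        idx = rng.choice(n, size=m, replace=False)
        rho = partial_correlations(x[idx]).rho
        score = clr_scores(rho)
        counts += _top_pairs_mask(score, cfg.rank_thr)
    prob = counts / cfg.niter
    np.fill_diagonal(prob, 0.0)
    return ProbabilityMatrix(p=prob)


def threshold_network(
    prob: ProbabilityMatrix,
    x: np.ndarray,
    cfg: PCLRCConfig,
    *,
    node_ids: tuple[str, ...] | None = None,
) -> AssociationNetwork:
    """Keep full-data partial correlations where p_ij >= prob_thr.

    The probability boundary is inclusive: a pair exactly at the cutoff is
    kept.
    """
    x = np.asarray(x, dtype=float)
    if prob.p.shape[0] != x.shape[1]:
        raise ValueError(
            f"probability matrix is {prob.p.shape[0]} x {prob.p.shape[0]} but "
            f"data has {x.shape[1]} features"
        )
    rho = partial_correlations(x).rho
    w = np.where(prob.p >= cfg.prob_thr, rho, 0.0)
    np.fill_diagonal(w, 0.0)
    if node_ids is None:
        node_ids = tuple(f"f{j}" for j in range(x.shape[1]))
    return AssociationNetwork(weights=w, node_ids=node_ids, prob=prob, config=cfg)


class PCLRC:
    """Resampled association-network model for one group's data matrix.

    statsmodels-style entry point: construct from a samples x features
    matrix (or :class:`~canetx.dataio.OmicsMatrix`), call :meth:`fit` to run
    the resampling loop and thresholding, obtain an
    :class:`AssociationNetwork`.
    """

    def __init__(self, x, config: PCLRCConfig | None = None, node_ids=None):
        from .dataio import OmicsMatrix

        if isinstance(x, OmicsMatrix):
            node_ids = x.feature_ids
            x = x.values
        self.x = np.asarray(x, dtype=float)
        if node_ids is None:
            node_ids = tuple(f"f{j}" for j in range(self.x.shape[1]))
        self.node_ids = tuple(node_ids)
        self.config = config or PCLRCConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: PCLRCConfig | None = None) -> "PCLRC":
        return cls(df.to_numpy(dtype=float), config=config, node_ids=tuple(map(str, df.columns)))

    def fit(self) -> AssociationNetwork:
        prob = pclrc_probabilities(self.x, self.config)
        return threshold_network(prob, self.x, self.config, node_ids=self.node_ids)


def write_edge_list(net: AssociationNetwork, path) -> None:
    """Weighted edge list TSV: nodeA, nodeB, weight, probability."""
    iu, ju = np.nonzero(np.triu(net.weights, 1))
    rows = []
    for i, j in zip(iu, ju):
        prob = float(net.prob.p[i, j]) if net.prob is not None else float("nan")
        rows.append(
            (net.node_ids[i], net.node_ids[j], float(net.weights[i, j]), prob)
        )
    pd.DataFrame(rows, columns=["nodeA", "nodeB", "weight", "probability"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path, node_ids=None) -> AssociationNetwork:
    """Read a weighted edge-list TSV back into an AssociationNetwork."""
    df = pd.read_csv(path, sep="\t", dtype={"nodeA": str, "nodeB": str})
    if node_ids is None:
        node_ids = sorted(set(df["nodeA"]) | set(df["nodeB"]))
    node_ids = tuple(node_ids)
    idx = {n: i for i, n in enumerate(node_ids)}
    w = np.zeros((len(node_ids), len(node_ids)))
    for _, row in df.iterrows():
        i, j = idx[row["nodeA"]], idx[row["nodeB"]]
        w[i, j] = w[j, i] = row["weight"]
    return AssociationNetwork(weights=w, node_ids=node_ids)
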