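"""Differential node connectivity between matched cancer/control networks.

Observed statistic: Delta_i = chi_i(cancer) - chi_i(control), with chi the
absolute-weight node connectivity of the PCLRC-thresholded networks.  The
null is built by independently permuting every feature column within each
group matrix (destroying inter-feature association, preserving marginals),
re-inferring both networks, and recording the permuted Delta_i,k; the
empirical p-value is

    p_i = (1 + #{|Delta_i,k| > |Delta_i|}) / k

(by default the null is folded to absolute values; ``null="signed"``
compares the signed permuted deltas as printed in some formulations).
Benjamini-Hochberg adjustment is applied across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import OmicsMatrix
from .netinfer import AssociationNetwork, PCLRCConfig, pclrc_probabilities, threshold_network
from .topology import node_connectivity

__all__ = [
    "DifferentialConnectivityResult",
    "differential_connectivity",
    "adjust_pvalues",
    "empirical_pvalues",
    "permutation_null",
    "DifferentialConnectivityTest",
]


@dataclass(frozen=True)
class DifferentialConnectivityResult:
    """Per-node differential connectivity with its permutation null."""

    node_ids: tuple[str, ...]
    chi_cancer: np.ndarray
    chi_control: np.ndarray
    delta: np.ndarray
    null_deltas: np.ndarray  # shape (k, n_nodes)
    p: np.ndarray
    p_adj: np.ndarray
    k: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.node_ids),
                "chi_cancer": self.chi_cancer,
                "chi_control": self.chi_control,
                "delta": self.delta,
                "p": self.p,
                "p_adj": self.p_adj,
            }
        ).set_index("node")

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [n for n, q in zip(self.node_ids, self.p_adj) if q < alpha]


def differential_connectivity(
    net_cancer: AssociationNetwork, net_control: AssociationNetwork
) -> np.ndarray:
    """Delta_i = chi_i(cancer) - chi_i(control); requires identical node sets."""
    if net_cancer.node_ids != net_control.node_ids:
        diff = set(net_cancer.node_ids) ^ set(net_control.node_ids)
        raise ValueError(f"node sets differ (symmetric difference: {sorted(diff)})")
    return node_connectivity(net_cancer).chi - node_connectivity(net_control).chi


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method != "BH":
        raise ValueError(f"unknown adjustment method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(1.0, adj)
    return out


def empirical_pvalues(delta, null_deltas, *, null: str = "absolute") -> np.ndarray:
    """p_i = (1 + #{null exceedances of |Delta_i|}) / k.

    ``null_deltas`` has one row per permutation; with ``null="absolute"``
    the permuted deltas are folded before the strict comparison, with
    ``"signed"`` they are compared as-is.
    """
    delta = np.asarray(delta, dtype=float)
    null_deltas = np.atleast_2d(np.asarray(null_deltas, dtype=float))
    if null_deltas.shape[1] != delta.size:
        raise ValueError("null_deltas must have one column per node")
    k = null_deltas.shape[0]
    null_cmp = np.abs(null_deltas) if null == "absolute" else null_deltas
    exceed = (null_cmp > np.abs(delta)[None, :]).sum(axis=0)
    return (1.0 + exceed) / k


def _infer(x: np.ndarray, cfg: PCLRCConfig, node_ids) -> AssociationNetwork:
    prob = pclrc_probabilities(x, cfg)
    return threshold_network(prob, x, cfg, node_ids=node_ids)


def permutation_null(
    x_cancer: OmicsMatrix | np.ndarray,
    x_control: OmicsMatrix | np.ndarray,
    *,
    k: int = 1000,
    net_cfg: PCLRCConfig | None = None,
    perm_niter: int = 50,
    seed: int = 0,
    null: str = "absolute",
    max_runs: int = 2_000_000,
) -> DifferentialConnectivityResult:
    """Column-permutation null for differential node connectivity.

    Every permutation re-runs the full network-inference pipeline on both
    group matrices with ``perm_niter`` PCLRC iterations (the observed
    networks use ``net_cfg.niter``); ``k * perm_niter`` must stay within
    ``max_runs`` GGM evaluations per group.
    """
    node_ids, xa = _unpack(x_cancer)
    node_ids_b, xb = _unpack(x_control)
    if node_ids != node_ids_b:
        raise ValueError("feature sets of the two groups differ")
    if k < 1:
        raise ValueError("k must be >= 1")
    if null not in ("absolute", "signed"):
        raise ValueError("null must be 'absolute' or 'signed'")
    net_cfg = net_cfg or PCLRCConfig()
    if k * perm_niter > max_runs:
        raise ValueError(
            f"k * perm_niter = {k * perm_niter} exceeds the compute budget "
            f"({max_runs}); reduce perm_niter for permutation-time inference"
        )

    rng = np.random.default_rng(seed)
    obs_cfg_a = PCLRCConfig(**{**vars(net_cfg), "seed": int(rng.integers(2**31))})
    obs_cfg_b = PCLRCConfig(**{**vars(net_cfg), "seed": int(rng.integers(2**31))})
    net_a = _infer(xa, obs_cfg_a, node_ids)
    net_b = _infer(xb, obs_cfg_b, node_ids)
    delta = differential_connectivity(net_a, net_b)
    chi_a = node_connectivity(net_a).chi
    chi_b = node_connectivity(net_b).chi

    p_features = xa.shape[1]
    null_deltas = np.empty((k, p_features))
    for it in range(k):
        pa = _permute_columns(xa, rng)
        pb = _permute_columns(xb, rng)
        cfg_a = PCLRCConfig(
            **{**vars(net_cfg), "niter": perm_niter, "seed": int(rng.integers(2**31))}
        )
        cfg_b = PCLRCConfig(
            **{**vars(net_cfg), "niter": perm_niter, "seed": int(rng.integers(2**31))}
        )
        na = _infer(pa, cfg_a, node_ids)
        nb = _infer(pb, cfg_b, node_ids)
        null_deltas[it] = differential_connectivity(na, nb)

    p = empirical_pvalues(delta, null_deltas, null=null)
    p_adj = adjust_pvalues(np.minimum(p, 1.0), "BH")
    return DifferentialConnectivityResult(
        node_ids=node_ids,
        chi_cancer=chi_a,
        chi_control=chi_b,
        delta=delta,
        null_deltas=null_deltas,
        p=p,
        p_adj=p_adj,
        k=k,
    )


def _unpack(x) -> tuple[tuple[str, ...], np.ndarray]:
    if isinstance(x, OmicsMatrix):
        return x.feature_ids, x.values
    x = np.asarray(x, dtype=float)
    return tuple(f"f{j}" for j in range(x.shape[1])), x


def _permute_columns(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = x[rng.permutation(x.shape[0]), j]
    return out


class DifferentialConnectivityTest:
    """Model object: matched case/control matrices -> permutation test.

    Construct with the two group matrices (``OmicsMatrix`` or arrays with
    matching feature order) and a :class:`PCLRCConfig`; :meth:`fit` runs
    the observed inference plus ``k`` column-permutation re-inferences and
    returns a :class:`DifferentialConnectivityResult`.
    """

    def __init__(
        self,
        x_cancer,
        x_control,
        *,
        net_cfg: PCLRCConfig | None = None,
        k: int = 1000,
        perm_niter: int = 50,
        null: str = "absolute",
    ):
        self.x_cancer = x_cancer
        self.x_control = x_control
        self.net_cfg = net_cfg or PCLRCConfig()
        self.k = k
        self.perm_niter = perm_niter
        self.null = null

    def fit(self, seed: int = 0) -> DifferentialConnectivityResult:
        return permutation_null(
            self.x_cancer,
            self.x_control,
            k=self.k,
            net_cfg=self.net_cfg,
            perm_niter=self.perm_niter,
            seed=seed,
            null=self.null,
        )
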