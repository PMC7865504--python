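"""Cross-analysis comparison: PCA, UPGMA dendrograms, cophenetic
correlation, and LOOCV logistic classification of network topology.

Analyses (pathway-impact matrices, topology tables) are compared by (i)
PCA on unit-variance-scaled columns, (ii) average-linkage hierarchical
clustering of the first three principal components, (iii) pairwise
dendrogram agreement via the cophenetic correlation after pruning to the
common leaf set, and (iv) leave-one-out cross-validated univariate
logistic regression quantifying how well a single topology measure
separates cancer from control networks (ROC AUC with a DeLong interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy import stats

__all__ = [
    "Dendrogram",
    "AUCResult",
    "pca_scores",
    "collapse_centroids",
    "hcluster",
    "prune_to_common",
    "cophenetic_correlation",
    "mann_whitney_auc",
    "loocv_logistic_auc",
]


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        z = np.asarray(self.linkage, dtype=float)
        object.__setattr__(self, "linkage", z)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("leaf labels must be unique")
        if z.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")
        heights = z[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Leaf x leaf matrix of merge heights at which pairs first join."""
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=list(self.labels), columns=list(self.labels))

    def to_newick(self) -> str:
        """Newick string; branch lengths are half the merge-height gaps, so
        leaf-to-leaf path lengths equal cophenetic distances."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            bl = (parent_height - node.dist) / 2.0
            if node.is_leaf():
                return f"{self.labels[node.id]}:{bl:.6g}"
            inner = f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
            return f"{inner}:{bl:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


@dataclass(frozen=True)
class AUCResult:
    """LOOCV classification result for one topology measure."""

    measure: str
    auc: float
    heldout_probs: np.ndarray
    labels: np.ndarray
    ci_low: float
    ci_high: float
    raw_auc: float

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")


def pca_scores(m, ncomp: int = 3, *, return_model: bool = False):
    """Scores of the first ``ncomp`` principal components.

    Columns are standardised to zero mean / unit variance (zero-variance
    columns dropped with a warning); the SVD sign convention fixes each
    component so that its largest-|loading| entry is positive.
    """
    import warnings

    df = pd.DataFrame(m) if not isinstance(m, pd.DataFrame) else m
    x = df.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)")
        x = x[:, keep]
        sd = sd[keep]
    xs = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if ncomp > rank:
        raise ValueError(f"ncomp = {ncomp} exceeds matrix rank {rank}")
    # deterministic signs: largest-|loading| entry of each component positive
    for k in range(ncomp):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u[:, :ncomp] * s[:ncomp]
    out = pd.DataFrame(
        scores, index=df.index, columns=[f"PC{k + 1}" for k in range(ncomp)]
    )
    if return_model:
        eigvals = s**2 / (x.shape[0] - 1)
        return out, {"singular_values": s, "eigenvalues": eigvals, "loadings": vt}
    return out


def collapse_centroids(scores, labels) -> tuple[np.ndarray, list[str]]:
    """Replace rows sharing a label by their coordinate-wise mean."""
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    seen: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        seen.setdefault(lab, []).append(i)
    out = np.vstack([scores[rows].mean(axis=0) for rows in seen.values()])
    return out, list(seen.keys())


def hcluster(scores, labels) -> Dendrogram:
    """UPGMA (average linkage) on Euclidean distances between rows."""
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels; collapse to centroids first")
    z = hierarchy.linkage(pdist(scores), method="average")
    return Dendrogram(linkage=z, labels=tuple(labels))


def prune_to_common(d1: Dendrogram, d2: Dendrogram) -> tuple[Dendrogram, Dendrogram]:
    """Restrict both dendrograms to their shared leaves.

    Pruning preserves the cophenetic distances among surviving leaves: the
    induced subtree is rebuilt by average linkage on the restricted
    cophenetic matrix, which reproduces the original merge heights exactly
    because cophenetic distances are ultrametric.
    """
    common = [lab for lab in d1.labels if lab in set(d2.labels)]
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} shared leaves; cophenetic comparison needs >= 3"
        )
    return _restrict(d1, common), _restrict(d2, common)


def _restrict(d: Dendrogram, leaves: list[str]) -> Dendrogram:
    if list(d.labels) == leaves:
        return d
    c = d.cophenetic_matrix().loc[leaves, leaves].to_numpy()
    z = hierarchy.linkage(squareform(c, checks=False), method="average")
    return Dendrogram(linkage=z, labels=tuple(leaves))


def cophenetic_correlation(d1: Dendrogram, d2: Dendrogram) -> float:
    """Pearson correlation of the two cophenetic-distance vectors."""
    if set(d1.labels) != set(d2.labels):
        raise ValueError("leaf sets differ; prune to the common set first")
    order = list(d1.labels)
    c1 = squareform(d1.cophenetic_matrix().loc[order, order].to_numpy(), checks=False)
    c2 = squareform(d2.cophenetic_matrix().loc[order, order].to_numpy(), checks=False)
    if np.std(c1) == 0 or np.std(c2) == 0:
        raise ValueError("constant cophenetic distances; correlation undefined")
    return float(np.corrcoef(c1, c2)[0, 1])


# ---------------------------------------------------------------------------
# LOOCV logistic classification of topology measures


def mann_whitney_auc(scores, labels) -> float:
    """ROC AUC of ``scores`` for binary ``labels`` (ties count 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def _logistic_irls(x, y, *, max_iter: int = 100, tol: float = 1e-8):
    """Unregularised univariate logistic regression (intercept + slope).

    On perfect separation the deviance never converges; the last iterate is
    returned — held-out probabilities then saturate monotonely, so the ROC
    ordering remains well-defined.
    """
    n = x.size
    design = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    dev_old = np.inf
    for _ in range(max_iter):
        eta = design @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        wx = design * w[:, None]
        try:
            beta = np.linalg.solve(design.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            break
        with np.errstate(divide="ignore"):
            dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        if abs(dev_old - dev) < tol * (abs(dev) + 1.0):
            break
        dev_old = dev
    return beta


def _delong_ci(pos, neg, auc: float, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance of the AUC and normal-approximation interval."""
    m, n = pos.size, neg.size
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / n for p in pos])
    v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return float(max(0.0, auc - zq * se)), float(min(1.0, auc + zq * se))


def loocv_logistic_auc(
    profiles: pd.DataFrame, labels, measure: str, *, method: str = "pair"
) -> AUCResult:
    """Leave-one-out cross-validated univariate logistic ROC AUC.

    ``method="pair"`` (default) is leave-pair-out: every cancer/control
    pair is held out together, a logistic model (intercept + the measure)
    is fitted on the remaining networks, and the pair is scored by that one
    model; the AUC is the fraction of correctly ordered pairs (ties 0.5).
    Comparing both members of a pair under the same refit removes the
    pessimistic bias that arises when held-out probabilities produced by
    different leave-one-out models are ranked against each other, which for
    weakly informative measures can push the AUC far below the resubstitution
    value.  ``method="single"`` is that plain variant: each network's
    probability comes from the model fitted on the other n-1, and the AUC
    is the Mann-Whitney statistic of the held-out probabilities.

    ``heldout_probs`` always carries the per-network leave-one-out
    probabilities; ``raw_auc`` is the Mann-Whitney AUC of the measure
    values themselves.  The 95% interval is DeLong's, computed from the
    pair-win matrix (pair method) or the held-out probabilities.
    """
    x = profiles[measure].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in measure {measure!r}")
    y = _binary_labels(labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 networks per class")
    n = x.size
    heldout = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta = _logistic_irls(x[mask], y[mask].astype(float))
        eta = np.clip(beta[0] + beta[1] * x[i], -700, 700)
        heldout[i] = 1.0 / (1.0 + np.exp(-eta))

    if method == "pair":
        pos_idx = np.where(y)[0]
        neg_idx = np.where(~y)[0]
        wins = np.empty((pos_idx.size, neg_idx.size))
        for a, i in enumerate(pos_idx):
            for b, j in enumerate(neg_idx):
                mask = np.ones(n, dtype=bool)
                mask[[i, j]] = False
                beta = _logistic_irls(x[mask], y[mask].astype(float))
                si = beta[0] + beta[1] * x[i]
                sj = beta[0] + beta[1] * x[j]
                wins[a, b] = 1.0 if si > sj else (0.5 if si == sj else 0.0)
        auc = float(wins.mean())
        ci_low, ci_high = _delong_ci_from_structural(wins, auc)
    elif method == "single":
        auc = mann_whitney_auc(heldout, y)
        ci_low, ci_high = _delong_ci(heldout[y], heldout[~y], auc)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AUCResult(
        measure=measure,
        auc=auc,
        heldout_probs=heldout,
        labels=y,
        ci_low=ci_low,
        ci_high=ci_high,
        raw_auc=mann_whitney_auc(x, y),
    )


def _delong_ci_from_structural(wins: np.ndarray, auc: float, level: float = 0.95):
    """DeLong interval directly from a positives x negatives win matrix."""
    m, n = wins.shape
    v10 = wins.mean(axis=1)
    v01 = wins.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return float(max(0.0, auc - zq * se)), float(min(1.0, auc + zq * se))


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    vals = set(map(str, arr))
    if vals <= {"cancer", "control"}:
        return np.array([str(v) == "cancer" for v in arr])
    if vals <= {"0", "1"}:
        return arr.astype(int).astype(bool)
    raise ValueError(f"cannot interpret labels {sorted(vals)}")
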