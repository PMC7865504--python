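"""Moderated-t differential abundance / expression analysis.

Per feature, the two-group contrast (cancer - control) on log-scale data is
fitted by least squares; residual variances are shrunk toward a common
prior by empirical Bayes.  The prior (d0, s0^2) is estimated from the
marginal distribution of the log residual variances by closed-form moment
matching on the digamma/trigamma scale (Smyth 2004); the posterior variance

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

yields the moderated t with d0 + d_g degrees of freedom.  p-values are
adjusted with Benjamini-Hochberg for metabolites or the stricter Bonferroni
for genome-wide transcript panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .dataio import OmicsMatrix
from .diffnet import adjust_pvalues

__all__ = [
    "DifferentialExpressionResult",
    "moderated_ttest",
    "ModeratedTTest",
    "fit_variance_prior",
]


@dataclass(frozen=True)
class DifferentialExpressionResult:
    feature_ids: tuple[str, ...]
    logfc: np.ndarray
    t_mod: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    d0: float
    s0_sq: float
    f_stat: np.ndarray
    lods: np.ndarray
    df_total: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.feature_ids),
                "logfc": self.logfc,
                "t": self.t_mod,
                "p": self.p,
                "p_adj": self.p_adj,
                "F": self.f_stat,
                "B": self.lods,
            }
        ).set_index("feature")

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [f for f, q in zip(self.feature_ids, self.p_adj) if q < alpha]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment estimation of the scaled inverse-chi-square variance prior.

    Returns (d0, s0_sq); d0 = inf when the log-variances show no excess
    spread beyond sampling noise (all shrink to the common value).
    Zero sample variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero")
    z = np.log(s2[ok])
    dfo = df[ok]
    if np.allclose(z, z[0], atol=1e-12):
        # degenerate: all variances identical — the common value is exact
        return np.inf, float(s2[ok][0])
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = np.sum((e - emean) ** 2) / (n - 1.0)
    evar -= np.mean(special.polygamma(1, dfo / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def _var_prior_coef(
    t: np.ndarray,
    stdev_unscaled: float,
    df_total: np.ndarray,
    proportion: float,
    v0_lim: tuple[float, float],
) -> float:
    """Prior variance of the contrast for the log-odds, from the top
    ``proportion`` of |t| (mixture moment matching), clamped to ``v0_lim``."""
    ngenes = t.size
    ntarget = int(np.ceil(proportion / 2.0 * ngenes))
    if ntarget < 1:
        return v0_lim[0]
    p = max(ntarget / ngenes, proportion)
    at = np.abs(t)
    maxdf = float(np.max(df_total))
    order = np.argsort(-at)[:ntarget]
    tt = at[order]
    v1 = stdev_unscaled**2
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tt, maxdf)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, maxdf)
        v0[pos] = v1 * ((tt[pos] / qtarget) ** 2 - 1.0)
    v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(np.mean(v0))


def moderated_ttest(
    x_cancer: OmicsMatrix | np.ndarray,
    x_control: OmicsMatrix | np.ndarray,
    *,
    adjust: str = "BH",
    prior_df: float | None = None,
    lods_proportion: float = 0.01,
) -> DifferentialExpressionResult:
    """Empirical-Bayes moderated two-group t-test per feature.

    ``prior_df`` overrides the estimated prior degrees of freedom d0
    (0 disables moderation, recovering the classical pooled t).  ``adjust``
    is ``"BH"`` or ``"bonferroni"``.
    """
    fa, xa = _unpack(x_cancer)
    fb, xb = _unpack(x_control)
    if fa != fb:
        raise ValueError("feature sets of the two groups differ")
    na, nb = xa.shape[0], xb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    logfc = xa.mean(axis=0) - xb.mean(axis=0)
    dg = float(na + nb - 2)
    rss = ((xa - xa.mean(axis=0)) ** 2).sum(axis=0) + ((xb - xb.mean(axis=0)) ** 2).sum(axis=0)
    s2 = rss / dg
    if np.all(s2 == 0):
        raise ValueError("zero residual variance for every feature")

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, dg)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.exp(np.mean(np.log(s2[s2 > 0])))) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = np.full_like(s2, d0 + dg)

    su = np.sqrt(1.0 / na + 1.0 / nb)  # unscaled stdev of the contrast
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(s2_post) * su)
    t[~np.isfinite(t)] = 0.0
    finite_df = np.isfinite(df_total)
    p = np.empty_like(t)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t[~finite_df]))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p_adj = adjust_pvalues(p, adjust)

    f_stat = t**2
    # contrast-coefficient prior bounded to standard deviations in [0.1, 4]
    # relative to the variance prior
    v0_lim = (0.1**2 / s0_sq, 4.0**2 / s0_sq) if s0_sq > 0 else (1e-4, 16.0)
    v0 = _var_prior_coef(t, su, np.where(finite_df, df_total, 1e6), lods_proportion, v0_lim)
    rr = (su**2 + v0) / su**2
    t2 = t**2
    dft = np.where(finite_df, df_total, 1e6)
    kernel = (1.0 + dft) / 2.0 * np.log((t2 + dft) / (t2 / rr + dft))
    lods = np.log(lods_proportion / (1.0 - lods_proportion)) - np.log(rr) / 2.0 + kernel

    return DifferentialExpressionResult(
        feature_ids=fa,
        logfc=logfc,
        t_mod=t,
        p=p,
        p_adj=p_adj,
        d0=d0,
        s0_sq=s0_sq,
        f_stat=f_stat,
        lods=lods,
        df_total=df_total,
    )


def _unpack(x) -> tuple[tuple[str, ...], np.ndarray]:
    if isinstance(x, OmicsMatrix):
        return x.feature_ids, x.values
    x = np.asarray(x, dtype=float)
    return tuple(f"f{j}" for j in range(x.shape[1])), x


class ModeratedTTest:
    """Model object for the two-group moderated t; ``fit()`` returns a
    :class:`DifferentialExpressionResult` with a ``summary()`` table."""

    def __init__(self, x_cancer, x_control, *, adjust: str = "BH"):
        self.x_cancer = x_cancer
        self.x_control = x_control
        self.adjust = adjust

    @classmethod
    def from_matrix(cls, m: OmicsMatrix, *, adjust: str = "BH") -> "ModeratedTTest":
        """Split one labelled matrix into its cancer/control groups."""
        return cls(m.subset_group("cancer"), m.subset_group("control"), adjust=adjust)

    def fit(self, **kwargs) -> DifferentialExpressionResult:
        return moderated_ttest(self.x_cancer, self.x_control, adjust=self.adjust, **kwargs)
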