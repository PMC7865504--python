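"""Reading, harmonizing, filtering, imputing and transforming omics tables.

The analysis-ready object is :class:`OmicsMatrix`: a samples x features
abundance (or expression) table with per-sample case/control labels.  The
preparation pipeline applied to every data set is fixed:

    consolidate duplicates -> missingness filter -> kNN imputation -> log

Missing cells are represented as NaN in memory; on disk both the empty
string and ``NA`` are accepted (``NA`` is written).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("cancer", "control")
MODALITIES = ("metabolomics", "transcriptomics")

__all__ = [
    "OmicsMatrix",
    "AliasTable",
    "load_omics_table",
    "write_omics_table",
    "harmonize_names",
    "consolidate_duplicates",
    "filter_missingness",
    "impute_knn",
    "log_transform",
    "variance_filter_genes",
    "prepare",
]


@dataclass(frozen=True)
class OmicsMatrix:
    """Samples x features abundance table with group labels.

    Parameters
    ----------
    values : (n_samples, n_features) float array; NaN marks missing cells.
    sample_ids, feature_ids : row / column identifiers.
    group : per-sample label, each in ``{"cancer", "control"}``.
    modality : ``"metabolomics"`` or ``"transcriptomics"``.
    log_transformed : whether values are on natural-log scale.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    group: tuple[str, ...]
    modality: str = "metabolomics"
    log_transformed: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "group", tuple(self.group))
        if v.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if v.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {v.shape} inconsistent with {len(self.sample_ids)} "
                f"samples / {len(self.feature_ids)} features"
            )
        if len(self.group) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def subset_group(self, group: str) -> "OmicsMatrix":
        """Rows belonging to one group, as a new matrix."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        keep = [i for i, g in enumerate(self.group) if g == group]
        return replace(
            self,
            values=self.values[keep],
            sample_ids=tuple(self.sample_ids[i] for i in keep),
            group=tuple(self.group[i] for i in keep),
        )


@dataclass(frozen=True)
class AliasTable:
    """Feature-identifier alias map: (namespace, id) -> canonical name."""

    entries: tuple[tuple[str, str, str], ...]  # (namespace, source_id, canonical)

    def __post_init__(self):
        entries = tuple((str(a), str(b), str(c)) for a, b, c in self.entries)
        object.__setattr__(self, "entries", entries)
        keys = [(ns, sid) for ns, sid, _ in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (namespace, source_id) pairs in alias table")

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, namespace: str, source_id: str) -> str | None:
        for ns, sid, canon in self.entries:
            if ns == namespace and sid == source_id:
                return canon
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasTable":
        df = pd.read_csv(path, sep="\t", dtype=str, header=0)
        if df.shape[1] != 3:
            raise ValueError("alias table must have exactly three columns")
        return cls(tuple(map(tuple, df.itertuples(index=False))))


_MISSING_MARKERS = {"", "NA", "nan", "NaN"}


def load_omics_table(
    path: str | Path,
    *,
    orientation: str = "features_in_columns",
    group_map: Mapping[str, str],
    modality: str = "metabolomics",
    sep: str = "\t",
    log_transformed: bool = False,
) -> OmicsMatrix:
    """Read a delimited abundance table into an :class:`OmicsMatrix`.

    ``orientation`` declares whether features run along columns (rows are
    samples) or along rows.  Empty cells and ``NA`` are read as missing;
    any other non-numeric cell is an error.  Every sample must appear in
    ``group_map``.
    """
    if orientation not in ("features_in_rows", "features_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if orientation == "features_in_rows":
        df = df.T
    sample_ids = [str(s) for s in df.index]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids in {path}")
    missing_from_map = [s for s in sample_ids if s not in group_map]
    if missing_from_map:
        raise ValueError(f"samples absent from group map: {missing_from_map}")

    def _cell(x: str) -> float:
        x = x.strip()
        if x in _MISSING_MARKERS:
            return np.nan
        try:
            return float(x)
        except ValueError:
            raise ValueError(f"non-numeric cell {x!r} in {path}") from None

    values = df.map(_cell).to_numpy(dtype=float)
    return OmicsMatrix(
        values=values,
        sample_ids=tuple(sample_ids),
        feature_ids=tuple(str(f) for f in df.columns),
        group=tuple(group_map[s] for s in sample_ids),
        modality=modality,
        log_transformed=log_transformed,
    )


def write_omics_table(m: OmicsMatrix, path: str | Path, *, sep: str = "\t") -> None:
    """Write samples x features TSV; missing cells become ``NA``."""
    m.to_frame().to_csv(path, sep=sep, na_rep="NA")


def harmonize_names(m: OmicsMatrix, aliases: AliasTable) -> OmicsMatrix:
    """Rename features to canonical names by majority vote over alias matches.

    A feature id may carry several namespace-qualified identifiers separated
    by ``;`` (e.g. ``"kegg:C00031;hmdb:HMDB0000122"``).  Each identifier that
    matches the alias table casts one vote for its canonical name; the
    majority wins, ties break to the lexicographically smallest canonical
    name.  Features with no matching identifier keep their original name.
    """
    if len(aliases) == 0:
        warnings.warn("empty alias table: feature names left unchanged")
        return m
    lut = {(ns, sid): canon for ns, sid, canon in aliases.entries}
    new_names = []
    for fid in m.feature_ids:
        votes: dict[str, int] = {}
        for token in str(fid).split(";"):
            token = token.strip()
            if ":" in token:
                ns, sid = token.split(":", 1)
                canon = lut.get((ns.strip(), sid.strip()))
            else:
                canon = None
            if canon is not None:
                votes[canon] = votes.get(canon, 0) + 1
        if votes:
            top = max(votes.values())
            new_names.append(min(n for n, c in votes.items() if c == top))
        else:
            new_names.append(fid)
    return replace(m, feature_ids=tuple(new_names))


def consolidate_duplicates(m: OmicsMatrix) -> OmicsMatrix:
    """Collapse features sharing an identifier to their per-sample mean.

    Missing values are excluded from each mean; a cell missing in every
    duplicate stays missing.  First-occurrence order is preserved.
    """
    seen: dict[str, list[int]] = {}
    for j, fid in enumerate(m.feature_ids):
        seen.setdefault(fid, []).append(j)
    if all(len(cols) == 1 for cols in seen.values()):
        return m
    out = np.empty((m.n_samples, len(seen)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        for k, cols in enumerate(seen.values()):
            out[:, k] = np.nanmean(m.values[:, cols], axis=1)
    return replace(m, values=out, feature_ids=tuple(seen.keys()))


def filter_missingness(m: OmicsMatrix, max_frac: float = 0.10) -> OmicsMatrix:
    """Drop features whose missing fraction strictly exceeds ``max_frac``."""
    if not 0.0 <= max_frac <= 1.0:
        raise ValueError("max_frac must lie in [0, 1]")
    frac = np.isnan(m.values).mean(axis=0)
    keep = frac <= max_frac + 1e-12
    if not keep.any():
        raise ValueError(
            f"all features exceed the {max_frac:.0%} missingness threshold"
        )
    if keep.all():
        return m
    return replace(
        m,
        values=m.values[:, keep],
        feature_ids=tuple(f for f, k in zip(m.feature_ids, keep) if k),
    )


def impute_knn(m: OmicsMatrix, k: int = 10, *, min_shared: int = 3) -> OmicsMatrix:
    """Nearest-neighbour-averaging imputation of missing cells.

    For each feature with missing values, candidate neighbour features are
    ranked by Euclidean distance computed over the samples observed in both
    (scaled to the number of shared samples); candidates sharing fewer than
    ``min_shared`` observed samples are excluded.  Each missing cell is the
    mean of the ``k`` nearest neighbours observed in that sample; if no
    neighbour is available the feature mean is used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = m.values.copy()
    nan_mask = np.isnan(x)
    if not nan_mask.any():
        return m
    obs = ~nan_mask
    feature_means = np.array(
        [np.nanmean(x[:, j]) if obs[:, j].any() else np.nan for j in range(x.shape[1])]
    )
    out = x.copy()
    incomplete = np.where(nan_mask.any(axis=0))[0]
    for j in incomplete:
        # distance from feature j to every other feature over shared samples
        dists = np.full(x.shape[1], np.inf)
        for l in range(x.shape[1]):
            if l == j:
                continue
            shared = obs[:, j] & obs[:, l]
            ns = int(shared.sum())
            if ns < min_shared:
                continue
            d = x[shared, j] - x[shared, l]
            dists[l] = np.sqrt(np.dot(d, d) / ns)
        order = np.argsort(dists, kind="stable")
        order = order[np.isfinite(dists[order])]
        for i in np.where(nan_mask[:, j])[0]:
            donors = [l for l in order if obs[i, l]][:k]
            if donors:
                out[i, j] = x[i, donors].mean()
            else:
                out[i, j] = feature_means[j]
    if np.isnan(out).any():
        raise ValueError("imputation left missing cells (all-missing feature?)")
    return replace(m, values=out)


def log_transform(m: OmicsMatrix, *, offset: float | None = None) -> OmicsMatrix:
    """Natural-log transform strictly positive abundances.

    ``offset`` is added to every value first when configured; without it any
    non-positive value is an error naming the offending features.
    """
    if m.log_transformed:
        raise ValueError("matrix is already log-transformed")
    v = m.values + (offset or 0.0)
    if np.nanmin(v) <= 0:
        bad = [
            f
            for f, col in zip(m.feature_ids, v.T)
            if np.nanmin(col) <= 0
        ]
        raise ValueError(
            f"non-positive values in features {bad[:10]}; configure an offset"
        )
    return replace(m, values=np.log(v), log_transformed=True)


def variance_filter_genes(matrices: Sequence[OmicsMatrix]) -> list[str]:
    """Select highly variable genes shared by all transcriptomics matrices.

    Per-matrix gene variances are log-transformed (to normalise them), then
    one mean and standard deviation are computed over the pooled
    log-variances of the shared genes across all matrices; genes whose
    log-variance exceeds mean + 1 SD in the pooled distribution are selected.
    A gene must be present in every matrix to be eligible.
    """
    if not matrices:
        raise ValueError("at least one matrix required")
    common: set[str] = set(matrices[0].feature_ids)
    for m in matrices[1:]:
        common &= set(m.feature_ids)
    if not common:
        raise ValueError("no genes shared by all matrices")
    common_sorted = [f for f in matrices[0].feature_ids if f in common]
    logvar = {}  # (matrix index, gene) -> log variance
    pooled = []
    for mi, m in enumerate(matrices):
        idx = {f: j for j, f in enumerate(m.feature_ids)}
        for g in common_sorted:
            v = np.var(m.values[:, idx[g]], ddof=1)
            if v <= 0:
                lv = -np.inf
            else:
                lv = np.log(v)
            logvar[(mi, g)] = lv
            if np.isfinite(lv):
                pooled.append(lv)
    pooled = np.asarray(pooled)
    cut = pooled.mean() + pooled.std(ddof=1)
    selected = []
    for g in common_sorted:
        lvs = [logvar[(mi, g)] for mi in range(len(matrices))]
        if np.mean(lvs) > cut:
            selected.append(g)
    if not selected:
        raise ValueError("variance filter selected no genes")
    return selected


def prepare(
    m: OmicsMatrix,
    *,
    aliases: AliasTable | None = None,
    max_missing: float = 0.10,
    knn: int = 10,
    log: bool = True,
    log_offset: float | None = None,
) -> OmicsMatrix:
    """Standard preparation pipeline: harmonize -> consolidate -> filter ->
    impute -> log."""
    if aliases is not None:
        m = harmonize_names(m, aliases)
    m = consolidate_duplicates(m)
    m = filter_missingness(m, max_missing)
    m = impute_knn(m, knn)
    if log and not m.log_transformed:
        m = log_transform(m, offset=log_offset)
    return m
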