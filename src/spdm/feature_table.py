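"""Feature-table preparation for age-ordered microbiome cohorts.

Turns a raw samples x genera read-count table plus per-sample metadata into
the matrices the progression analysis consumes:

* a relative-abundance matrix ``F`` with ``f_ij = n_ij / sum_k n_ik``,
* an assignment of samples to ordered age groups (weaning-based bins for
  infants, decades for adults, a final ">=100" bin for centenarians),
* a groups x features matrix of mean relative abundances, together with a
  per-feature standardized (z-scored) variant.

Count tables are held as :class:`pandas.DataFrame` objects with sample ids
on the index and feature (genus) names on the columns; all functions here
accept and return DataFrames so the pipeline composes with ordinary pandas
workflows.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeGrouping",
    "GroupProfiles",
    "DEFAULT_AGE_GROUPING",
    "read_counts",
    "read_metadata",
    "to_relative_abundance",
    "merge_features",
    "filter_low_abundance",
    "flag_outlier_samples",
    "assign_age_groups",
    "group_means",
    "normalize_features",
]


class FeatureTableError(ValueError):
    """Raised on malformed count tables or metadata."""


@dataclass(frozen=True)
class AgeGrouping:
    """Ordered, contiguous half-open age intervals ``(lo, hi]``.

    The last interval is unbounded above.  Group ids are 1-based positions
    in ``boundaries``.  Ages on an interval's upper boundary belong to the
    lower group; age exactly 0 belongs to no group.
    """

    boundaries: tuple[tuple[float, float], ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.boundaries:
            raise FeatureTableError("age grouping needs at least one interval")
        lo_prev = None
        for lo, hi in self.boundaries:
            if not hi > lo:
                raise FeatureTableError(f"empty interval ({lo}, {hi}]")
            if lo_prev is not None and lo != lo_prev:
                raise FeatureTableError("age intervals must be contiguous")
            lo_prev = hi
        if not math.isinf(self.boundaries[-1][1]):
            raise FeatureTableError("last age interval must be unbounded above")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(self._default_label(lo, hi) for lo, hi in self.boundaries)
            )

    @staticmethod
    def _default_label(lo: float, hi: float) -> str:
        if math.isinf(hi):
            return f">{lo:g}"
        return f"({lo:g}, {hi:g}]"

    @property
    def n_groups(self) -> int:
        return len(self.boundaries)

    def group_of(self, age: float) -> int:
        """1-based group id of ``age``; raises if no interval contains it."""
        if age <= 0:
            raise FeatureTableError(f"age {age!r} is outside every interval (ages must be > 0)")
        for g, (lo, hi) in enumerate(self.boundaries, start=1):
            if lo < age <= hi:
                return g
        raise FeatureTableError(f"age {age!r} is outside every interval")


#: Fourteen host-age bins: three weaning-status bins for infants, decades for
#: adults, and an unbounded centenarian bin.  The final interval is (99, inf)
#: so the intervals tile (0, inf); its label reflects that every subject in
#: the bin is at least 100 in the cohorts this default was designed around.
DEFAULT_AGE_GROUPING = AgeGrouping(
    boundaries=(
        (0.0, 0.4),
        (0.4, 1.2),
        (1.2, 3.0),
        (3.0, 9.0),
        (9.0, 19.0),
        (19.0, 29.0),
        (29.0, 39.0),
        (39.0, 49.0),
        (49.0, 59.0),
        (59.0, 69.0),
        (69.0, 79.0),
        (79.0, 89.0),
        (89.0, 99.0),
        (99.0, math.inf),
    ),
    labels=(
        "(0, 0.4]", "(0.4, 1.2]", "(1.2, 3]", "(3, 9]", "(9, 19]",
        "(19, 29]", "(29, 39]", "(39, 49]", "(49, 59]", "(59, 69]",
        "(69, 79]", "(79, 89]", "(89, 99]", ">=100",
    ),
)


@dataclass
class GroupProfiles:
    """Groups x features mean relative abundances with a standardized variant.

    ``means`` has group ids (1..G) on the index; ``normalized`` is filled by
    :func:`normalize_features` and is per-feature z-scored across groups
    (population standard deviation), constant features mapping to all zeros.
    """

    means: pd.DataFrame
    n_samples: pd.Series
    normalized: pd.DataFrame | None = None

    @property
    def group_ids(self) -> list[int]:
        return list(self.means.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.means.columns)


def _validate_counts(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FeatureTableError(f"{source}: empty count table")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FeatureTableError(f"{source}: duplicate sample ids {dups}")
    for pos, col in enumerate(df.columns):
        vals = df.iloc[:, pos]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric))
        if bad.any():
            row = vals.index[bad.to_numpy().nonzero()[0][0]]
            raise FeatureTableError(
                f"{source}: non-integer count at sample {row!r}, feature {col!r}"
            )
    out = df.astype(np.int64)
    if (out.to_numpy() < 0).any():
        r, c = np.argwhere(out.to_numpy() < 0)[0]
        raise FeatureTableError(
            f"{source}: negative count at sample {out.index[r]!r}, feature {out.columns[c]!r}"
        )
    return out


def _collapse_duplicate_features(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if not df.columns.has_duplicates:
        return df
    dups = df.columns[df.columns.duplicated()].unique().tolist()
    warnings.warn(
        f"{source}: duplicate feature columns {dups} summed into single features",
        UserWarning,
        stacklevel=3,
    )
    return df.T.groupby(level=0, sort=False).sum().T


def read_counts(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a samples x features count table from TSV or BIOM-1.0 JSON.

    TSV layout: first column sample ids, header row feature names, integer
    cells.  Duplicate feature columns are summed with a warning.  BIOM 1.0
    ("JSON BIOM") tables are transposed from their native observations x
    samples orientation; both dense and sparse matrix types are handled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
        df.index = df.index.astype(str)
        df.index.name = None
        # pandas de-duplicates repeated header names (g1, g1.1, ...); restore
        # the original header so duplicate features can be summed
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#") and line.strip():
                    df.columns = line.rstrip("\n").split("\t")[1:]
                    break
        df = _collapse_duplicate_features(
            _validate_counts(df, str(path)), str(path)
        )
        return df
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        sample_ids = [c["id"] for c in doc["columns"]]
        feature_ids = [r["id"] for r in doc["rows"]]
        shape = tuple(doc["shape"])  # (features, samples)
        mat = np.zeros(shape, dtype=np.int64)
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat[:] = np.asarray(doc["data"])
        df = pd.DataFrame(mat.T, index=sample_ids, columns=feature_ids)
        return _collapse_duplicate_features(_validate_counts(df, str(path)), str(path))
    raise FeatureTableError(f"unknown count-table format {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (columns ``sample_id``, ``age``, optional ``sex``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in ("sample_id", "age"):
        if col not in df.columns:
            raise FeatureTableError(f"{path}: metadata missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].unique().tolist()
        raise FeatureTableError(f"{path}: duplicate sample ids {dups}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any():
        missing = df.loc[ages.isna(), "sample_id"].tolist()
        raise FeatureTableError(f"{path}: missing/unparseable age for samples {missing}")
    if (ages < 0).any():
        neg = df.loc[ages < 0, "sample_id"].tolist()
        raise FeatureTableError(f"{path}: negative age for samples {neg}")
    df = df.copy()
    df["age"] = ages.astype(float)
    return df.set_index("sample_id", drop=False)


def to_relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts: ``f_ij = n_ij / sum_k n_ik``.

    Zeros stay exactly zero and every row sums to 1; a sample with no reads
    at all is an error (it has no defined composition).
    """
    totals = counts.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise FeatureTableError(f"samples with zero total count: {list(empty.index)}")
    return counts.div(totals, axis=0)


def merge_features(counts: pd.DataFrame, merge_map: Mapping[str, str]) -> pd.DataFrame:
    """Sum the columns named in ``merge_map`` into their target labels.

    Mirrors collapsing several unresolved genera into a single
    "unclassified" cluster.  A target label may not collide with an
    existing feature that is not itself being merged.
    """
    if not merge_map:
        return counts.copy()
    missing = [f for f in merge_map if f not in counts.columns]
    if missing:
        raise FeatureTableError(f"merge_map names absent features: {missing}")
    for target in set(merge_map.values()):
        if target in counts.columns and merge_map.get(target, target) != target:
            raise FeatureTableError(
                f"merge target {target!r} collides with an existing feature being renamed away"
            )
        if target in counts.columns and target not in merge_map:
            raise FeatureTableError(
                f"merge target {target!r} collides with an existing unmapped feature"
            )
    renamed = counts.columns.to_series().map(lambda c: merge_map.get(c, c))
    out = counts.T.groupby(renamed.to_numpy(), sort=False).sum().T
    return out


def filter_low_abundance(
    counts: pd.DataFrame, cum_fraction: float = 1e-4
) -> tuple[pd.DataFrame, list[str]]:
    """Drop the rarest features whose combined reads stay within a budget.

    Features are ordered by ascending total count (ties broken by name);
    the longest prefix of that ordering whose cumulative reads are at most
    ``cum_fraction`` of the grand total is removed.  The removed feature
    names are returned for audit.
    """
    if not 0 <= cum_fraction < 1:
        raise FeatureTableError("cum_fraction must be in [0, 1)")
    totals = counts.sum(axis=0)
    order = sorted(counts.columns, key=lambda c: (totals[c], c))
    budget = cum_fraction * float(totals.sum())
    removed: list[str] = []
    acc = 0
    for feat in order:
        acc += int(totals[feat])
        if acc > budget:
            break
        removed.append(feat)
    kept = [c for c in counts.columns if c not in set(removed)]
    return counts[kept], removed


def flag_outlier_samples(
    rel: pd.DataFrame, dominance_threshold: float = 0.8
) -> list[tuple[str, str, float]]:
    """Flag samples dominated by a single feature (possible sampling artifact).

    Returns ``(sample_id, feature_id, value)`` for every sample whose maximal
    single-feature relative abundance is >= the threshold.  Flag-only: the
    caller decides whether to exclude.
    """
    if not 0 < dominance_threshold <= 1:
        raise FeatureTableError("dominance_threshold must be in (0, 1]")
    flags = []
    vals = rel.to_numpy()
    argmax = vals.argmax(axis=1)
    for i, sample in enumerate(rel.index):
        v = vals[i, argmax[i]]
        if v >= dominance_threshold:
            flags.append((sample, rel.columns[argmax[i]], float(v)))
    return flags


def assign_age_groups(
    metadata: pd.DataFrame, grouping: AgeGrouping = DEFAULT_AGE_GROUPING
) -> pd.DataFrame:
    """Return metadata with a ``group_id`` column (1-based age-bin index)."""
    out = metadata.copy()
    out["group_id"] = [grouping.group_of(a) for a in out["age"]]
    return out


def group_means(rel: pd.DataFrame, metadata: pd.DataFrame) -> GroupProfiles:
    """Mean relative abundance of each feature within each age group.

    Every declared group must contain at least one sample; the estimate is
    the arithmetic mean of the member samples' relative abundances.
    """
    if "group_id" not in metadata.columns:
        raise FeatureTableError("metadata lacks group_id; run assign_age_groups first")
    groups = metadata.loc[rel.index, "group_id"]
    declared = sorted(metadata["group_id"].unique())
    means = rel.groupby(groups).mean()
    empty = [g for g in declared if g not in means.index]
    if empty:
        raise FeatureTableError(f"age groups with no samples: {empty}")
    n = rel.groupby(groups).size()
    means = means.loc[declared]
    return GroupProfiles(means=means, n_samples=n.loc[declared])


def normalize_features(profiles: GroupProfiles, mode: str = "zscore") -> GroupProfiles:
    """Fill ``profiles.normalized`` with a per-feature rescaling across groups.

    ``zscore`` (default) standardizes each feature column with the
    population standard deviation over the G groups; ``minmax`` maps it to
    [0, 1].  A constant column becomes all zeros either way.  Per-feature
    minimum-spanning-tree structure is invariant to this choice (both maps
    are affine), but the overall multi-feature tree is not.
    """
    X = profiles.means
    if mode == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        # a column whose spread is pure rounding noise counts as constant
        const = sd <= 1e-12 * X.abs().max(axis=0).clip(lower=1e-300)
        Z = (X - mu).div(sd.where(~const, 1.0), axis=1)
        Z.loc[:, const] = 0.0
    elif mode == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = hi - lo
        const = span <= 1e-12 * X.abs().max(axis=0).clip(lower=1e-300)
        Z = (X - lo).div(span.where(~const, 1.0), axis=1)
        Z.loc[:, const] = 0.0
    else:
        raise FeatureTableError(f"unknown normalization mode {mode!r}")
    return GroupProfiles(means=X, n_samples=profiles.n_samples, normalized=Z)
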