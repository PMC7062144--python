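"""Abundance-table I/O, validation, normalisation and variance filtering.

The central container is :class:`AbundanceMatrix`, a features x samples numeric
matrix tagged with the scale it lives on:

``raw``
    untransformed counts or measurements (non-negative);
``relative``
    per-sample closure, every column sums to 1;
``log``
    log-transformed (relative or raw) abundances;
``presence``
    0/1 detection calls.

All downstream model fitting operates on ``relative``, ``log`` or ``presence``
data; raw input is normalised on the fly (with a logged notice) by the search
layer.  Tables follow the metagenomic convention of features in rows, samples
in columns; a flag flips the orientation at read time.
"""

from __future__ import annotations

import logging
from dataclasses import InitVar, dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("raw", "relative", "log", "presence")

#: tolerance on per-sample sums for scale="relative"
RELATIVE_TOL = 1e-6

#: default pseudocount for the log transform; on the order of the smallest
#: non-zero relative abundances seen in shotgun profiles
DEFAULT_PSEUDOCOUNT = 1e-6


class DataError(ValueError):
    """Base class for data-layer failures."""


class ParseError(DataError):
    """A cell could not be parsed as a number."""


class ValidationError(DataError):
    """An invariant of a data container is violated."""


class DegenerateSampleError(DataError):
    """A sample carries no signal (e.g. an all-zero column)."""


@dataclass
class AbundanceMatrix:
    """Features x samples numeric matrix with identifiers and a scale tag.

    Parameters
    ----------
    values:
        2-D float array, one row per feature, one column per sample.
    feature_ids, sample_ids:
        Unique identifiers matching the matrix dimensions.
    scale:
        One of :data:`SCALES`.
    validate:
        Scale-specific numeric checks can be skipped (``validate=False``) by
        internal callers that intentionally break closure, e.g. the
        permutation step of the feature-importance computation.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    scale: str = "raw"
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array (features x samples)")
        p, n = self.values.shape
        if len(self.feature_ids) != p:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {p} rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.feature_ids)) != p:
            dup = _first_duplicate(self.feature_ids)
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if len(set(self.sample_ids)) != n:
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not np.isfinite(self.values).all():
            raise ValidationError("matrix contains missing or non-finite values")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if validate:
            self._check_scale()

    def _check_scale(self) -> None:
        if self.scale == "relative":
            if (self.values < 0).any():
                raise ValidationError("relative matrix has negative entries")
            sums = self.values.sum(axis=0)
            bad = np.nonzero(np.abs(sums - 1.0) > RELATIVE_TOL)[0]
            if bad.size:
                raise ValidationError(
                    f"sample {self.sample_ids[bad[0]]!r} sums to {sums[bad[0]]:.6g}, not 1"
                )
        elif self.scale == "presence":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValidationError("presence matrix has entries outside {0, 1}")

    # -- basic geometry -----------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def feature_index(self, name: str) -> int:
        try:
            return self._feature_lookup[name]
        except AttributeError:
            self._feature_lookup = {f: i for i, f in enumerate(self.feature_ids)}
            return self._feature_lookup[name]

    def subset_features(self, indices) -> "AbundanceMatrix":
        # a feature subset of a relative matrix keeps the scale tag but its
        # columns no longer close to 1, so the closure check is skipped
        indices = np.asarray(indices, dtype=int)
        return AbundanceMatrix(
            self.values[indices],
            [self.feature_ids[i] for i in indices],
            list(self.sample_ids),
            self.scale,
            validate=self.scale != "relative",
        )

    def subset_samples(self, indices) -> "AbundanceMatrix":
        indices = np.asarray(indices, dtype=int)
        return AbundanceMatrix(
            self.values[:, indices],
            list(self.feature_ids),
            [self.sample_ids[i] for i in indices],
            self.scale,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


def _first_duplicate(items) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


@dataclass
class SampleTarget:
    """Per-sample prediction target aligned to an :class:`AbundanceMatrix`.

    ``kind="binary_class"`` holds exactly two distinct labels; ``positive_class``
    names the label mapped to the score-high side of a fitted model and defaults
    (at fit time) to the lexicographically larger label.
    """

    sample_ids: list[str]
    kind: str  # "binary_class" | "continuous"
    values: np.ndarray
    positive_class: str | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.kind not in ("binary_class", "continuous"):
            raise ValidationError(f"unknown target kind {self.kind!r}")
        if self.kind == "continuous":
            self.values = np.asarray(self.values, dtype=float)
            if not np.isfinite(self.values).all():
                raise ValidationError("continuous target has non-finite values")
        else:
            self.values = np.asarray([str(v) for v in np.asarray(self.values).ravel()],
                                     dtype=object)
            labels = sorted(set(self.values))
            if len(labels) != 2:
                raise ValidationError(
                    f"binary target must have exactly 2 labels, got {labels}"
                )
            if self.positive_class is not None and str(self.positive_class) not in labels:
                raise ValidationError(
                    f"positive_class {self.positive_class!r} not among labels {labels}"
                )
        if len(self.sample_ids) != len(self.values):
            raise ValidationError("sample_ids and values differ in length")

    @property
    def classes(self) -> list[str]:
        if self.kind != "binary_class":
            raise ValidationError("classes defined for binary targets only")
        return sorted(set(self.values))

    def resolved_positive(self) -> str:
        """The configured positive class, defaulting to the larger label."""
        return str(self.positive_class) if self.positive_class is not None else self.classes[1]

    def positive_mask(self) -> np.ndarray:
        pos = self.resolved_positive()
        return np.asarray([v == pos for v in self.values], dtype=bool)

    def subset(self, indices) -> "SampleTarget":
        indices = np.asarray(indices, dtype=int)
        return SampleTarget(
            [self.sample_ids[i] for i in indices],
            self.kind,
            self.values[indices],
            self.positive_class,
        )


# -- reading and writing ----------------------------------------------------


def read_abundance_table(path, delimiter: str = "\t",
                         features_in_rows: bool = True) -> AbundanceMatrix:
    """Read a delimited abundance table into an :class:`AbundanceMatrix`.

    The first row holds sample ids, the first column feature ids (flipped when
    ``features_in_rows`` is False).  Cells must all parse as numbers; the
    returned matrix has ``scale="raw"``.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                     keep_default_na=False, na_values=[])
    if not features_in_rows:
        df = df.T
    numeric = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                numeric[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric cell {raw[i, j]!r} at feature "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}"
                ) from None
    return AbundanceMatrix(numeric, list(df.index), list(df.columns), scale="raw")


def read_sample_target(path, delimiter: str = "\t",
                       kind: str | None = None,
                       positive_class: str | None = None) -> SampleTarget:
    """Read a metadata table with columns ``sample_id`` and ``target``.

    ``kind`` is inferred when omitted: a target column with exactly two
    distinct values is binary, anything else must parse as numbers.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str,
                     keep_default_na=False, na_values=[])
    for col in ("sample_id", "target"):
        if col not in df.columns:
            raise ParseError(f"metadata file lacks required column {col!r}")
    raw = [str(v) for v in df["target"]]
    if kind is None:
        kind = "binary_class" if len(set(raw)) == 2 else "continuous"
    if kind == "continuous":
        try:
            vals = np.asarray([float(v) for v in raw])
        except ValueError as exc:
            raise ParseError(f"non-numeric continuous target: {exc}") from None
        return SampleTarget(list(df["sample_id"]), kind, vals)
    return SampleTarget(list(df["sample_id"]), kind, raw, positive_class=positive_class)


def align_target(m: AbundanceMatrix, y: SampleTarget) -> SampleTarget:
    """Reorder ``y`` to follow the sample order of ``m``; error on mismatch."""
    pos = {s: i for i, s in enumerate(y.sample_ids)}
    missing = [s for s in m.sample_ids if s not in pos]
    if missing:
        raise ValidationError(f"samples missing from target: {missing[:5]}")
    order = [pos[s] for s in m.sample_ids]
    return y.subset(order)


def write_abundance_table(m: AbundanceMatrix, path, delimiter: str = "\t") -> None:
    """Write a table byte-stably (``%.10g`` float formatting)."""
    with open(path, "w") as fh:
        fh.write("feature_id" + delimiter + delimiter.join(m.sample_ids) + "\n")
        for i, fid in enumerate(m.feature_ids):
            row = delimiter.join("%.10g" % v for v in m.values[i])
            fh.write(fid + delimiter + row + "\n")


# -- transforms -------------------------------------------------------------


def normalize_relative(m: AbundanceMatrix) -> AbundanceMatrix:
    """Close every sample to sum 1 (``scale="relative"``).

    Idempotent; rejects negative entries and all-zero samples.
    """
    if (m.values < 0).any():
        raise DataError("cannot normalise a matrix with negative entries")
    sums = m.values.sum(axis=0)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise DegenerateSampleError(
            f"sample {m.sample_ids[zero[0]]!r} is all zero; cannot normalise"
        )
    return AbundanceMatrix(m.values / sums, list(m.feature_ids),
                           list(m.sample_ids), scale="relative")


def to_presence(m: AbundanceMatrix) -> AbundanceMatrix:
    """Binarise to detection calls: entry > 0 becomes 1. Idempotent."""
    if (m.values < 0).any():
        raise DataError("presence transform expects non-negative entries")
    return AbundanceMatrix((m.values > 0).astype(float), list(m.feature_ids),
                           list(m.sample_ids), scale="presence")


def log_transform(m: AbundanceMatrix,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> AbundanceMatrix:
    """Entrywise log(x + pseudocount) on relative or raw data."""
    if m.scale not in ("relative", "raw"):
        raise DataError(f"log transform defined on relative/raw data, not {m.scale!r}")
    if (m.values < 0).any():
        raise DataError("log transform expects non-negative entries")
    if pseudocount <= 0 and (m.values == 0).any():
        raise DataError("pseudocount must be positive when zeros are present")
    return AbundanceMatrix(np.log(m.values + pseudocount), list(m.feature_ids),
                           list(m.sample_ids), scale="log")


# -- variance filtering -----------------------------------------------------


def filter_low_sd(m: AbundanceMatrix) -> tuple[AbundanceMatrix, list[str]]:
    """Drop low-variance features using the elbow of the sorted-SD curve.

    Per-feature standard deviations are sorted ascending; the elbow is the
    point of maximum central second difference of that curve against rank.
    Features whose SD falls strictly below the first retained SD (the value
    just past the elbow) are removed; SD = 0 features are always removed.
    A flat curve (maximum second difference <= 0) triggers no elbow filtering.
    Ties in the maximum take the smallest threshold, retaining more features.
    """
    if m.n_features < 3:
        raise DataError("SD filtering needs at least 3 features")
    sds = m.values.std(axis=1, ddof=1)
    if (sds == 0).all():
        raise DataError("all features are constant; no informative features")
    s = np.sort(sds)
    d2 = s[2:] - 2.0 * s[1:-1] + s[:-2]  # central second difference vs rank
    threshold = 0.0  # always removes SD=0 features (strict < below keeps SD>0)
    if d2.size and d2.max() > 0:
        elbow = int(np.argmax(d2)) + 1  # index into s of the corner point
        threshold = s[elbow + 1] if elbow + 1 < s.size else s[elbow]
    keep = np.nonzero((sds >= threshold) & (sds > 0))[0]
    removed = [m.feature_ids[i] for i in range(m.n_features) if i not in set(keep)]
    if keep.size == 0:
        raise DataError("SD filter removed every feature")
    return m.subset_features(keep), removed


def prepare_for_fitting(m: AbundanceMatrix) -> AbundanceMatrix:
    """Make a matrix fit-ready: raw input is closed to relative abundance."""
    if m.scale == "raw":
        logger.info("raw input: applying relative-abundance normalisation")
        return normalize_relative(m)
    return m
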