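"""Count-matrix containers, I/O and data preparation.

The universal currency of the toolkit is a genes x samples matrix of
non-negative integer read counts with unique feature and sample identifiers,
plus a two-class sample annotation.  Preparation steps mirror the standard
pre-processing of a two-class bulk RNA-seq cohort: drop features whose median
count is zero, subset to a balanced number of samples per class, and clip
extreme outlier counts at a ceiling.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from ._rng import substream

__all__ = [
    "CountMatrix",
    "SampleAnnotation",
    "CountMatrixError",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "filter_zero_median",
    "subset_balanced",
    "truncate_outliers",
]

#: default outlier ceiling applied by ``truncate_outliers`` (reads)
DEFAULT_TRUNCATION_CEILING = 10**7


class CountMatrixError(ValueError):
    """Raised for malformed count matrices or annotation mismatches."""


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer count table.

    Parameters
    ----------
    counts
        ``(n_features, n_samples)`` array of non-negative integers.
    feature_ids, sample_ids
        Unique row / column identifiers.
    """

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountMatrixError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise CountMatrixError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise CountMatrixError("counts must be non-negative")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        nf, ns = self.counts.shape
        if len(self.feature_ids) != nf:
            raise CountMatrixError(
                f"{len(self.feature_ids)} feature ids for {nf} rows"
            )
        if len(self.sample_ids) != ns:
            raise CountMatrixError(
                f"{len(self.sample_ids)} sample ids for {ns} columns"
            )
        if len(set(self.feature_ids)) != nf:
            raise CountMatrixError("duplicate feature identifiers")
        if len(set(self.sample_ids)) != ns:
            raise CountMatrixError("duplicate sample identifiers")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise CountMatrixError(f"unknown sample ids: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(
            self.counts[:, cols], list(self.feature_ids), list(sample_ids)
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise CountMatrixError(f"unknown feature ids: {missing[:5]}")
        rows = [idx[f] for f in feature_ids]
        return CountMatrix(
            self.counts[rows, :], list(feature_ids), list(self.sample_ids)
        )


@dataclass
class SampleAnnotation:
    """Two-class (and optional subgroup) labels for samples.

    ``class_of`` maps sample id -> class label in {1, 2}; ``subgroup_of``
    optionally maps sample id -> integer subgroup.
    """

    class_of: dict[str, int]
    subgroup_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, c in self.class_of.items():
            if c not in (1, 2):
                raise CountMatrixError(
                    f"sample {s!r}: class label must be 1 or 2, got {c!r}"
                )

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Class labels aligned to ``sample_ids``; every sample must be annotated."""
        missing = [s for s in sample_ids if s not in self.class_of]
        if missing:
            raise CountMatrixError(
                f"samples without annotation: {missing[:5]}"
            )
        return np.array([self.class_of[s] for s in sample_ids], dtype=int)

    def samples_in_class(self, label: int) -> list[str]:
        return [s for s, c in self.class_of.items() if c == label]

    def validate_two_class(self, sample_ids: Sequence[str]) -> None:
        labels = self.labels_for(sample_ids)
        for c in (1, 2):
            if np.sum(labels == c) < 1:
                raise CountMatrixError(f"no samples in class {c}")


# ---------------------------------------------------------------------------
# I/O: tab-separated text and matrix-market
# ---------------------------------------------------------------------------

HEADER_CELL = "feature_id"


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from TSV or matrix-market coordinate format.

    The TSV dialect is tab-separated UTF-8 with the literal header cell
    ``feature_id`` followed by sample identifiers; each subsequent row is a
    feature identifier and its integer counts.  Matrix-market input expects
    companion ``<stem>.features.txt`` and ``<stem>.samples.txt`` id lists.
    """
    path = Path(path)
    if format == "tsv":
        return _read_counts_tsv(path)
    if format == "mtx":
        return _read_counts_mtx(path)
    raise CountMatrixError(f"unknown count format {format!r}")


def _read_counts_tsv(path: Path) -> CountMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cells = header.split("\t")
        if not cells or cells[0] != HEADER_CELL:
            raise CountMatrixError(
                f"{path}:1: header must start with {HEADER_CELL!r}, "
                f"got {cells[0]!r}"
            )
        sample_ids = cells[1:]
        n_cols = len(sample_ids)
        feature_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_cols + 1:
                raise CountMatrixError(
                    f"{path}:{lineno}: expected {n_cols + 1} columns, "
                    f"got {len(parts)}"
                )
            feature_ids.append(parts[0])
            row = []
            for j, tok in enumerate(parts[1:], start=2):
                try:
                    val = int(tok)
                except ValueError:
                    raise CountMatrixError(
                        f"{path}:{lineno} column {j}: non-integer count "
                        f"{tok!r}"
                    ) from None
                if val < 0:
                    raise CountMatrixError(
                        f"{path}:{lineno} column {j}: negative count {val}"
                    )
                row.append(val)
            rows.append(row)
    if not rows:
        raise CountMatrixError(f"{path}: no data rows")
    return CountMatrix(np.array(rows, dtype=np.int64), feature_ids, sample_ids)


def _mtx_companions(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("") if path.suffix == ".mtx" else path
    return (
        stem.with_suffix(".features.txt"),
        stem.with_suffix(".samples.txt"),
    )


def _read_counts_mtx(path: Path) -> CountMatrix:
    feat_path, samp_path = _mtx_companions(path)
    for p in (path, feat_path, samp_path):
        if not p.exists():
            raise CountMatrixError(f"missing file: {p}")
    mat = spio.mmread(path)
    dense = np.asarray(sparse.coo_matrix(mat).todense())
    if not np.all(np.equal(np.mod(dense, 1), 0)):
        raise CountMatrixError(f"{path}: non-integer entries")
    feature_ids = feat_path.read_text(encoding="utf-8").split()
    sample_ids = samp_path.read_text(encoding="utf-8").split()
    return CountMatrix(dense.astype(np.int64), feature_ids, sample_ids)


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a count matrix as TSV or matrix-market (with id companions)."""
    path = Path(path)
    if format == "tsv":
        buf = _io.StringIO()
        buf.write(HEADER_CELL + "\t" + "\t".join(cm.sample_ids) + "\n")
        for fid, row in zip(cm.feature_ids, cm.counts):
            buf.write(fid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        path.write_text(buf.getvalue(), encoding="utf-8")
    elif format == "mtx":
        feat_path, samp_path = _mtx_companions(path)
        spio.mmwrite(path, sparse.coo_matrix(cm.counts))
        feat_path.write_text("\n".join(cm.feature_ids) + "\n", encoding="utf-8")
        samp_path.write_text("\n".join(cm.sample_ids) + "\n", encoding="utf-8")
    else:
        raise CountMatrixError(f"unknown count format {format!r}")


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample-annotation TSV (sample_id, class[, subgroup])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "class"):
        if col not in df.columns:
            raise CountMatrixError(f"{path}: missing column {col!r}")
    class_of = dict(zip(df["sample_id"], df["class"].astype(int)))
    subgroup_of: dict[str, int] = {}
    if "subgroup" in df.columns:
        sub = df.dropna(subset=["subgroup"])
        subgroup_of = dict(zip(sub["sample_id"], sub["subgroup"].astype(int)))
    return SampleAnnotation(class_of, subgroup_of)


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    rows = []
    for s, c in ann.class_of.items():
        rows.append(
            {"sample_id": s, "class": c, "subgroup": ann.subgroup_of.get(s, "")}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preparation steps
# ---------------------------------------------------------------------------

def filter_zero_median(cm: CountMatrix) -> CountMatrix:
    """Drop features whose median count across samples is 0; order preserved.

    With integer counts a zero median means at least half the samples have
    zero reads for the feature (midpoint convention for an even number of
    samples).
    """
    medians = np.median(cm.counts, axis=1)
    keep = medians > 0
    if not np.any(keep):
        warnings.warn("filter_zero_median removed every feature", stacklevel=2)
    kept_ids = [f for f, k in zip(cm.feature_ids, keep) if k]
    return CountMatrix(cm.counts[keep, :], kept_ids, list(cm.sample_ids))


def subset_balanced(
    cm: CountMatrix,
    ann: SampleAnnotation,
    n_per_class: int,
    seed: int,
) -> CountMatrix:
    """Sample ``n_per_class`` columns per class without replacement (seeded).

    Selected samples keep the input column order.  Raises when a class has
    fewer than ``n_per_class`` annotated samples in the matrix.
    """
    labels = ann.labels_for(cm.sample_ids)
    rng = substream(seed, "subset_balanced")
    chosen: set[str] = set()
    for c in (1, 2):
        members = [s for s, l in zip(cm.sample_ids, labels) if l == c]
        if len(members) < n_per_class:
            raise CountMatrixError(
                f"class {c} has {len(members)} samples, need {n_per_class}"
            )
        picked = rng.choice(len(members), size=n_per_class, replace=False)
        chosen.update(members[i] for i in picked)
    kept = [s for s in cm.sample_ids if s in chosen]
    return cm.subset_samples(kept)


def truncate_outliers(
    cm: CountMatrix, ceiling: int = DEFAULT_TRUNCATION_CEILING
) -> tuple[CountMatrix, int]:
    """Clip every count above ``ceiling`` to ``ceiling``.

    Returns the clipped matrix and the number of entries that were truncated.
    Entries exactly at the ceiling are unchanged.
    """
    if ceiling <= 0:
        raise CountMatrixError("ceiling must be positive")
    n_trunc = int(np.sum(cm.counts > ceiling))
    clipped = np.minimum(cm.counts, ceiling)
    return (
        CountMatrix(clipped, list(cm.feature_ids), list(cm.sample_ids)),
        n_trunc,
    )
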