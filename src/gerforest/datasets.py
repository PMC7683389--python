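"""Dataset containers and readers for partially labeled tabular data.

The canonical in-memory representation splits a feature table into a
labeled block ``(X_l, y_l)`` and an unlabeled block ``X_u`` sharing the
same feature dimension.  Classes are always encoded as contiguous
integers ``0..K-1``; the original label values (e.g. ``-1/+1`` from a
LIBSVM file) are retained in ``label_names`` so reports can show them.

Two on-disk dialects are supported: the LIBSVM sparse text format
(1-based feature indices) and dense CSV/TSV tables with a header row,
where an empty label cell marks an unlabeled row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class DatasetFormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class PartiallyLabeledDataset:
    """Feature vectors with a labeled and an (optionally empty) unlabeled block.

    Parameters
    ----------
    X_labeled : ndarray of shape (l, d)
        Features of the labeled instances.
    y_labeled : ndarray of shape (l,)
        Integer class labels in ``{0..K-1}``.
    X_unlabeled : ndarray of shape (u, d)
        Features of the unlabeled instances (``u`` may be 0).
    n_classes : int
        Number of classes ``K``.  May be 0 for prediction-only tables.
    y_unlabeled_oracle : ndarray of shape (u,), optional
        True labels of the unlabeled block, withheld from training.
        Populated by :func:`split_labeled_subset` so that oracle
        baselines and evaluation can access them explicitly.
    label_names : ndarray, optional
        Original label values in sorted order; ``label_names[k]`` is the
        raw value encoded as class ``k``.
    row_order : ndarray, optional
        For datasets read from a file: original row index of each
        instance, labeled block first, so predictions can be written
        back in file order.
    """

    X_labeled: np.ndarray
    y_labeled: np.ndarray
    X_unlabeled: np.ndarray
    n_classes: int
    y_unlabeled_oracle: np.ndarray | None = None
    label_names: np.ndarray | None = None
    row_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X_labeled = np.asarray(self.X_labeled, dtype=float)
        self.X_unlabeled = np.asarray(self.X_unlabeled, dtype=float)
        self.y_labeled = np.asarray(self.y_labeled, dtype=int)
        if self.X_labeled.ndim != 2 or self.X_unlabeled.ndim != 2:
            raise ValueError("feature blocks must be 2-D matrices")
        if self.X_labeled.shape[0] != self.y_labeled.shape[0]:
            raise ValueError("labeled features and labels disagree in length")
        if self.X_labeled.shape[0] and self.X_unlabeled.shape[0]:
            if self.X_labeled.shape[1] != self.X_unlabeled.shape[1]:
                raise ValueError("labeled and unlabeled blocks differ in dimension")
        if self.y_labeled.size and (
            self.y_labeled.min() < 0 or self.y_labeled.max() >= max(self.n_classes, 1)
        ):
            raise ValueError("labels must lie in {0..K-1}")
        if self.y_unlabeled_oracle is not None:
            self.y_unlabeled_oracle = np.asarray(self.y_unlabeled_oracle, dtype=int)
            if self.y_unlabeled_oracle.shape[0] != self.X_unlabeled.shape[0]:
                raise ValueError("oracle labels must match the unlabeled block")

    @property
    def n_labeled(self) -> int:
        return self.X_labeled.shape[0]

    @property
    def n_unlabeled(self) -> int:
        return self.X_unlabeled.shape[0]

    @property
    def n_features(self) -> int:
        if self.X_labeled.shape[0]:
            return self.X_labeled.shape[1]
        return self.X_unlabeled.shape[1]

    def all_features(self) -> np.ndarray:
        """Stack labeled then unlabeled features into one (l+u, d) matrix."""
        if self.n_unlabeled == 0:
            return self.X_labeled
        if self.n_labeled == 0:
            return self.X_unlabeled
        return np.vstack([self.X_labeled, self.X_unlabeled])

    def require_trainable(self) -> None:
        """Check the training preconditions: l >= 1 and >= 2 classes present."""
        if self.n_labeled < 1:
            raise ValueError("training requires at least one labeled instance")
        if np.unique(self.y_labeled).size < 2:
            raise ValueError("training requires at least 2 distinct classes")

    def replace(self, **changes) -> "PartiallyLabeledDataset":
        return dataclasses.replace(self, **changes)


def label_matrix(dataset: PartiallyLabeledDataset) -> np.ndarray:
    """One-hot label matrix Y of shape (l+u, K).

    Labeled rows are one-hot; unlabeled rows are all zero, so each
    labeled row sums to 1 and each unlabeled row to 0.
    """
    n = dataset.n_labeled + dataset.n_unlabeled
    K = dataset.n_classes
    Y = np.zeros((n, K), dtype=float)
    Y[np.arange(dataset.n_labeled), dataset.y_labeled] = 1.0
    return Y


def _encode_labels(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map raw label values to 0..K-1 preserving sorted original order."""
    names, encoded = np.unique(raw, return_inverse=True)
    return encoded.astype(int), names


def read_libsvm(path: str | Path) -> PartiallyLabeledDataset:
    """Read a LIBSVM sparse text file into a dense, fully labeled dataset.

    Each line is ``label index:value ...`` with 1-based indices; absent
    indices are zero.  Labels are remapped to ``0..K-1`` in sorted order
    of the original values (so ``-1 -> 0`` and ``+1 -> 1``).
    """
    path = Path(path)
    raw_labels: list[float] = []
    rows: list[dict[int, float]] = []
    max_index = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                raw_labels.append(float(parts[0]))
            except ValueError as exc:
                raise DatasetFormatError(
                    f"{path}:{lineno}: non-numeric label {parts[0]!r}"
                ) from exc
            entries: dict[int, float] = {}
            for token in parts[1:]:
                if ":" not in token:
                    raise DatasetFormatError(
                        f"{path}:{lineno}: malformed feature token {token!r}"
                    )
                idx_s, val_s = token.split(":", 1)
                try:
                    idx = int(idx_s)
                    val = float(val_s)
                except ValueError as exc:
                    raise DatasetFormatError(
                        f"{path}:{lineno}: non-numeric entry {token!r}"
                    ) from exc
                if idx < 1:
                    raise DatasetFormatError(
                        f"{path}:{lineno}: feature index {idx} is not 1-based"
                    )
                entries[idx] = val
                max_index = max(max_index, idx)
            rows.append(entries)
    if not rows:
        raise DatasetFormatError(f"{path}: no records")
    X = np.zeros((len(rows), max_index), dtype=float)
    for i, entries in enumerate(rows):
        for idx, val in entries.items():
            X[i, idx - 1] = val
    y, names = _encode_labels(np.asarray(raw_labels))
    return PartiallyLabeledDataset(
        X_labeled=X,
        y_labeled=y,
        X_unlabeled=np.empty((0, max_index)),
        n_classes=names.size,
        label_names=names,
        row_order=np.arange(len(rows)),
    )


def write_libsvm(dataset: PartiallyLabeledDataset, path: str | Path) -> None:
    """Write the labeled block to LIBSVM format (original label values)."""
    names = dataset.label_names
    with open(path, "w") as fh:
        for i in range(dataset.n_labeled):
            raw = dataset.y_labeled[i] if names is None else names[dataset.y_labeled[i]]
            tokens = [f"{raw:g}" if isinstance(raw, (int, float, np.number)) else str(raw)]
            row = dataset.X_labeled[i]
            for j in np.nonzero(row)[0]:
                tokens.append(f"{j + 1}:{row[j]:.17g}")
            fh.write(" ".join(tokens) + "\n")


def read_csv_table(
    path: str | Path,
    label_column: str | None = "label",
    unlabeled_rows: list[int] | None = None,
) -> PartiallyLabeledDataset:
    """Read a dense CSV/TSV table with a header row.

    Rows whose label cell is empty form the unlabeled block; an explicit
    ``unlabeled_rows`` list (0-based data-row indices) is also honored.
    With ``label_column=None`` every row is unlabeled (prediction-only).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise DatasetFormatError(f"{path}: ragged or malformed table: {exc}") from exc
    if frame.shape[0] == 0:
        raise DatasetFormatError(f"{path}: no records")

    if label_column is not None and label_column not in frame.columns:
        raise DatasetFormatError(
            f"{path}: label column {label_column!r} not found"
        )
    feature_cols = [c for c in frame.columns if c != label_column]
    features = frame[feature_cols]
    bad = features.apply(lambda col: pd.to_numeric(col, errors="coerce")).isna() & features.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DatasetFormatError(
            f"{path}: non-numeric feature cell at row {r}, column {feature_cols[c]!r}"
        )
    if features.isna().to_numpy().any():
        r, c = np.argwhere(features.isna().to_numpy())[0]
        raise DatasetFormatError(
            f"{path}: missing feature cell at row {r}, column {feature_cols[c]!r}"
        )
    X = features.to_numpy(dtype=float)

    if label_column is None:
        return PartiallyLabeledDataset(
            X_labeled=np.empty((0, X.shape[1])),
            y_labeled=np.empty(0, dtype=int),
            X_unlabeled=X,
            n_classes=0,
            row_order=np.arange(X.shape[0]),
        )

    labels = frame[label_column]
    is_unlabeled = labels.isna().to_numpy()
    if unlabeled_rows is not None:
        is_unlabeled = is_unlabeled.copy()
        is_unlabeled[np.asarray(unlabeled_rows, dtype=int)] = True
    if is_unlabeled.all():
        raise DatasetFormatError(f"{path}: all rows unlabeled")
    labeled_idx = np.nonzero(~is_unlabeled)[0]
    unlabeled_idx = np.nonzero(is_unlabeled)[0]
    y, names = _encode_labels(labels.to_numpy()[labeled_idx])
    return PartiallyLabeledDataset(
        X_labeled=X[labeled_idx],
        y_labeled=y,
        X_unlabeled=X[unlabeled_idx],
        n_classes=names.size,
        label_names=names,
        row_order=np.concatenate([labeled_idx, unlabeled_idx]),
    )


def write_csv_table(
    dataset: PartiallyLabeledDataset,
    path: str | Path,
    label_column: str = "label",
    float_format: str = "%.17g",
) -> None:
    """Write a dataset back to CSV, restoring original row order if known."""
    d = dataset.n_features
    X = dataset.all_features()
    names = dataset.label_names
    raw_labels: list[object] = [
        names[k] if names is not None else k for k in dataset.y_labeled
    ]
    label_col = raw_labels + [np.nan] * dataset.n_unlabeled
    frame = pd.DataFrame(X, columns=[f"f{j}" for j in range(d)])
    frame[label_column] = label_col
    if dataset.row_order is not None:
        frame.index = dataset.row_order
        frame = frame.sort_index()
    frame.to_csv(path, index=False, float_format=float_format)


def split_labeled_subset(
    dataset: PartiallyLabeledDataset,
    n: int,
    seed: int,
    stratify: bool = True,
) -> PartiallyLabeledDataset:
    """Keep labels on a random subset of ``n`` rows; withhold the rest.

    The withheld labels are retained in ``y_unlabeled_oracle`` so that
    oracle baselines and evaluation can use them.  Sampling is without
    replacement and, by default, stratified to guarantee at least one
    labeled instance per class whenever ``n >= K``.
    """
    if dataset.n_unlabeled:
        raise ValueError("split_labeled_subset expects a fully labeled dataset")
    total = dataset.n_labeled
    if n > total:
        raise ValueError(f"n={n} exceeds dataset size {total}")
    if n < 2:
        raise ValueError("need n >= 2 labeled rows")
    K = dataset.n_classes
    rng = np.random.default_rng(seed)
    if stratify:
        if n < K:
            raise ValueError(f"cannot stratify n={n} rows over {K} classes")
        chosen: list[np.ndarray] = []
        # one guaranteed draw per class, then top up uniformly
        for k in range(K):
            members = np.nonzero(dataset.y_labeled == k)[0]
            chosen.append(rng.choice(members, size=1, replace=False))
        base = np.concatenate(chosen)
        rest_pool = np.setdiff1d(np.arange(total), base)
        extra = rng.choice(rest_pool, size=n - base.size, replace=False)
        labeled_idx = np.sort(np.concatenate([base, extra]))
    else:
        labeled_idx = np.sort(rng.choice(total, size=n, replace=False))
    unlabeled_idx = np.setdiff1d(np.arange(total), labeled_idx)
    return PartiallyLabeledDataset(
        X_labeled=dataset.X_labeled[labeled_idx],
        y_labeled=dataset.y_labeled[labeled_idx],
        X_unlabeled=dataset.X_labeled[unlabeled_idx],
        n_classes=K,
        y_unlabeled_oracle=dataset.y_labeled[unlabeled_idx],
        label_names=dataset.label_names,
        row_order=np.concatenate([labeled_idx, unlabeled_idx]),
    )
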