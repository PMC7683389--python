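"""Synthetic manifold-structured datasets and vessel-like phantom images.

These generators provide every fixture the pipeline needs without any
download: Gaussian cluster pairs (linearly separable baseline), the
two-moons interleaving half-circles (the canonical fixture where graph
propagation beats linear structure), and a curvilinear-tube phantom
image emulating a retinal-vessel patch-classification input.

All generators are pure functions of their arguments: the same seed
yields bit-identical output.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from sklearn.datasets import make_moons as _sk_make_moons

from .datasets import PartiallyLabeledDataset, split_labeled_subset


def _random_embedding(dim_in: int, dim_out: int, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal (dim_in, dim_out) embedding via QR of a Gaussian draw."""
    if dim_out < dim_in:
        raise ValueError("embedding dimension must be >= intrinsic dimension")
    G = rng.standard_normal((dim_out, dim_in))
    Q, _ = np.linalg.qr(G)
    return Q[:, :dim_in].T  # (dim_in, dim_out), orthonormal rows


def _finalize(X: np.ndarray, y: np.ndarray, dimension: int | None, rng) -> PartiallyLabeledDataset:
    if dimension is not None and dimension != X.shape[1]:
        E = _random_embedding(X.shape[1], dimension, rng)
        X = X @ E
    return PartiallyLabeledDataset(
        X_labeled=X,
        y_labeled=y,
        X_unlabeled=np.empty((0, X.shape[1])),
        n_classes=int(y.max()) + 1,
    )


def make_clusters(
    n_per_class: int = 50,
    noise_scale: float = 0.5,
    dimension: int | None = None,
    seed: int = 0,
    center_distance: float | None = None,
) -> PartiallyLabeledDataset:
    """Two isotropic Gaussian clusters, fully labeled.

    Centers sit ``center_distance`` apart along the first axis
    (default ``20 * noise_scale``, i.e. a separation/noise ratio of 20);
    each cluster is isotropic with standard deviation ``noise_scale``.
    With ``dimension`` set, the 2-D cloud is mapped through a random
    orthonormal embedding into that many dimensions.
    """
    rng = np.random.default_rng(seed)
    sep = 20.0 * noise_scale if center_distance is None else center_distance
    centers = np.array([[0.0, 0.0], [sep, 0.0]])
    X = np.vstack(
        [c + noise_scale * rng.standard_normal((n_per_class, 2)) for c in centers]
    )
    y = np.repeat([0, 1], n_per_class)
    return _finalize(X, y, dimension, rng)


def make_moons(
    n_per_class: int = 200,
    noise_scale: float = 0.05,
    dimension: int | None = None,
    seed: int = 0,
) -> PartiallyLabeledDataset:
    """Two interleaving half-circles of radius 1 with Gaussian jitter."""
    rng = np.random.default_rng(seed)
    X, y = _sk_make_moons(
        n_samples=2 * n_per_class,
        noise=noise_scale,
        random_state=np.random.RandomState(seed),
    )
    return _finalize(np.asarray(X, float), np.asarray(y, int), dimension, rng)


def as_partially_labeled(
    dataset: PartiallyLabeledDataset,
    labeled_per_class: int,
    seed: int = 0,
) -> PartiallyLabeledDataset:
    """Keep exactly ``labeled_per_class`` labels per class, withhold the rest."""
    rng = np.random.default_rng(seed)
    chosen = []
    for k in range(dataset.n_classes):
        members = np.nonzero(dataset.y_labeled == k)[0]
        if members.size < labeled_per_class:
            raise ValueError(f"class {k} has only {members.size} members")
        chosen.append(rng.choice(members, size=labeled_per_class, replace=False))
    labeled_idx = np.sort(np.concatenate(chosen))
    unlabeled_idx = np.setdiff1d(np.arange(dataset.n_labeled), labeled_idx)
    return PartiallyLabeledDataset(
        X_labeled=dataset.X_labeled[labeled_idx],
        y_labeled=dataset.y_labeled[labeled_idx],
        X_unlabeled=dataset.X_labeled[unlabeled_idx],
        n_classes=dataset.n_classes,
        y_unlabeled_oracle=dataset.y_labeled[unlabeled_idx],
        label_names=dataset.label_names,
    )


def _bezier_points(control: np.ndarray, n: int = 600) -> np.ndarray:
    """Dense samples of a cubic Bezier curve from 4 control points."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2, p3 = control
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * p1
        + 3 * (1 - t) * t ** 2 * p2
        + t ** 3 * p3
    )


def make_vessel_image(
    height: int = 128,
    width: int = 128,
    n_tubes: int = 3,
    snr: float = 10.0,
    background: float = 0.1,
    contrast: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Phantom image of bright curvilinear tubes on a noisy background.

    Tube centerlines are random cubic Bezier curves; each tube has a
    Gaussian cross-section profile of full width 2-5 px.  ``snr`` is the
    peak tube contrast divided by the background noise standard
    deviation.  Returns ``(image, mask)`` with ``mask`` true on tube
    pixels (within half a tube width of a centerline).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    image = np.full((height, width), background)
    mask = np.zeros((height, width), dtype=bool)
    for _ in range(n_tubes):
        control = rng.uniform([0, 0], [height - 1, width - 1], size=(4, 2))
        pts = _bezier_points(control)
        centerline = np.zeros((height, width), dtype=bool)
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, height - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, width - 1)
        centerline[rr, cc] = True
        dist = ndi.distance_transform_edt(~centerline)
        tube_width = rng.uniform(2.0, 5.0)
        profile_sigma = tube_width / 2.0
        image += contrast * np.exp(-(dist ** 2) / (2.0 * profile_sigma ** 2))
        mask |= dist <= tube_width / 2.0
    noise_sigma = contrast / snr
    image += noise_sigma * rng.standard_normal((height, width))
    return image, mask
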