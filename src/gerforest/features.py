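"""Patch and Gabor-wavelet features for pixel classification.

Two feature families turn an image plus a list of sampled pixel
positions into a feature table: raw local patches (odd-sized windows
centered on the pixel, reflect-padded at borders, values scaled to
[0, 1]) and the modulus of 2-D Gabor responses over a bank of scales
and orientations.  The default bank covers 4 wavelengths x 7 evenly
spaced orientations per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import gabor_kernel


@dataclass
class PatchSpec:
    """Odd-sized patch geometry; ``depth > 1`` extracts a 3-D cube."""

    height: int = 15
    width: int = 15
    channels: int = 1
    depth: int = 1

    def __post_init__(self) -> None:
        if self.height % 2 == 0 or self.width % 2 == 0:
            raise ValueError("patch height and width must be odd")
        if self.depth > 1 and self.depth % 2 == 0:
            raise ValueError("patch depth must be odd")

    @property
    def length(self) -> int:
        return self.height * self.width * self.channels * self.depth


@dataclass
class GaborBankSpec:
    """Gabor bank geometry: scales x orientations x channels."""

    scale_count: int = 4
    orientation_count: int = 7
    channels: int = 3

    @property
    def length(self) -> int:
        return self.scale_count * self.orientation_count * self.channels


def _to_unit_float(image: np.ndarray) -> np.ndarray:
    """Scale integer images by their dtype range; pass floats through."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(float) / np.iinfo(image.dtype).max
    return image.astype(float)


def extract_patches(
    image: np.ndarray,
    points: np.ndarray,
    spec: PatchSpec | None = None,
) -> np.ndarray:
    """Flattened local patches centered on each sampled point.

    ``image`` is (H, W), (H, W, C) for 2-D inputs or (D, H, W) for
    volumes; ``points`` are (row, col) or (slice, row, col) positions.
    Borders are reflect-padded.  Flattening is row-major over
    (row, col, channel) for 2-D and (slice, row, col) for 3-D.
    """
    spec = spec or PatchSpec()
    image = _to_unit_float(image)
    points = np.atleast_2d(np.asarray(points, dtype=int))

    if spec.depth > 1:
        if image.ndim != 3:
            raise ValueError("3-D patches require a (D, H, W) volume")
        if points.shape[1] != 3:
            raise ValueError("3-D patches require (slice, row, col) points")
        pad_z, pad_r, pad_c = spec.depth // 2, spec.height // 2, spec.width // 2
        _check_bounds(points, image.shape)
        padded = np.pad(image, ((pad_z, pad_z), (pad_r, pad_r), (pad_c, pad_c)), mode="reflect")
        out = np.empty((points.shape[0], spec.length))
        for i, (z, r, c) in enumerate(points):
            cube = padded[z : z + spec.depth, r : r + spec.height, c : c + spec.width]
            out[i] = cube.ravel()
        return out

    if image.ndim == 2:
        image = image[:, :, None]
    if image.shape[2] != spec.channels:
        raise ValueError(
            f"image has {image.shape[2]} channels, spec expects {spec.channels}"
        )
    if points.shape[1] != 2:
        raise ValueError("2-D patches require (row, col) points")
    _check_bounds(points, image.shape[:2])
    pad_r, pad_c = spec.height // 2, spec.width // 2
    padded = np.pad(image, ((pad_r, pad_r), (pad_c, pad_c), (0, 0)), mode="reflect")
    out = np.empty((points.shape[0], spec.length))
    for i, (r, c) in enumerate(points):
        patch = padded[r : r + spec.height, c : c + spec.width, :]
        out[i] = patch.ravel()
    return out


def _check_bounds(points: np.ndarray, shape: tuple[int, ...]) -> None:
    for axis, size in enumerate(shape):
        coord = points[:, axis]
        if (coord < 0).any() or (coord >= size).any():
            bad = points[(coord < 0) | (coord >= size)][0]
            raise ValueError(f"point {tuple(bad)} outside image of shape {shape}")


def gabor_features(
    image: np.ndarray,
    points: np.ndarray,
    wavelengths: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0),
    n_orientations: int = 7,
) -> np.ndarray:
    """Modulus of 2-D Gabor responses sampled at each point.

    One response per (scale, orientation, channel), orientations evenly
    spaced in [0, pi); flattening follows that order.  Kernels are made
    exactly zero-mean (DC-free) so a constant image elicits no response.
    """
    image = _to_unit_float(image)
    if image.ndim == 2:
        image = image[:, :, None]
    points = np.atleast_2d(np.asarray(points, dtype=int))
    _check_bounds(points, image.shape[:2])
    for lam in wavelengths:
        if lam <= 0:
            raise ValueError(f"non-positive wavelength {lam}")
    thetas = np.arange(n_orientations) * np.pi / n_orientations
    rows, cols = points[:, 0], points[:, 1]
    feats = []
    for lam in wavelengths:
        for theta in thetas:
            kernel = gabor_kernel(frequency=1.0 / lam, theta=theta)
            kernel = kernel - kernel.mean()  # remove the DC component
            for ch in range(image.shape[2]):
                chan = image[:, :, ch]
                real = ndi.convolve(chan, np.real(kernel), mode="reflect")
                imag = ndi.convolve(chan, np.imag(kernel), mode="reflect")
                feats.append(np.hypot(real, imag)[rows, cols])
    return np.column_stack(feats)


def gabor_orientation_grid(n_orientations: int = 7) -> np.ndarray:
    """The bank's orientation angles, evenly spaced in [0, pi)."""
    return np.arange(n_orientations) * np.pi / n_orientations


def sample_pixels(
    mask: np.ndarray,
    n_pos: int,
    n_neg: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw pixel positions from each class of a binary ground-truth mask.

    Uniform without-replacement draws of ``n_pos`` foreground and
    ``n_neg`` background pixels; returns ``(points, labels)`` with
    points as (row, col) pairs and labels 1 for foreground.
    """
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)
    pos = np.argwhere(mask)
    neg = np.argwhere(~mask)
    if pos.shape[0] < n_pos:
        raise ValueError(f"only {pos.shape[0]} positive pixels, need {n_pos}")
    if neg.shape[0] < n_neg:
        raise ValueError(f"only {neg.shape[0]} negative pixels, need {n_neg}")
    pos_sel = pos[rng.choice(pos.shape[0], size=n_pos, replace=False)]
    neg_sel = neg[rng.choice(neg.shape[0], size=n_neg, replace=False)]
    points = np.vstack([pos_sel, neg_sel])
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return points, labels
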