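"""Retina/LGN-style preprocessing and patch geometry.

Images are plain 2-D float arrays. Preprocessing applies DC removal and a
radially symmetric whitening/lowpass filter with gain profile
``W(f) = f * exp(-(f/f0)^4)`` (f in cycles/image). Training patches are
30x30, mean-subtracted and variance-normalized, and are decomposed into
nine 12x12 sub-patches overlapping by 3 pixels — one per level-1 module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TilingGeometry",
    "FrequencyFilter",
    "remove_dc",
    "whitening_gain",
    "build_whitening_filter",
    "whiten",
    "preprocess_image",
    "sample_patch_batch",
    "tile_patch",
    "untile",
]


@dataclass(frozen=True)
class TilingGeometry:
    """Tiling of a square input patch into overlapping square windows.

    The default geometry (30 -> nine 12x12 windows overlapping by 3 px)
    has window starts {0, 9, 18} x {0, 9, 18}, enumerated row-major.
    """

    patch_size: int = 30
    sub_size: int = 12
    overlap: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.sub_size <= self.patch_size):
            raise ValueError("sub_size must be in (0, patch_size]")
        if not (0 <= self.overlap < self.sub_size):
            raise ValueError("overlap must be in [0, sub_size)")
        if self.sub_size < self.patch_size:
            stride = self.sub_size - self.overlap
            if (self.patch_size - self.sub_size) % stride != 0:
                raise ValueError(
                    "patch_size - sub_size must be divisible by sub_size - overlap"
                )

    @property
    def stride(self) -> int:
        return self.sub_size - self.overlap

    @property
    def starts(self) -> tuple[int, ...]:
        if self.patch_size == self.sub_size:
            return (0,)
        return tuple(range(0, self.patch_size - self.sub_size + 1, self.stride))

    @property
    def windows(self) -> tuple[tuple[int, int], ...]:
        """(row_start, col_start) of each window, row-major order."""
        return tuple((r, c) for r in self.starts for c in self.starts)

    @property
    def n_modules(self) -> int:
        return len(self.windows)

    @property
    def sub_dim(self) -> int:
        return self.sub_size * self.sub_size

    def coverage_counts(self) -> np.ndarray:
        """How many windows cover each pixel of the patch."""
        n = np.zeros((self.patch_size, self.patch_size))
        for r, c in self.windows:
            n[r : r + self.sub_size, c : c + self.sub_size] += 1.0
        return n


def remove_dc(image: np.ndarray) -> np.ndarray:
    """Subtract the mean intensity; shape is preserved."""
    image = np.asarray(image, dtype=float)
    return image - image.mean()


def whitening_gain(f, f0: float):
    """Whitening/lowpass gain ``W(f) = f * exp(-(f/f0)^4)``."""
    f = np.asarray(f, dtype=float)
    return f * np.exp(-((f / f0) ** 4))


@dataclass(frozen=True)
class FrequencyFilter:
    """Radially symmetric frequency-domain gains on an n x n FFT grid.

    ``gains`` is laid out to match ``numpy.fft.fft2`` output (DC at [0, 0]);
    the DC gain is exactly zero.
    """

    gains: np.ndarray
    f0: float

    @property
    def size(self) -> int:
        return self.gains.shape[0]

    def impulse_response(self) -> np.ndarray:
        """Spatial kernel of the equivalent circular convolution."""
        return np.real(np.fft.ifft2(self.gains))


def build_whitening_filter(n: int, f0: float) -> FrequencyFilter:
    """Build the whitening filter for an n x n image.

    Frequencies are measured in cycles/image of the n x n grid; callers
    working at a different image size than the filter was calibrated for
    should rescale ``f0`` proportionally (``f0 * n / 512`` for the printed
    200 cycles/image on 512 px training images).
    """
    if n < 2:
        raise ValueError("grid size must be >= 2")
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    fr = np.fft.fftfreq(n, d=1.0 / n)
    f = np.hypot(fr[:, None], fr[None, :])
    return FrequencyFilter(gains=whitening_gain(f, f0), f0=float(f0))


def whiten(image: np.ndarray, filt: FrequencyFilter) -> np.ndarray:
    """Apply the filter in the frequency domain (circular boundary)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    if image.shape[0] != filt.size:
        raise ValueError(
            f"image size {image.shape[0]} does not match filter size {filt.size}"
        )
    return np.real(np.fft.ifft2(np.fft.fft2(image) * filt.gains))


def preprocess_image(image: np.ndarray, f0: float = 200.0, ref_size: int = 512) -> np.ndarray:
    """DC removal followed by whitening, with f0 scaled to the image size."""
    image = remove_dc(image)
    n = image.shape[0]
    filt = build_whitening_filter(n, f0 * n / ref_size)
    return whiten(image, filt)


def sample_patch_batch(
    images,
    count: int,
    seed,
    patch_size: int = 30,
    normalization: str = "patch",
) -> np.ndarray:
    """Sample ``count`` mean-zero, variance-normalized patches.

    ``seed`` may be an int or a ``numpy.random.Generator``. With
    ``normalization="patch"`` every patch is scaled to unit variance
    individually; with ``"batch"`` the whole batch is scaled by one factor
    (unit average variance), preserving the natural contrast variation
    across patches. Degenerate (zero-variance) draws are resampled, never
    emitted.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if normalization not in ("patch", "batch"):
        raise ValueError("normalization must be 'patch' or 'batch'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    images = [np.asarray(im, dtype=float) for im in images]
    for im in images:
        if im.shape[0] < patch_size or im.shape[1] < patch_size:
            raise ValueError("every image must be at least patch_size on each side")
    out = np.empty((count, patch_size, patch_size))
    filled = 0
    attempts = 0
    while filled < count:
        attempts += 1
        if attempts > 1000 * count:
            raise RuntimeError("could not sample non-degenerate patches")
        im = images[int(rng.integers(len(images)))]
        r = int(rng.integers(im.shape[0] - patch_size + 1))
        c = int(rng.integers(im.shape[1] - patch_size + 1))
        patch = im[r : r + patch_size, c : c + patch_size].copy()
        patch -= patch.mean()
        v = patch.var()
        if v < 1e-12:
            continue
        out[filled] = patch / np.sqrt(v) if normalization == "patch" else patch
        filled += 1
    if normalization == "batch":
        out /= np.sqrt(out.var(axis=(1, 2)).mean())
    return out


def tile_patch(patch: np.ndarray, geometry: TilingGeometry) -> np.ndarray:
    """Split a patch into its windows -> array (n_modules, sub, sub)."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (geometry.patch_size, geometry.patch_size):
        raise ValueError(
            f"patch must be {geometry.patch_size}x{geometry.patch_size}, got {patch.shape}"
        )
    s = geometry.sub_size
    return np.stack([patch[r : r + s, c : c + s] for r, c in geometry.windows])


def untile(sub_images: np.ndarray, geometry: TilingGeometry) -> np.ndarray:
    """Reassemble windows into a patch, averaging overlapping pixels."""
    sub_images = np.asarray(sub_images, dtype=float)
    s = geometry.sub_size
    if sub_images.shape != (geometry.n_modules, s, s):
        raise ValueError("sub_images must have shape (n_modules, sub, sub)")
    acc = np.zeros((geometry.patch_size, geometry.patch_size))
    for sub, (r, c) in zip(sub_images, geometry.windows):
        acc[r : r + s, c : c + s] += sub
    return acc / geometry.coverage_counts()
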