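"""Surrogate natural images and bar-stimulus batteries.

The surrogate images stand in for natural photographs: 1/f-amplitude
random-phase noise with opaque elongated segments composited on top. Three
segment layouts are available — independent dead leaves ("leaves"),
spatially clustered segments with locally coherent orientation
("clustered"), and a dense coherent fine texture ("grass") — plus a
masonry-like periodic partition used only in the training ensemble.
Segment edges can be softened (optics-style blur); the noise floor is
composited unblurred so the pure-noise amplitude spectrum stays exactly
1/f. Test stimuli are 30x30 frames with horizontal bars drawn at a single
amplitude on a zero background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "STIM_SIZE",
    "BarSpec",
    "Stimulus",
    "generate_surrogate_image",
    "make_training_ensemble",
    "make_shifting_bar",
    "shifting_bar_battery",
    "make_bar_pair",
    "make_nonlinearity_stimuli",
]

STIM_SIZE = 30
#: inclusive column/row range of the default central 8x8 blind spot
_BS_LO, _BS_HI = 11, 18


@dataclass(frozen=True)
class BarSpec:
    """Geometry of a horizontal test bar.

    ``row`` is the top row of the bar; the bar covers rows
    [row, row + thickness). Columns are 0-based inclusive.
    """

    row: int = 12
    thickness: int = 3
    amplitude: float = -8.0
    col_start: int = 2
    col_end: int = 27

    def __post_init__(self) -> None:
        if not (0 <= self.col_start <= self.col_end <= STIM_SIZE - 1):
            raise ValueError("require 0 <= col_start <= col_end <= 29")
        if self.thickness < 1:
            raise ValueError("thickness must be >= 1")
        if self.amplitude == 0:
            raise ValueError("amplitude must be nonzero")
        if not (0 <= self.row and self.row + self.thickness <= STIM_SIZE):
            raise ValueError("bar rows fall outside the 30x30 frame")


@dataclass(frozen=True)
class Stimulus:
    """A labelled 30x30 test frame (background 0, bar at one amplitude)."""

    label: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.shape != (STIM_SIZE, STIM_SIZE):
            raise ValueError("stimulus must be 30x30")
        object.__setattr__(self, "pixels", px)


def _noise_1f(width: int, height: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance random-phase noise with amplitude spectrum 1/f."""
    fy = np.fft.fftfreq(height, d=1.0 / height)[:, None]
    fx = np.fft.fftfreq(width, d=1.0 / width)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = 1.0 / f[nz]
    spectrum = np.fft.fft2(rng.standard_normal((height, width))) * amp
    img = np.real(np.fft.ifft2(spectrum))
    return img / img.std()


class _SegmentLayer:
    """Accumulates opaque segments (later draws occlude earlier ones)."""

    def __init__(self, width: int, height: int):
        self.values = np.zeros((height, width))
        self.cover = np.zeros((height, width))
        self.yy, self.xx = np.mgrid[0:height, 0:width].astype(float)

    def draw(self, cy, cx, theta, half_len, half_wid, intensity) -> None:
        dy = self.yy - cy
        dx = self.xx - cx
        along = dx * np.cos(theta) + dy * np.sin(theta)
        across = -dx * np.sin(theta) + dy * np.cos(theta)
        sel = (np.abs(along) <= half_len) & (np.abs(across) <= half_wid)
        self.values[sel] = intensity
        self.cover[sel] = 1.0

    def composite(self, noise: np.ndarray, blur: float) -> np.ndarray:
        """Overlay the (optionally edge-softened) segments on the noise."""
        if blur > 0:
            m = gaussian_filter(self.cover, blur)
            v = gaussian_filter(self.values, blur)
        else:
            m, v = self.cover, self.values
        return noise * (1.0 - m) + v


def _rand_intensity(rng) -> float:
    return float(rng.uniform(0.3, 2.5) * rng.choice((-1.0, 1.0)))


def _draw_leaves(layer, rng, n_segments, min_dim) -> None:
    for _ in range(n_segments):
        layer.draw(
            rng.uniform(0, layer.values.shape[0]),
            rng.uniform(0, layer.values.shape[1]),
            rng.uniform(0, np.pi),
            0.5 * rng.uniform(0.15, 0.7) * min_dim,
            rng.uniform(0.5, 4.0),
            _rand_intensity(rng),
        )


def _draw_clustered(layer, rng, n_segments, min_dim, n_clusters: int = 8) -> None:
    h, w = layer.values.shape
    # a few very large leaves provide flat low-contrast regions
    for _ in range(max(1, n_segments // 100)):
        layer.draw(
            rng.uniform(0, h), rng.uniform(0, w), rng.uniform(0, np.pi),
            0.5 * rng.uniform(0.5, 1.0) * min_dim, rng.uniform(15, 50),
            float(rng.uniform(0.1, 1.0) * rng.choice((-1.0, 1.0))),
        )
    centers = rng.uniform(0, min_dim, size=(n_clusters, 2))
    base_theta = rng.uniform(0, np.pi, size=n_clusters)
    spread = rng.uniform(15, 60, size=n_clusters)
    for _ in range(n_segments):
        c = int(rng.integers(n_clusters))
        layer.draw(
            centers[c, 0] + rng.normal(0, spread[c]),
            centers[c, 1] + rng.normal(0, spread[c]),
            base_theta[c] + rng.normal(0, 0.25),
            0.5 * 4.0 * ((0.5 * min_dim) / 4.0) ** rng.power(0.4),
            rng.uniform(0.5, 2.5),
            _rand_intensity(rng),
        )


def _draw_grass(layer, rng, n_segments, min_dim) -> None:
    h, w = layer.values.shape
    theta0 = rng.uniform(0, np.pi)
    for _ in range(n_segments):
        layer.draw(
            rng.uniform(0, h), rng.uniform(0, w),
            theta0 + rng.normal(0, 0.18),
            rng.uniform(5, 25), rng.uniform(0.5, 1.5),
            _rand_intensity(rng),
        )


def _draw_brick(layer, rng, min_dim) -> None:
    """Masonry-like partition: brick fills plus thin dark mortar segments."""
    h, w = layer.values.shape
    bh = rng.uniform(12, 24)
    bw = rng.uniform(24, 48)
    mortar = rng.uniform(1.5, 2.5)
    mortar_int = rng.uniform(-1.5, -0.5)
    for r in range(int(h // bh) + 2):
        y = r * bh
        layer.draw(y, w / 2, 0.0, w, mortar / 2, mortar_int)
        off = (r % 2) * bw / 2
        for c in range(int(w // bw) + 2):
            x = c * bw + off
            layer.draw(y + bh / 2, x, np.pi / 2, bh / 2, mortar / 2, mortar_int)
            layer.draw(
                y + bh / 2, x + bw / 2, 0.0,
                bw / 2 - mortar, bh / 2 - mortar, float(rng.uniform(0.2, 1.2)),
            )


_NOISE_SCALE = {"leaves": 1.0, "clustered": 0.1, "grass": 0.05, "brick": 0.05}


def generate_surrogate_image(
    width: int,
    height: int,
    n_segments: int = 40,
    seed: int = 0,
    style: str = "leaves",
    blur: float = 0.0,
) -> np.ndarray:
    """Generate a surrogate natural image.

    The background is random-phase noise with amplitude spectrum
    proportional to 1/f; ``n_segments`` opaque elongated segments of
    random orientation, length, width and intensity are composited on top
    (later segments occlude earlier ones). ``style`` selects the segment
    layout ("leaves", "clustered", "grass", "brick"); ``blur`` softens
    segment edges only, so with ``n_segments=0`` the output is exactly the
    1/f noise. Deterministic given ``seed``.
    """
    if width < 64 or height < 64:
        raise ValueError("width and height must be >= 64")
    if n_segments < 0:
        raise ValueError("n_segments must be >= 0")
    if style not in _NOISE_SCALE:
        raise ValueError(f"unknown style {style!r}")
    rng = np.random.default_rng(seed)
    noise = _noise_1f(width, height, rng)
    if n_segments == 0:
        return noise
    noise = noise * _NOISE_SCALE[style]
    layer = _SegmentLayer(width, height)
    min_dim = min(width, height)
    if style == "leaves":
        _draw_leaves(layer, rng, n_segments, min_dim)
    elif style == "clustered":
        _draw_clustered(layer, rng, n_segments, min_dim)
    elif style == "grass":
        _draw_grass(layer, rng, n_segments, min_dim)
    else:
        _draw_brick(layer, rng, min_dim)
    return layer.composite(noise, blur)


def make_training_ensemble(
    count: int = 6, size: int = 256, seed: int = 0, blur: float = 0.8
) -> list[np.ndarray]:
    """The surrogate stand-ins for the six training photographs.

    Styles cycle through clustered scenes, coherent fine texture and
    masonry so the ensemble spans flat regions, long edges and dense
    oriented texture.
    """
    spec = [("clustered", 600), ("grass", 2500), ("brick", 1)]
    images = []
    for i in range(count):
        style, nseg = spec[(i // 2) % len(spec)]
        images.append(
            generate_surrogate_image(size, size, nseg, seed=seed * 1000 + i,
                                     style=style, blur=blur)
        )
    return images


def _blank() -> np.ndarray:
    return np.zeros((STIM_SIZE, STIM_SIZE))


def _draw_bar(px: np.ndarray, spec: BarSpec, c0: int, c1: int, row=None) -> None:
    r = spec.row if row is None else row
    if not (0 <= r and r + spec.thickness <= STIM_SIZE):
        raise ValueError("bar rows fall outside the 30x30 frame")
    px[r : r + spec.thickness, c0 : c1 + 1] = spec.amplitude


def make_shifting_bar(spec: BarSpec, end_col: int) -> Stimulus:
    """Horizontal bar from ``spec.col_start`` through ``end_col``."""
    if not (0 <= end_col <= STIM_SIZE - 1):
        raise ValueError("end_col must lie in 0..29")
    if end_col < spec.col_start:
        raise ValueError("end_col must be >= col_start")
    px = _blank()
    _draw_bar(px, spec, spec.col_start, end_col)
    return Stimulus(label=f"shift_{end_col:02d}", pixels=px)


def shifting_bar_battery(spec: BarSpec, end_cols=range(4, 28)) -> list[Stimulus]:
    """The 1-px shifting-bar sweep (default end columns 4..27)."""
    return [make_shifting_bar(spec, int(e)) for e in end_cols]


def make_bar_pair(
    spec: BarSpec,
    vertical_offset: int,
    bs_cols: tuple[int, int] = (_BS_LO, _BS_HI),
) -> Stimulus:
    """Two bar segments flanking the blind spot.

    The left segment sits at ``spec.row``; the right one is shifted
    vertically by ``vertical_offset`` pixels. Neither segment enters the
    blind-spot columns.
    """
    if abs(vertical_offset) > 3:
        raise ValueError("vertical_offset must lie in -3..+3")
    right_row = spec.row + vertical_offset
    if not (0 <= right_row and right_row + spec.thickness <= STIM_SIZE):
        raise ValueError("offset pushes the right segment outside the frame")
    px = _blank()
    _draw_bar(px, spec, spec.col_start, bs_cols[0] - 1)
    _draw_bar(px, spec, bs_cols[1] + 1, spec.col_end, row=right_row)
    return Stimulus(label=f"pair_{vertical_offset:+d}", pixels=px)


def make_nonlinearity_stimuli(
    spec: BarSpec, bs_cols: tuple[int, int] = (_BS_LO, _BS_HI)
) -> dict[str, Stimulus]:
    """Build the a/b/c/ab battery.

    a: left flank segment ending at the blind-spot border;
    b: right flank segment starting at the border;
    c: short control segment confined inside the blind spot;
    ab: pixelwise union of a and b.
    """
    a = _blank()
    _draw_bar(a, spec, spec.col_start, bs_cols[0] - 1)
    b = _blank()
    _draw_bar(b, spec, bs_cols[1] + 1, spec.col_end)
    c = _blank()
    mid = (bs_cols[0] + bs_cols[1]) // 2
    _draw_bar(c, spec, mid - 1, mid + 2)
    ab = a + b  # disjoint footprints, so the sum is the union
    return {
        "a": Stimulus("a", a),
        "b": Stimulus("b", b),
        "c": Stimulus("c", c),
        "ab": Stimulus("ab", ab),
    }
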