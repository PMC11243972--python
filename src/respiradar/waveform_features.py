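"""Waveform rendering, HOG descriptors and PCA reduction.

Breathing-pattern classification operates on *images* of the normalised
respiration waveform: each record is drawn as a fixed-style 256 x 256
grayscale plot, described by a histogram-of-oriented-gradients (HOG)
feature vector, and reduced with PCA before classification.

The HOG pipeline: per-pixel gradients by centred differences
(``G = sqrt(Gx**2 + Gy**2)``, orientation ``atan2`` folded to [0, 180)),
magnitude-weighted orientation histograms with 9 bins per 8 x 8-pixel cell
(bilinear vote splitting between adjacent bin centres, circular over 180),
L2-normalised 2 x 2-cell blocks at 1-cell stride, all block vectors
concatenated.  On 256 x 256 inputs the default geometry yields
31 * 31 * 4 * 9 = 34596 features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from sklearn.decomposition import PCA

from .breath_metrics import NormalizedWaveform

__all__ = [
    "WaveformImage",
    "GradientField",
    "HogGeometry",
    "HogDescriptor",
    "PcaModel",
    "render_image",
    "gradients",
    "hog",
    "fit_pca",
    "project",
]

#: Rendering style, frozen so images (and thus descriptors) are bit
#: reproducible across runs: y-limits just beyond the normalised amplitude
#: range, a 2-px line at output scale drawn at 4x supersampling.
IMAGE_SIZE = 256
Y_LIMITS = (-1.1, 1.1)
LINE_WIDTH = 2
SUPERSAMPLE = 4


@dataclass
class WaveformImage:
    """256 x 256 grayscale image, intensities in [0, 1] (1 = white)."""

    pixels: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"image must be {IMAGE_SIZE} x {IMAGE_SIZE}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")


@dataclass
class GradientField:
    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray       # degrees in [0, 180)


@dataclass(frozen=True)
class HogGeometry:
    cell_size: int = 8
    block_cells: int = 2          # block is block_cells x block_cells cells
    block_stride: int = 1         # in cells
    n_bins: int = 9

    def descriptor_length(self, image_size: int = IMAGE_SIZE) -> int:
        if image_size % self.cell_size:
            raise ValueError("image size must be divisible by cell size")
        cells = image_size // self.cell_size
        blocks = (cells - self.block_cells) // self.block_stride + 1
        return blocks * blocks * self.block_cells ** 2 * self.n_bins


@dataclass
class HogDescriptor:
    vector: np.ndarray
    geometry: HogGeometry


@dataclass
class PcaModel:
    mean: np.ndarray
    components: np.ndarray                 # (m, d), rows orthonormal
    explained_variance_ratio: np.ndarray


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_image(waveform: NormalizedWaveform,
                 label: str | None = None) -> WaveformImage:
    """Deterministic grayscale plot of a normalised waveform.

    Time spans the full width, amplitude maps to fixed y-limits
    (-1.1, 1.1), and the trace is a dark polyline on a white background
    with no axes or ticks.  Drawn at 4x resolution and box-downsampled to
    256 x 256 so the line is smooth but rendering stays exactly
    reproducible.
    """
    values = np.asarray(waveform.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty waveform")
    big = IMAGE_SIZE * SUPERSAMPLE
    img = Image.new("L", (big, big), color=255)
    draw = ImageDraw.Draw(img)
    xs = np.linspace(0, big - 1, len(values))
    lo, hi = Y_LIMITS
    ys = (hi - values) / (hi - lo) * (big - 1)
    points = list(zip(xs.tolist(), ys.tolist()))
    if len(points) == 1:
        points = points * 2
    draw.line(points, fill=0, width=LINE_WIDTH * SUPERSAMPLE, joint="curve")
    small = img.resize((IMAGE_SIZE, IMAGE_SIZE), resample=Image.Resampling.BOX)
    pixels = np.asarray(small, dtype=float) / 255.0
    if label is None and getattr(waveform, "label", None) is not None:
        label = waveform.label
    return WaveformImage(pixels=pixels, label=label)


# ---------------------------------------------------------------------------
# Gradients and HOG
# ---------------------------------------------------------------------------

def gradients(image: WaveformImage | np.ndarray) -> GradientField:
    """Centred-difference gradients with replicated borders.

    ``Gx[r, c] = I[r, c+1] - I[r, c-1]`` (and analogously ``Gy`` down the
    rows); magnitude ``sqrt(Gx**2 + Gy**2)``; orientation
    ``atan2(Gy, Gx)`` in degrees folded to [0, 180).
    """
    pix = image.pixels if isinstance(image, WaveformImage) else np.asarray(image, float)
    padded = np.pad(pix, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    mag = np.hypot(gx, gy)
    ori = np.degrees(np.arctan2(gy, gx)) % 180.0
    return GradientField(gx=gx, gy=gy, magnitude=mag, orientation=ori)


def _cell_histograms(mag: np.ndarray, ori: np.ndarray,
                     geometry: HogGeometry) -> np.ndarray:
    """Per-cell orientation histograms, shape (cells_y, cells_x, n_bins)."""
    h, w = mag.shape
    cs, nb = geometry.cell_size, geometry.n_bins
    bin_width = 180.0 / nb
    # Bilinear vote splitting between the two adjacent bin centres
    # (centres at (b + 0.5) * bin_width), circular modulo 180.
    pos = ori / bin_width - 0.5
    lower = np.floor(pos).astype(int)
    frac = pos - lower
    lower %= nb
    upper = (lower + 1) % nb
    votes = np.zeros((h, w, nb))
    rows, cols = np.indices((h, w))
    np.add.at(votes, (rows, cols, lower), mag * (1.0 - frac))
    np.add.at(votes, (rows, cols, upper), mag * frac)
    return votes.reshape(h // cs, cs, w // cs, cs, nb).sum(axis=(1, 3))


def hog(image: WaveformImage | np.ndarray,
        geometry: HogGeometry = HogGeometry()) -> HogDescriptor:
    """HOG descriptor: cell histograms -> L2-normalised blocks -> concat.

    Blocks and the cells within each block are traversed row-major; bins
    are the fastest-varying axis.  Block vectors are normalised as
    ``v / sqrt(|v|**2 + eps)`` so a constant image maps to the zero vector.
    """
    pix = image.pixels if isinstance(image, WaveformImage) else np.asarray(image, float)
    h, w = pix.shape
    if h % geometry.cell_size or w % geometry.cell_size:
        raise ValueError("image dimensions must be divisible by cell size")
    field_ = gradients(pix)
    cells = _cell_histograms(field_.magnitude, field_.orientation, geometry)
    cy, cx, nb = cells.shape
    bc, stride = geometry.block_cells, geometry.block_stride
    nby = (cy - bc) // stride + 1
    nbx = (cx - bc) // stride + 1
    eps = 1e-12
    out = np.empty((nby, nbx, bc * bc * nb))
    for dy in range(bc):
        for dx in range(bc):
            sl = cells[dy:dy + nby * stride:stride, dx:dx + nbx * stride:stride]
            out[:, :, (dy * bc + dx) * nb:(dy * bc + dx + 1) * nb] = sl
    norms = np.sqrt((out ** 2).sum(axis=2, keepdims=True) + eps)
    out = out / norms
    return HogDescriptor(vector=out.reshape(-1), geometry=geometry)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(descriptors: np.ndarray | list, n_components: int | None = None,
            variance_target: float = 0.95) -> PcaModel:
    """Fit PCA on stacked descriptors.

    Samples are centred by the mean and the covariance eigendecomposed;
    the top-``m`` unit eigenvectors are retained.  With
    ``n_components=None``, ``m`` is the smallest count reaching
    ``variance_target`` cumulative explained variance.  ``m`` is always
    capped at ``n_samples - 1`` (warning when the request exceeds it).
    """
    x = np.asarray([d.vector if isinstance(d, HogDescriptor) else d
                    for d in descriptors], dtype=float)
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples to fit PCA")
    cap = min(n - 1, d)
    if n_components is None:
        m = variance_target      # sklearn interprets a float as a variance target
    else:
        m = n_components
        if m > cap:
            warnings.warn(f"n_components={m} capped to {cap}")
            m = cap
    pca = PCA(n_components=m, svd_solver="full")
    pca.fit(x)
    return PcaModel(mean=pca.mean_, components=pca.components_,
                    explained_variance_ratio=pca.explained_variance_ratio_)


def project(model: PcaModel, descriptor: HogDescriptor | np.ndarray) -> np.ndarray:
    """Project centred descriptor(s) onto the retained components."""
    x = descriptor.vector if isinstance(descriptor, HogDescriptor) else np.asarray(descriptor, float)
    if x.shape[-1] != model.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: descriptor has {x.shape[-1]}, model expects "
            f"{model.mean.shape[0]}")
    return (x - model.mean) @ model.components.T
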