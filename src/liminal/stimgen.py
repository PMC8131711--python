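"""Stimulus synthesis at calibrated contrast.

Object photographs are reduced to grayscale grids, standardized, lightly
smoothed, optionally phase-scrambled (amplitude spectrum preserved, phases
randomized), faded to the background at the edges with a Gaussian window,
rescaled to [-1, 1], and finally mapped to display intensities around a
constant background ``b`` via

    I(c) = b * (I_scaled * c + 1)

so that the displayed Michelson-style contrast is recoverable as
``c = (I_max - I_min) / (2 b)`` whenever the scaled image spans the full
[-1, 1] range.

The processing order is standardize -> smooth -> (scramble) -> edge-window ->
rescale -> contrast.  Display intensities are kept as floats; 8-bit
quantization happens only on export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BACKGROUND_INTENSITY = 127.0

CATEGORIES = ("face", "animal", "house", "object")


class DegenerateImageError(ValueError):
    """Raised for images that cannot be standardized (zero variance)."""


def gaussian_kernel_2d(sigma: float = 1.5, size: int = 7) -> np.ndarray:
    """Normalized discrete 2-D Gaussian kernel (default 7x7, sigma 1.5 px)."""
    if sigma <= 0 or size < 1:
        raise ValueError("sigma and size must be positive")
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def standardize(raw: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sd version of ``raw``.

    Raises
    ------
    DegenerateImageError
        if the image is constant (sd = 0).
    """
    raw = np.asarray(raw, dtype=float)
    sd = raw.std()
    if sd == 0:
        raise DegenerateImageError("constant image has zero standard deviation")
    return (raw - raw.mean()) / sd


def standardize_and_smooth(
    raw: np.ndarray, sigma: float = 1.5, kernel_size: int = 7
) -> np.ndarray:
    """Standardize then smooth with a normalized discrete Gaussian kernel.

    Border handling replicates edge pixels, matching common image-filtering
    practice.
    """
    from scipy import ndimage

    z = standardize(raw)
    k = gaussian_kernel_2d(sigma, kernel_size)
    return ndimage.convolve(z, k, mode="nearest")


def phase_scramble(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomize the 2-D Fourier phases of ``img``, keeping the amplitudes.

    Fresh phases are drawn with exact Hermitian symmetry (the phase field of
    the FFT of white Gaussian noise), so the inverse transform is real up to
    floating-point residue.  The DC phase is retained, preserving the pixel
    mean.  Deterministic under a fixed generator state.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    f = np.fft.fft2(img)
    amp = np.abs(f)
    noise_phase = np.angle(np.fft.fft2(rng.standard_normal(img.shape)))
    g = amp * np.exp(1j * noise_phase)
    g[0, 0] = f[0, 0]  # keep DC: mean intensity unchanged
    out = np.fft.ifft2(g)
    scale = max(np.abs(img).max(), 1.0)
    if np.abs(out.imag).max() > 1e-9 * scale:
        raise FloatingPointError("Hermitian symmetry violated in phase scramble")
    return out.real


def edge_window(shape: tuple[int, int], window_sd: float = 0.2) -> np.ndarray:
    """Centered 2-D Gaussian window, peak-normalized to 1.

    ``window_sd`` is a fraction of the image width (0.2 -> 60 px at 300 px).
    """
    if window_sd <= 0:
        raise ValueError("window_sd must be positive")
    rows, cols = shape
    sd = window_sd * cols
    y = np.arange(rows) - (rows - 1) / 2.0
    x = np.arange(cols) - (cols - 1) / 2.0
    wy = np.exp(-(y**2) / (2.0 * sd**2))
    wx = np.exp(-(x**2) / (2.0 * sd**2))
    return np.outer(wy, wx)


def apply_edge_window(img: np.ndarray, window_sd: float = 0.2) -> np.ndarray:
    """Fade image edges toward zero with a centered Gaussian window."""
    img = np.asarray(img, dtype=float)
    return img * edge_window(img.shape, window_sd)


def rescale_unit(img: np.ndarray) -> np.ndarray:
    """Affine rescale to span exactly [-1, 1]."""
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        raise DegenerateImageError("constant image cannot be rescaled to [-1, 1]")
    return 2.0 * (img - lo) / (hi - lo) - 1.0


def apply_contrast(
    scaled: np.ndarray, c: float, b: float = BACKGROUND_INTENSITY
) -> np.ndarray:
    """Map a [-1, 1] image to display intensities: I(c) = b (I_scaled c + 1)."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"contrast must lie in [0, 1], got {c}")
    scaled = np.asarray(scaled, dtype=float)
    if scaled.min() < -1.0 - 1e-9 or scaled.max() > 1.0 + 1e-9:
        raise ValueError("scaled image must lie within [-1, 1]")
    return b * (scaled * c + 1.0)


def measure_contrast(img: np.ndarray, b: float = BACKGROUND_INTENSITY) -> float:
    """Displayed contrast c = (I_max - I_min) / (2 b)."""
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    return float((img.max() - img.min()) / (2.0 * b))


@dataclass(frozen=True)
class Stimulus:
    """A display-ready stimulus with its generating parameters."""

    pixels: np.ndarray
    contrast: float
    background: float
    scrambled: bool
    stimulus_id: str = ""


def make_stimulus(
    raw: np.ndarray,
    contrast: float,
    *,
    scramble: bool = False,
    rng: np.random.Generator | None = None,
    sigma: float = 1.5,
    kernel_size: int = 7,
    window_sd: float = 0.2,
    background: float = BACKGROUND_INTENSITY,
    stimulus_id: str = "",
) -> Stimulus:
    """Run the full stimulus chain on a raw grayscale image.

    standardize -> smooth -> (phase-scramble) -> edge-window -> rescale ->
    contrast mapping around ``background``.
    """
    z = standardize_and_smooth(raw, sigma=sigma, kernel_size=kernel_size)
    if scramble:
        if rng is None:
            raise ValueError("phase scrambling requires an rng")
        z = phase_scramble(z, rng)
    z = apply_edge_window(z, window_sd)
    z = rescale_unit(z)
    pixels = apply_contrast(z, contrast, background)
    return Stimulus(pixels, contrast, background, scramble, stimulus_id)


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Quantize display intensities to 8-bit gray for export only."""
    return np.clip(np.round(pixels), 0, 255).astype(np.uint8)


def save_png(pixels: np.ndarray, path) -> None:
    """Write display intensities as an 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(to_uint8(pixels), mode="L").save(str(path), format="PNG")


def load_png(path) -> np.ndarray:
    """Read a grayscale PNG as a float RawImage grid (0-255)."""
    from PIL import Image

    with Image.open(str(path)) as img:
        return np.asarray(img.convert("L"), dtype=float)


def synthetic_photo(
    category: str, size: int = 300, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw a category-specific geometric 'photograph' on a gray canvas.

    Stand-ins for real object photographs (which are not redistributable):
    face = disk with two darker dots, animal = ellipse with triangular ears,
    house = square with triangular roof, object = cross.  Mild texture noise
    keeps the pixel sd strictly positive.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    rng = rng or np.random.default_rng(0)
    img = np.full((size, size), 110.0)
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    r = size / 5.0
    if category == "face":
        img[(yy - cy) ** 2 + (xx - cx) ** 2 < r**2] = 190.0
        for dx in (-r / 2.5, r / 2.5):
            img[(yy - (cy - r / 3)) ** 2 + (xx - (cx + dx)) ** 2 < (r / 6) ** 2] = 60.0
    elif category == "animal":
        body = ((yy - cy) / (0.7 * r)) ** 2 + ((xx - cx) / (1.4 * r)) ** 2 < 1.0
        img[body] = 175.0
        ears = (yy < cy - 0.4 * r) & (np.abs(xx - cx) > 0.8 * r) & (
            np.abs(xx - cx) < 1.3 * r
        ) & (yy > cy - r)
        img[ears] = 150.0
    elif category == "house":
        img[(np.abs(yy - cy) < r) & (np.abs(xx - cx) < r)] = 170.0
        roof = (yy < cy - r) & (yy > cy - 2 * r) & (np.abs(xx - cx) < (yy - (cy - 2 * r)))
        img[roof] = 80.0
    else:  # manmade object: a cross
        img[(np.abs(yy - cy) < r / 3) & (np.abs(xx - cx) < 1.3 * r)] = 200.0
        img[(np.abs(xx - cx) < r / 3) & (np.abs(yy - cy) < 1.3 * r)] = 200.0
    img += rng.normal(0.0, 3.0, img.shape)
    return np.clip(img, 0.0, 255.0)
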