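"""Seeded mammogram-like phantoms.

Real screening mammograms cannot be redistributed, so every downstream stage
of the pipeline (patch extraction, texture synthesis, simulated psychophysics)
is exercised on synthetic phantoms instead.  A phantom is a power-law
("lumpy background") Gaussian random field emulating fibroglandular tissue
texture, optionally with a superposed lesion whose appearance depends on one
of the four diagnostic categories used in screening databases:

``normal``
    background only, empty ROI mask.
``benign_no_callback``
    a single sharp-edged disc of low contrast (obviously benign finding).
``benign``
    a single fuzzy-edged mass with a Gaussian radial profile.
``cancer``
    a cluster of small high-contrast Gaussian blobs inside a compact disc,
    mimicking a microcalcification cluster; the mask is that disc.

All lesion parameters are stand-ins chosen for texture-statistics
separability, not radiological realism (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError
from .seeds import child_seed

__all__ = [
    "CLASS_LABELS",
    "PhantomParams",
    "Phantom",
    "generate_phantom",
    "generate_cohort",
]

#: The four diagnostic categories, in canonical order.
CLASS_LABELS = ("normal", "benign_no_callback", "benign", "cancer")

# Background intensity band after rescaling the random field.
_BG_LO, _BG_HI = 0.2, 0.8


@dataclass(frozen=True)
class PhantomParams:
    """Generator parameters for one phantom.

    Parameters
    ----------
    class_label
        One of :data:`CLASS_LABELS`.
    height, width
        Image size in pixels; at least 32 each.
    background_exponent
        Spectral slope beta of the 1/f**beta background power spectrum.
    blob_count_range
        Inclusive (lo, hi) number of blobs for the cancer cluster.
    blob_sigma_range
        Inclusive (lo, hi) Gaussian sigma of cluster blobs, pixels.
    blob_contrast
        Peak added intensity of cluster blobs, in (0, 1].
    seed
        Nonnegative integer seed; fixed seed gives a bit-identical phantom.
    """

    class_label: str = "normal"
    height: int = 128
    width: int = 128
    background_exponent: float = 3.0
    blob_count_range: tuple[int, int] = (5, 15)
    blob_sigma_range: tuple[float, float] = (1.0, 2.0)
    blob_contrast: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ParameterError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        if self.height < 32 or self.width < 32:
            raise ParameterError("height and width must be >= 32 pixels")
        lo, hi = self.blob_count_range
        if lo > hi or lo < 1:
            raise ParameterError("blob_count_range must be a nonempty range with lo >= 1")
        if not (0.0 < self.blob_contrast <= 1.0):
            raise ParameterError("blob_contrast must lie in (0, 1]")
        if self.background_exponent < 0:
            raise ParameterError("background_exponent must be nonnegative")


@dataclass(frozen=True)
class Phantom:
    """A generated phantom: image in [0,1], binary ROI mask, provenance."""

    image: np.ndarray
    roi_mask: np.ndarray
    class_label: str
    seed: int


def _powerlaw_background(height, width, beta, rng):
    """Isotropic Gaussian random field with power spectrum ~ 1/f**beta,
    min-max rescaled to [0.2, 0.8]."""
    white = rng.standard_normal((height, width))
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nonzero = f > 0
    # amplitude ~ f**(-beta/2) so that power ~ f**(-beta)
    amp[nonzero] = f[nonzero] ** (-beta / 2.0)
    field = np.fft.ifft2(np.fft.fft2(white) * amp).real
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:  # beta=0 edge case aside, the field is never flat
        return np.full((height, width), (_BG_LO + _BG_HI) / 2.0)
    return _BG_LO + (_BG_HI - _BG_LO) * (field - lo) / (hi - lo)


def _disc_mask(height, width, center, radius):
    yy, xx = np.ogrid[:height, :width]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _gaussian_bump(height, width, center, sigma):
    yy, xx = np.ogrid[:height, :width]
    return np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2.0 * sigma**2)))


def _lesion_center(rng, height, width, margin):
    """Uniform lesion center within the central region, `margin` px from edges.

    On images too small to honor the margin the center collapses to the middle
    (the draw still consumes rng state uniformly so seeds stay comparable).
    """
    mr = min(margin, (height - 1) // 2)
    mc = min(margin, (width - 1) // 2)
    r = int(rng.integers(mr, height - mr)) if height - mr > mr else height // 2
    c = int(rng.integers(mc, width - mc)) if width - mc > mc else width // 2
    return r, c


def generate_phantom(params: PhantomParams) -> Phantom:
    """Generate one phantom deterministically from its parameters.

    The background field is drawn first, then the class-specific lesion is
    superposed and the image clipped back to [0, 1].  For a fixed ``params``
    (seed included) the output is bit-identical across calls and platforms.
    """
    p = params  # validated in __post_init__
    rng = np.random.default_rng(p.seed)
    image = _powerlaw_background(p.height, p.width, p.background_exponent, rng)
    mask = np.zeros((p.height, p.width), dtype=np.uint8)

    if p.class_label == "benign_no_callback":
        radius = rng.uniform(8.0, 12.0)
        center = _lesion_center(rng, p.height, p.width, int(np.ceil(radius)) + 2)
        disc = _disc_mask(p.height, p.width, center, radius)
        image = image + 0.10 * disc
        mask[disc] = 1
    elif p.class_label == "benign":
        sigma = rng.uniform(6.0, 10.0)
        center = _lesion_center(rng, p.height, p.width, int(np.ceil(2 * sigma)) + 2)
        image = image + 0.18 * _gaussian_bump(p.height, p.width, center, sigma)
        # mask: full-width-at-half-maximum disc of the Gaussian profile
        mask[_disc_mask(p.height, p.width, center, sigma * np.sqrt(2.0 * np.log(2.0)))] = 1
    elif p.class_label == "cancer":
        cluster_radius = 12.0
        center = _lesion_center(rng, p.height, p.width, int(cluster_radius) + 2)
        n_blobs = int(rng.integers(p.blob_count_range[0], p.blob_count_range[1] + 1))
        for _ in range(n_blobs):
            # rejection-free: uniform in the disc via polar coordinates
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rad = cluster_radius * np.sqrt(rng.uniform())
            br = center[0] + rad * np.sin(theta)
            bc = center[1] + rad * np.cos(theta)
            sigma = rng.uniform(*p.blob_sigma_range)
            image = image + p.blob_contrast * _gaussian_bump(
                p.height, p.width, (br, bc), sigma
            )
        mask[_disc_mask(p.height, p.width, center, cluster_radius)] = 1

    return Phantom(
        image=np.clip(image, 0.0, 1.0),
        roi_mask=mask,
        class_label=p.class_label,
        seed=p.seed,
    )


def generate_cohort(n_per_class: int, size: int = 128, seed: int = 0,
                    base_params: PhantomParams | None = None) -> list[Phantom]:
    """Generate ``4 * n_per_class`` phantoms, exactly ``n_per_class`` per class.

    Per-phantom seeds are derived from the master seed with the package-wide
    hash (:func:`mammotex.seeds.child_seed` keyed by class index and replicate
    index), so cohorts are reproducible and individual phantoms can be
    regenerated in isolation.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    template = base_params or PhantomParams(height=size, width=size)
    cohort = []
    for ci, label in enumerate(CLASS_LABELS):
        for ri in range(n_per_class):
            params = replace(
                template,
                class_label=label,
                height=size,
                width=size,
                seed=child_seed(seed, ci, ri),
            )
            cohort.append(generate_phantom(params))
    return cohort
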