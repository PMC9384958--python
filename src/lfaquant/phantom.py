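"""Synthetic strip phantoms with known ground truth.

Renders images that mimic what a fixed-geometry CMOS strip reader captures: a
bright membrane background crossed by two darker bands — the test line, whose
depth grows with analyte concentration, and the control line, which is always
present. Every phantom comes with a ground-truth record (band centers and
noise-free depths), so detection, ratio and calibration code can be validated
pixel-for-pixel without hardware.

Band darkness follows a Langmuir saturation law

    depth(c) = amp_max * c / (c + k_half)

which is linear in concentration at low c and plateaus at ``amp_max`` — the
simplest form consistent with colour formation proportional to analyte capture
at low concentrations and the saturation seen on real strips at high ones.
With the default amplitudes (``amp_max=160``, ``control_amplitude=80``,
``k_half=300`` ng/ml) the test band matches the control band exactly at
300 ng/ml, so the test/control ratio crosses 1 there.

All phantom geometry (band widths, spacing, depths) is invented: real strip
dimensions are proprietary. The defaults are chosen to look like a plausible
640x480 reader capture and are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.ndimage
from scipy.stats import truncnorm

from .errors import ConfigError
from .image import RoiRect, StripImage

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "test_band_depth",
    "render_strip",
    "dilution_series",
    "strip_seed",
]


def _default_roi() -> RoiRect:
    return RoiRect(row0=220, col0=220, height=40, width=200)


@dataclass(frozen=True)
class PhantomConfig:
    """Full parametric description of a synthetic strip image.

    Geometry: the flow axis is the image width (sample wicks left to right);
    the test line sits upstream (left) of the control line by ``line_spacing``
    pixels. Band cross-sections along the flow axis are Gaussian with width
    ``band_sigma`` and are constant across the transverse axis.

    Optics / noise: ``background_level`` is the unstained membrane intensity;
    ``illumination_slope`` adds a linear ramp (counts per pixel, centered on
    the image) emulating uneven lighting; ``pixel_noise_sd`` is additive
    per-pixel Gaussian noise; ``strip_jitter_sd`` is the relative spread of a
    single multiplicative amplitude factor drawn once per strip, emulating
    strip-to-strip variation in line development.
    """

    image_height: int = 480
    image_width: int = 640
    roi: RoiRect = field(default_factory=_default_roi)
    background_level: float = 200.0
    control_center: int = 370  # image column of the control-line center
    line_spacing: int = 60  # test line this many px upstream of control
    band_sigma: float = 6.0
    control_amplitude: float = 80.0  # control-band depth below background
    amp_max: float = 160.0  # asymptotic test-band depth
    k_half: float = 300.0  # ng/ml at half-maximal test-band depth
    pixel_noise_sd: float = 2.0
    strip_jitter_sd: float = 0.07
    illumination_slope: float = 0.0
    rotation_deg: float = 0.0
    offset_px: float = 0.0

    @property
    def test_center(self) -> int:
        return self.control_center - self.line_spacing

    def validate(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ConfigError("image dimensions must be positive")
        if self.band_sigma <= 0:
            raise ConfigError("band_sigma must be > 0")
        if self.background_level - self.control_amplitude < 0:
            raise ConfigError("control band deeper than the background level")
        if self.amp_max > self.background_level:
            raise ConfigError("amp_max must not exceed background_level")
        if self.pixel_noise_sd < 0 or self.strip_jitter_sd < 0:
            raise ConfigError("noise parameters must be non-negative")
        img = StripImage(np.zeros((self.image_height, self.image_width), np.uint8))
        self.roi.check_within(img)
        lo, hi = self.roi.col0, self.roi.col0 + self.roi.width
        for name, c in (("control", self.control_center), ("test", self.test_center)):
            if not lo <= c < hi:
                raise ConfigError(
                    f"{name}-band center {c} lies outside the RoI columns [{lo}, {hi})"
                )

    def noise_free(self) -> "PhantomConfig":
        """Copy with pixel noise and strip jitter switched off."""
        return replace(self, pixel_noise_sd=0.0, strip_jitter_sd=0.0)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth for one rendered strip."""

    concentration: float  # ng/ml
    true_test_center: int  # image column
    true_control_center: int  # image column
    true_test_depth: float  # counts, after per-strip jitter, before pixel noise
    true_control_depth: float  # counts, same convention
    seed: int


def test_band_depth(concentration: float, cfg: PhantomConfig) -> float:
    """Noise-free test-band depth (counts below background) at a concentration.

    Langmuir form ``amp_max * c / (c + k_half)``: zero at c=0, strictly
    increasing, saturating at ``amp_max``. Equals ``control_amplitude`` at
    c = 300 ng/ml under the defaults.
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if concentration == 0:
        return 0.0
    return cfg.amp_max * concentration / (concentration + cfg.k_half)


def _jitter_factor(rng: np.random.Generator, sd: float) -> float:
    # Truncated at +-3 sd (symmetric, so the mean stays 1); never negative.
    if sd == 0:
        return 1.0
    return float(truncnorm.rvs(-3.0, 3.0, loc=1.0, scale=sd, random_state=rng))


def render_strip(
    concentration: float, cfg: PhantomConfig, seed: int
) -> tuple[StripImage, PhantomTruth]:
    """Render one synthetic strip image plus its ground truth.

    The image is ``background + illumination ramp - control band - test
    band``, each band Gaussian along the flow axis and constant across the
    transverse axis; both band amplitudes are scaled by one per-strip jitter
    factor, then per-pixel Gaussian noise is added, values are clipped to
    [0, 255] and quantised (round half-up), and any rotation/offset is applied
    last. Identical ``(concentration, cfg, seed)`` gives a bit-identical image.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)

    jitter = _jitter_factor(rng, cfg.strip_jitter_sd)
    test_depth = test_band_depth(concentration, cfg) * jitter
    control_depth = cfg.control_amplitude * jitter

    x = np.arange(cfg.image_width, dtype=float)
    row = cfg.background_level + cfg.illumination_slope * (
        x - (cfg.image_width - 1) / 2.0
    )
    two_s2 = 2.0 * cfg.band_sigma**2
    row = row - test_depth * np.exp(-((x - cfg.test_center) ** 2) / two_s2)
    row = row - control_depth * np.exp(-((x - cfg.control_center) ** 2) / two_s2)

    field_ = np.broadcast_to(row, (cfg.image_height, cfg.image_width)).copy()
    if cfg.pixel_noise_sd > 0:
        field_ += rng.normal(0.0, cfg.pixel_noise_sd, field_.shape)

    px = np.floor(field_ + 0.5).clip(0, 255).astype(np.uint8)

    if cfg.rotation_deg != 0.0:
        px = scipy.ndimage.rotate(
            px, cfg.rotation_deg, reshape=False, order=1, mode="nearest"
        )
    if cfg.offset_px != 0.0:
        px = scipy.ndimage.shift(px, (0.0, cfg.offset_px), order=1, mode="nearest")

    truth = PhantomTruth(
        concentration=float(concentration),
        true_test_center=cfg.test_center,
        true_control_center=cfg.control_center,
        true_test_depth=test_depth,
        true_control_depth=control_depth,
        seed=int(seed),
    )
    return StripImage(px), truth


def strip_seed(root_seed: int, conc_index: int, rep_index: int) -> int:
    """Stable per-strip seed derived from (root, concentration, replicate)."""
    ss = np.random.SeedSequence([int(root_seed), int(conc_index), int(rep_index)])
    return int(ss.generate_state(1)[0] % 2**31)


def dilution_series(
    concentrations: Sequence[float],
    replicates: int,
    cfg: PhantomConfig,
    seed: int,
) -> list[tuple[StripImage, PhantomTruth]]:
    """Render a full dilution series: every concentration times ``replicates``.

    Strips are ordered concentration-major. Per-strip seeds are derived from
    the root seed by stable hashing, so the same call is fully reproducible
    and individual strips can be re-rendered in isolation.
    """
    if len(concentrations) == 0:
        raise ValueError("concentration list must not be empty")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    out: list[tuple[StripImage, PhantomTruth]] = []
    for i, c in enumerate(concentrations):
        for j in range(replicates):
            out.append(render_strip(c, cfg, strip_seed(seed, i, j)))
    return out
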