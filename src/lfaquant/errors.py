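"""Exception hierarchy.

Detection failures carry a short machine-readable ``flag`` so batch runs can
record *why* a strip was rejected without parsing message text.
"""

from __future__ import annotations


class LfaQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(LfaQuantError):
    """Invalid configuration (bad geometry, impossible amplitudes, ...)."""


class ImageFormatError(LfaQuantError):
    """Unsupported or unreadable image file."""


class RoiError(LfaQuantError):
    """Region of interest does not fit inside the parent image."""


class DetectionError(LfaQuantError):
    """A line-detection stage rejected the strip."""

    flag: str = "detection_failed"


class NoControlLineError(DetectionError):
    """No control band found: the profile is flat in the control search band.

    A valid strip always develops a control line, so this aborts the
    measurement rather than reporting ratios from noise.
    """

    flag = "no_control_line"


class TestWindowError(DetectionError):
    """The test-line search window is empty after clipping to the profile."""

    flag = "test_window_out_of_profile"


class BackgroundTooSmallError(DetectionError):
    """Too few background pixels remain between the detected lines."""

    flag = "background_too_small"


class CalibrationError(LfaQuantError):
    """Calibration fit rejected (too few points or non-monotone curve)."""


class PipelineStageError(LfaQuantError):
    """Wraps an error raised inside :func:`analyze_strip`, naming the stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
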