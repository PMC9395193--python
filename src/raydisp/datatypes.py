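"""Shared domain types for the bony-ray quantification pipeline.

The central object is :class:`RayImage`, a registered two-channel view of a
single cropped bony-ray: a brightfield channel in which the intersegment
joints appear as darker vertical lines, and a GFP channel carrying the
osteoblast reporter signal.  Columns run along the proximal-distal axis of
the ray; by convention (``proximal_left=True``) low column indices are
proximal (anterior) and the amputation plane sits at high column indices.

Intensities are stored as floats and may dip slightly below zero: noisy or
offset-subtracted microscopy data routinely does, and clipping at zero would
bias every intensity-weighted statistic computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError


def _as_image(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValidationError(f"{name}: expected a non-empty 2-D intensity grid")
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{name}: non-finite intensity values")
    return a


@dataclass(frozen=True)
class RayImage:
    """Registered two-channel (brightfield + GFP) image of one bony-ray.

    Parameters
    ----------
    bf, gfp:
        2-D intensity grids of identical shape (rows x columns).
    pixel_size:
        Lateral pixel size in micrometres per pixel.
    proximal_left:
        True when the proximal (anterior) end of the ray is at low column
        indices, i.e. the amputation plane is on the right.
    amputation_column:
        Column index of the amputation plane, when known.
    """

    bf: np.ndarray
    gfp: np.ndarray
    pixel_size: float = 1.0
    proximal_left: bool = True
    amputation_column: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "bf", _as_image(self.bf, "bf"))
        object.__setattr__(self, "gfp", _as_image(self.gfp, "gfp"))
        if self.bf.shape != self.gfp.shape:
            raise ValidationError(
                f"gfp: shape {self.gfp.shape} does not match bf {self.bf.shape}"
            )
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size: must be > 0")
        if self.amputation_column is not None:
            if not 0 <= self.amputation_column < self.width:
                raise ValidationError(
                    "amputation_column: outside [0, image width)"
                )

    @property
    def height(self) -> int:
        return self.bf.shape[0]

    @property
    def width(self) -> int:
        return self.bf.shape[1]


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the intersegment-boundary detector.

    ``gaussian_sigma`` (2 px) and ``min_component_area`` (200 px) follow the
    original quantification workflow; the remaining knobs are implementation
    parameters with scale-free defaults.  ``profile_smoothing_sigma`` smooths
    the 1-D detection profile before peak finding so that the symmetric
    doublet produced by the edge magnitude of an intensity dip merges into a
    single peak at the dip center.
    """

    gaussian_sigma: float = 2.0
    binarize_quantile: float = 0.90
    dilation_kernel_height: int = 15
    min_component_area: int = 200
    peak_min_separation: int = 40
    peak_min_prominence: float = 1.0  # fraction of profile standard deviation
    profile_smoothing_sigma: float = 8.0
    mask_mode: str = "threshold"  # or "weighted"

    def __post_init__(self):
        if not self.gaussian_sigma > 0:
            raise ValidationError("gaussian_sigma: must be > 0")
        if not 0 < self.binarize_quantile < 1:
            raise ValidationError("binarize_quantile: must be in (0,1)")
        if self.dilation_kernel_height < 1:
            raise ValidationError("dilation_kernel_height: must be >= 1")
        if self.min_component_area < 0:
            raise ValidationError("min_component_area: must be >= 0")
        if self.peak_min_separation < 1:
            raise ValidationError("peak_min_separation: must be >= 1")
        if self.peak_min_prominence < 0:
            raise ValidationError("peak_min_prominence: must be >= 0")
        if self.profile_smoothing_sigma < 0:
            raise ValidationError("profile_smoothing_sigma: must be >= 0")
        if self.mask_mode not in ("threshold", "weighted"):
            raise ValidationError("mask_mode: must be 'threshold' or 'weighted'")


@dataclass(frozen=True)
class LineProfile:
    """A 1-D intensity profile sampled at ascending column coordinates."""

    x: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if x.ndim != 1 or v.ndim != 1 or len(x) != len(v):
            raise ValidationError("LineProfile: x and values must be equal-length 1-D")
        if len(x) > 1 and not np.all(np.diff(x) > 0):
            raise ValidationError("LineProfile: x must be strictly ascending")
        if not np.all(np.isfinite(v)):
            raise ValidationError("LineProfile: non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class BoundarySet:
    """Detected intersegment column positions plus the detection profile."""

    boundary_columns: np.ndarray
    image_width: int
    profile: Optional[LineProfile] = None

    def __post_init__(self):
        b = np.asarray(self.boundary_columns, dtype=int)
        if b.ndim != 1 or len(b) == 0:
            raise ValidationError("boundary_columns: expected a non-empty 1-D list")
        if len(b) > 1 and not np.all(np.diff(b) > 0):
            raise ValidationError("boundary_columns: must be strictly increasing")
        if b[0] < 0 or b[-1] >= self.image_width:
            raise ValidationError("boundary_columns: outside [0, image_width)")
        object.__setattr__(self, "boundary_columns", b)

    def __len__(self) -> int:
        return len(self.boundary_columns)


@dataclass(frozen=True)
class Segment:
    """A labeled inter-boundary interval, half-open ``[x_start, x_end)``.

    Label 0 is the most distal analyzed segment (the one just proximal to the
    amputation plane), -1 the next proximal one, and so on.
    """

    label: int
    x_start: int
    x_end: int

    def __post_init__(self):
        if not self.x_start < self.x_end:
            raise ValidationError("Segment: x_start must be < x_end")

    @property
    def length(self) -> int:
        return self.x_end - self.x_start


@dataclass(frozen=True)
class DisplacementResult:
    """Per-segment GFP center of mass and relative displacement ratio."""

    segment_label: int
    com_column: float
    ratio: float
    total_gfp: float
    frame_index: Optional[int] = None


@dataclass(frozen=True)
class DEConfig:
    """Differential-expression calling parameters.

    ``alpha`` is the significance threshold applied to the (by default
    adjusted) p-value; ``lfc_threshold`` the symmetric log2-fold-change cut
    (calls require ``|log2FC| > lfc_threshold``).
    """

    alpha: float = 0.05
    lfc_threshold: float = 1.0
    adjust_method: str = "adaptive_bh"  # or "bh"
    p_basis: str = "adjusted"  # or "raw"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha: must be in (0,1)")
        if self.lfc_threshold < 0:
            raise ValidationError("lfc_threshold: must be >= 0")
        if self.adjust_method not in ("adaptive_bh", "bh"):
            raise ValidationError("adjust_method: must be 'adaptive_bh' or 'bh'")
        if self.p_basis not in ("adjusted", "raw"):
            raise ValidationError("p_basis: must be 'adjusted' or 'raw'")
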