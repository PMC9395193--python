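"""Intersegment-boundary detection on the brightfield channel.

Bony-ray segments are separated by joints that image as darker vertical
lines in brightfield.  The detector follows an edge-based front end:
Gaussian smoothing, a vertical-edge Sobel response, quantile binarization,
vertical dilation, small-component removal, column-wise averaging into a 1-D
profile, and peak finding on that profile.

One subtlety: the absolute Sobel response of a symmetric intensity dip is a
*doublet* — two ridges flanking the dip center, where the gradient itself is
zero.  The column profile is therefore smoothed with a symmetric Gaussian
(``profile_smoothing_sigma``) before peak finding, which merges each doublet
into a single peak located exactly at the dip center for symmetric dips.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Union

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import find_peaks
from skimage.morphology import dilation, remove_small_objects

from .datatypes import BoundarySet, DetectionConfig, LineProfile, RayImage, Segment
from .errors import AnalysisError, ValidationError

__all__ = [
    "column_mean_profile",
    "detect_intersegments",
    "segments_from_boundaries",
]


def column_mean_profile(mask: np.ndarray) -> LineProfile:
    """Average a 2-D (binary or real) grid over rows into a column profile.

    The value at column ``c`` is the mean of ``mask[:, c]``; for a binary
    mask this is the fraction of rows covered, hence always in [0, 1].
    """
    m = np.asarray(mask, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValidationError("mask: expected a non-empty 2-D grid")
    values = m.mean(axis=0)
    return LineProfile(x=np.arange(m.shape[1], dtype=float), values=values)


def detect_intersegments(
    image: RayImage, config: Optional[DetectionConfig] = None
) -> BoundarySet:
    """Detect intersegment boundary columns from the brightfield channel.

    Pipeline: Gaussian filter (sigma ``gaussian_sigma``) -> vertical-edge
    Sobel magnitude -> binarize at the ``binarize_quantile`` of the magnitude
    distribution -> dilate with a vertical line kernel -> remove connected
    components (8-connectivity) below ``min_component_area`` -> column-mean
    profile -> Gaussian profile smoothing -> peak finding with minimum
    separation and prominence.  Returns all detected peaks, sorted.

    Raises
    ------
    AnalysisError
        With message ``no-boundaries`` when no peak survives (e.g. a
        constant brightfield image has no edges).
    """
    config = config or DetectionConfig()
    bf = image.bf
    n_rows, n_cols = bf.shape
    if n_cols < 3:
        raise ValidationError("image: width must be >= 3 columns")
    if n_rows < config.dilation_kernel_height:
        raise ValidationError(
            "image: fewer rows than dilation_kernel_height "
            f"({n_rows} < {config.dilation_kernel_height})"
        )

    smoothed = ndi.gaussian_filter(bf, config.gaussian_sigma)
    # gradient across columns == response to vertical lines
    magnitude = np.abs(ndi.sobel(smoothed, axis=1))

    threshold = np.quantile(magnitude, config.binarize_quantile)
    mask = magnitude > threshold
    mask = dilation(
        mask, footprint=np.ones((config.dilation_kernel_height, 1), dtype=bool)
    )
    if config.min_component_area > 0:
        # drop components strictly smaller than the area threshold
        mask = remove_small_objects(
            mask, max_size=config.min_component_area - 1, connectivity=2
        )

    if config.mask_mode == "weighted":
        profile_values = np.where(mask, magnitude, 0.0).mean(axis=0)
    else:
        profile_values = column_mean_profile(mask).values

    if config.profile_smoothing_sigma > 0:
        profile_values = ndi.gaussian_filter1d(
            profile_values, config.profile_smoothing_sigma
        )

    spread = profile_values.std()
    if spread == 0:
        raise AnalysisError("no-boundaries: detection profile is flat")

    peaks, props = find_peaks(
        profile_values,
        distance=config.peak_min_separation,
        prominence=config.peak_min_prominence * spread,
        plateau_size=(1, None),
    )
    if len(peaks) == 0:
        raise AnalysisError("no-boundaries: no peaks in detection profile")
    # leftmost sample of a plateau, deterministic tie-break
    columns = np.sort(props["left_edges"].astype(int))

    return BoundarySet(
        boundary_columns=columns,
        image_width=n_cols,
        profile=LineProfile(np.arange(n_cols, dtype=float), profile_values),
    )


def _boundary_array(boundaries: Union[BoundarySet, Iterable[int]]) -> np.ndarray:
    if isinstance(boundaries, BoundarySet):
        return np.asarray(boundaries.boundary_columns, dtype=int)
    b = np.sort(np.asarray(list(boundaries), dtype=int))
    return b


def segments_from_boundaries(
    boundaries: Union[BoundarySet, Iterable[int]],
    amputation_column: int,
    proximal_left: bool = True,
    mode: str = "complete",
) -> List[Segment]:
    """Label the inter-boundary intervals proximal to the amputation plane.

    Segment 0 is the most distal analyzed segment, segment -1 the next one
    proximal, continuing while boundaries remain.  Two conventions for
    segment 0 are supported:

    - ``mode="complete"`` (default): segment 0 spans the two most distal
      boundaries strictly proximal to ``amputation_column`` — the most distal
      *complete* segment, which has a well-defined total length even though
      the amputation cut falls mid-segment.
    - ``mode="to_amputation"``: segment 0 spans from the most distal
      qualifying boundary to the amputation column itself.

    Raises ``AnalysisError('insufficient-boundaries')`` when too few
    boundaries qualify (2 for ``complete``, 1 for ``to_amputation``).
    """
    if mode not in ("complete", "to_amputation"):
        raise ValidationError("mode: must be 'complete' or 'to_amputation'")
    b = _boundary_array(boundaries)

    if proximal_left:
        qual = b[b < amputation_column]
    else:
        qual = b[b > amputation_column]

    required = 2 if mode == "complete" else 1
    if len(qual) < required:
        raise AnalysisError(
            "insufficient-boundaries: need at least "
            f"{required} boundaries proximal to column {amputation_column}, "
            f"found {len(qual)}"
        )

    segments: List[Segment] = []
    if proximal_left:
        # distal end is at high columns; walk proximally (rightmost first)
        edges = list(qual)
        if mode == "to_amputation":
            edges = edges + [int(amputation_column)]
        label = 0
        for i in range(len(edges) - 1, 0, -1):
            segments.append(Segment(label=label, x_start=int(edges[i - 1]), x_end=int(edges[i])))
            label -= 1
    else:
        # mirrored orientation: distal end at low columns
        edges = list(qual)
        if mode == "to_amputation":
            edges = [int(amputation_column)] + edges
        label = 0
        for i in range(len(edges) - 1):
            segments.append(Segment(label=label, x_start=int(edges[i]), x_end=int(edges[i + 1])))
            label -= 1
    return segments
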