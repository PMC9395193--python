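"""Synthetic data with known ground truth for every pipeline stage.

The image generator emulates a cropped, registered bony-ray: a bright,
roughly uniform ray in brightfield interrupted by darker intersegment
joints (rendered as multiplicative Gaussian-profile intensity dips), and a
GFP channel composed of Gaussian osteoblast blobs.  Noise is additive
Gaussian with an optional signal-proportional variance term; it is *not*
clipped at zero, mimicking offset-subtracted camera data — clipping would
give the noise a positive mean and bias every center-of-mass statistic.

Tabular generators plant known two-group log2 effects into expression
matrices, known fold changes into Ct tables (perfect amplification
efficiency 2), and known log-normal mixture components into mitochondria
volume lists.  Every generator is deterministic given ``(spec, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .boundaries import segments_from_boundaries
from .datatypes import RayImage, Segment
from .errors import ValidationError

__all__ = [
    "SyntheticRaySpec",
    "GroundTruth",
    "generate_ray_image",
    "generate_timelapse",
    "generate_expression_dataset",
    "generate_ct_table",
    "generate_mito_volumes",
]


@dataclass(frozen=True)
class SyntheticRaySpec:
    """Parameters of a synthetic two-channel bony-ray image.

    ``blob_list`` entries are ``(center_column, center_row, amplitude,
    radius_px)``.  ``boundary_contrast`` is the fractional depth of the
    brightfield dip at each intersegment; the boundary signal-to-noise ratio
    is ``boundary_contrast * ray_baseline / noise_sd``.  GFP detector noise
    (``gfp_noise_sd``) is independent of the brightfield noise; the default
    blob amplitude of 150 over a 5-unit noise floor reflects the high
    contrast of a transgenic osteoblast reporter under confocal imaging.
    """

    image_height: int = 120
    image_width: int = 600
    boundary_columns: Tuple[int, ...] = (100, 300, 500)
    boundary_halfwidth: float = 3.0
    boundary_contrast: float = 0.6
    ray_baseline: float = 100.0
    blob_list: Tuple[Tuple[float, float, float, float], ...] = ((400.0, 60.0, 150.0, 8.0),)
    blob_aspect: float = 1.0
    noise_sd: float = 20.0
    gfp_noise_sd: float = 5.0
    signal_noise_scale: float = 0.0
    pixel_size: float = 1.0
    amputation_column: Optional[int] = 550

    def __post_init__(self):
        if self.image_height < 1 or self.image_width < 1:
            raise ValidationError("image_height/image_width: must be >= 1")
        b = np.asarray(self.boundary_columns)
        if b.size == 0:
            raise ValidationError("boundary_columns: must be non-empty")
        if np.any(np.diff(b) <= 0):
            raise ValidationError("boundary_columns: must be strictly increasing")
        if b[0] < 0 or b[-1] >= self.image_width:
            raise ValidationError("boundary_columns: outside [0, image_width)")
        if not self.boundary_halfwidth > 0:
            raise ValidationError("boundary_halfwidth: must be > 0")
        if not 0 < self.boundary_contrast <= 1:
            raise ValidationError("boundary_contrast: must be in (0,1]")
        if not self.ray_baseline > 0:
            raise ValidationError("ray_baseline: must be > 0")
        for i, (cc, cr, amp, rad) in enumerate(self.blob_list):
            if not (0 <= cc < self.image_width and 0 <= cr < self.image_height):
                raise ValidationError(f"blob_list[{i}]: center outside image")
            if amp <= 0 or rad <= 0:
                raise ValidationError(f"blob_list[{i}]: amplitude and radius must be > 0")
        if not self.blob_aspect > 0:
            raise ValidationError("blob_aspect: must be > 0")
        if self.noise_sd < 0 or self.gfp_noise_sd < 0:
            raise ValidationError("noise_sd/gfp_noise_sd: must be >= 0")
        if self.signal_noise_scale < 0:
            raise ValidationError("signal_noise_scale: must be >= 0")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size: must be > 0")
        if self.amputation_column is not None and not (
            0 <= self.amputation_column < self.image_width
        ):
            raise ValidationError("amputation_column: outside [0, image_width)")


@dataclass
class GroundTruth:
    """Known truth attached to a synthetic dataset.

    Only the fields relevant to the generator that produced it are set.
    """

    true_boundaries: Optional[np.ndarray] = None
    true_com_per_segment: Optional[Dict[int, float]] = None
    true_ratio_per_segment: Optional[Dict[int, float]] = None
    planted_de_labels: Optional[np.ndarray] = None
    planted_log2fc: Optional[np.ndarray] = None
    planted_fold: Optional[Dict[str, float]] = None
    component_assignment: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# image generators
# ---------------------------------------------------------------------------


def _clean_channels(spec: SyntheticRaySpec):
    cols = np.arange(spec.image_width, dtype=float)
    rows = np.arange(spec.image_height, dtype=float)

    dip = np.zeros_like(cols)
    for b in spec.boundary_columns:
        dip += spec.boundary_contrast * np.exp(
            -0.5 * ((cols - b) / spec.boundary_halfwidth) ** 2
        )
    bf = spec.ray_baseline * (1.0 - np.clip(dip, 0.0, 1.0))
    bf = np.broadcast_to(bf, (spec.image_height, spec.image_width)).copy()

    gfp = np.zeros((spec.image_height, spec.image_width))
    for cc, cr, amp, rad in spec.blob_list:
        sigma_col = rad * spec.blob_aspect
        col_part = np.exp(-0.5 * ((cols - cc) / sigma_col) ** 2)
        row_part = np.exp(-0.5 * ((rows - cr) / rad) ** 2)
        gfp += amp * np.outer(row_part, col_part)
    return bf, gfp


def _add_noise(clean: np.ndarray, sd: float, signal_scale: float, rng) -> np.ndarray:
    if sd == 0 and signal_scale == 0:
        return clean
    var = sd**2 + signal_scale * np.clip(clean, 0.0, None)
    return clean + rng.standard_normal(clean.shape) * np.sqrt(var)


def _truth_segments(spec: SyntheticRaySpec) -> List[Segment]:
    amp = spec.amputation_column if spec.amputation_column is not None else spec.image_width
    try:
        return segments_from_boundaries(spec.boundary_columns, amp)
    except Exception:
        return []


def _analytic_truth(spec: SyntheticRaySpec) -> GroundTruth:
    """Noise-free GFP center of mass per segment, from the blob parameters.

    The rendered blob is separable, so the exact column profile of the
    noise-free image is ``sum_b amplitude_b * rowsum_b * exp(-((c-c0)/s)^2/2)``
    with ``rowsum_b`` the discrete Gaussian row sum — identical, to machine
    precision, to summing the rendered image over rows.
    """
    rows = np.arange(spec.image_height, dtype=float)
    segments = _truth_segments(spec)
    coms: Dict[int, float] = {}
    ratios: Dict[int, float] = {}
    for seg in segments:
        cols = np.arange(seg.x_start, seg.x_end, dtype=float)
        profile = np.zeros_like(cols)
        for cc, cr, amp_, rad in spec.blob_list:
            rowsum = np.exp(-0.5 * ((rows - cr) / rad) ** 2).sum()
            profile += amp_ * rowsum * np.exp(
                -0.5 * ((cols - cc) / (rad * spec.blob_aspect)) ** 2
            )
        total = profile.sum()
        if total > 0:
            com = float((cols * profile).sum() / total)
            coms[seg.label] = com
            r = (com - seg.x_start) / seg.length
            ratios[seg.label] = float(r)
        else:
            coms[seg.label] = math.nan
            ratios[seg.label] = math.nan
    return GroundTruth(
        true_boundaries=np.asarray(spec.boundary_columns, dtype=int),
        true_com_per_segment=coms,
        true_ratio_per_segment=ratios,
    )


def _render(spec: SyntheticRaySpec, rng) -> RayImage:
    bf, gfp = _clean_channels(spec)
    bf = _add_noise(bf, spec.noise_sd, spec.signal_noise_scale, rng)
    gfp = _add_noise(gfp, spec.gfp_noise_sd, spec.signal_noise_scale, rng)
    return RayImage(
        bf=bf,
        gfp=gfp,
        pixel_size=spec.pixel_size,
        proximal_left=True,
        amputation_column=spec.amputation_column,
    )


def generate_ray_image(spec: SyntheticRaySpec, seed: int) -> Tuple[RayImage, GroundTruth]:
    """Render one two-channel ray image plus its analytic ground truth."""
    rng = np.random.default_rng(seed)
    return _render(spec, rng), _analytic_truth(spec)


def generate_timelapse(
    spec: SyntheticRaySpec, shift_schedule: Sequence[float], seed: int
) -> Tuple[List[RayImage], List[GroundTruth]]:
    """Render a registered movie in which all blobs follow a shift schedule.

    ``shift_schedule[t]`` is the column offset applied to every blob center
    in frame ``t`` (relative to the spec's base positions).  Boundaries stay
    fixed.  A schedule of ``[0]`` reproduces :func:`generate_ray_image`
    exactly for the same seed.
    """
    if len(shift_schedule) == 0:
        raise ValidationError("shift_schedule: must be non-empty")
    rng = np.random.default_rng(seed)
    frames: List[RayImage] = []
    truths: List[GroundTruth] = []
    for t, offset in enumerate(shift_schedule):
        blobs = []
        for cc, cr, amp, rad in spec.blob_list:
            new_cc = cc + offset
            if not 0 <= new_cc < spec.image_width:
                raise ValidationError(
                    f"blob-out-of-bounds: frame {t} shifts blob to column {new_cc}"
                )
            blobs.append((new_cc, cr, amp, rad))
        frame_spec = replace(spec, blob_list=tuple(blobs))
        frames.append(_render(frame_spec, rng))
        truths.append(_analytic_truth(frame_spec))
    return frames, truths


# ---------------------------------------------------------------------------
# tabular generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionDatasetSpec:
    """Convenience record of the expression-generator arguments."""

    n_genes: int
    n_per_group: int
    frac_up: float
    frac_down: float
    effect_log2: float
    noise_sd: float


def generate_expression_dataset(
    n_genes: int,
    n_per_group: int = 3,
    frac_up: float = 0.1,
    frac_down: float = 0.1,
    effect_log2: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    baseline_range: Tuple[float, float] = (6.0, 12.0),
    group_names: Tuple[str, str] = ("0hpa", "6hpa"),
):
    """Two-group expression matrix with planted log2 effects.

    Per-gene log2 intensities are ``baseline + effect*treated + noise`` with
    gene baselines uniform on ``baseline_range`` (log2 scale) and Gaussian
    noise; linear-scale intensities are ``2**log2``.  Exactly
    ``round(frac_up*n_genes)`` genes are labeled "up" (+effect in the second
    group), ``round(frac_down*n_genes)`` "down", the rest "null".

    Returns ``(ExpressionDataset, GroundTruth)``.
    """
    from .exprstats import ExpressionDataset  # local import to avoid a cycle

    if n_genes < 1:
        raise ValidationError("n_genes: must be >= 1")
    if n_per_group < 2:
        raise ValidationError("n_per_group: must be >= 2")
    if frac_up < 0 or frac_down < 0 or frac_up + frac_down > 1:
        raise ValidationError("frac_up/frac_down: must be >= 0 and sum to <= 1")
    if not noise_sd > 0:
        raise ValidationError("noise_sd: must be > 0")

    rng = np.random.default_rng(seed)
    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    labels = np.array(["up"] * n_up + ["down"] * n_down + ["null"] * (n_genes - n_up - n_down))
    labels = labels[rng.permutation(n_genes)]
    effects = np.where(labels == "up", effect_log2, np.where(labels == "down", -effect_log2, 0.0))

    baseline = rng.uniform(*baseline_range, size=n_genes)
    group = np.array([0] * n_per_group + [1] * n_per_group)
    log2x = (
        baseline[:, None]
        + effects[:, None] * group[None, :]
        + rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_group))
    )
    intensities = np.power(2.0, log2x)

    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    sample_labels = [group_names[g] for g in group]
    dataset = ExpressionDataset(
        gene_ids=gene_ids,
        intensities=intensities,
        group_labels=sample_labels,
        reference_label=group_names[0],
    )
    truth = GroundTruth(planted_de_labels=labels, planted_log2fc=effects)
    return dataset, truth


def generate_ct_table(
    targets: Sequence[str],
    planted_fold_per_target: Dict[str, float],
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    reference_gene: str = "ef1a",
    n_samples_per_condition: int = 3,
    conditions: Tuple[str, str] = ("control", "treated"),
):
    """Ct table consistent with perfect amplification efficiency 2.

    A planted fold ``f`` for a target shifts its mean Ct by ``-log2(f)`` in
    the treated condition; the housekeeping reference gene (fold 1) is
    included automatically.  Technical replicates get independent Gaussian
    Ct noise.  Returns ``(DataFrame, GroundTruth)`` with columns
    sample_id, condition, gene, ct.
    """
    if ct_noise_sd < 0:
        raise ValidationError("ct_noise_sd: must be >= 0")
    if n_replicates < 1 or n_samples_per_condition < 1:
        raise ValidationError("n_replicates/n_samples_per_condition: must be >= 1")
    folds = dict(planted_fold_per_target)
    genes = list(targets)
    if reference_gene not in genes:
        genes.append(reference_gene)
    folds.setdefault(reference_gene, 1.0)
    if folds[reference_gene] != 1.0:
        raise ValidationError("planted_fold_per_target: reference gene must have fold 1")
    for g in genes:
        if g not in folds:
            raise ValidationError(f"planted_fold_per_target: missing fold for {g}")
        if not folds[g] > 0:
            raise ValidationError(f"planted_fold_per_target: fold for {g} must be > 0")

    rng = np.random.default_rng(seed)
    base_ct = {g: rng.uniform(18.0, 26.0) for g in genes}
    rows = []
    for condition in conditions:
        treated = condition == conditions[1]
        for s in range(n_samples_per_condition):
            sample_id = f"{condition}_{s + 1}"
            for g in genes:
                mean_ct = base_ct[g] - (math.log2(folds[g]) if treated else 0.0)
                for _ in range(n_replicates):
                    ct = mean_ct + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                    rows.append(
                        {"sample_id": sample_id, "condition": condition, "gene": g, "ct": ct}
                    )
    table = pd.DataFrame(rows)
    return table, GroundTruth(planted_fold={g: folds[g] for g in genes})


def generate_mito_volumes(
    component_means: Sequence[float],
    component_fractions: Sequence[float],
    n: int,
    seed: int = 0,
    component_sigmas=0.25,
):
    """Mitochondria volumes drawn from a log-normal mixture.

    ``component_means`` are the geometric centers (medians) of the log-normal
    components, in cubic micrometres; ``component_sigmas`` the log-scale
    spread (scalar or per-component; 0 collapses a component to its center).
    Returns ``(volumes, GroundTruth)`` with the component assignment recorded.
    """
    means = np.asarray(component_means, dtype=float)
    fracs = np.asarray(component_fractions, dtype=float)
    if means.ndim != 1 or means.size == 0:
        raise ValidationError("component_means: must be a non-empty 1-D list")
    if np.any(means <= 0):
        raise ValidationError("component_means: must be > 0")
    if fracs.shape != means.shape or np.any(fracs < 0):
        raise ValidationError("component_fractions: must match means and be >= 0")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValidationError("component_fractions: must sum to 1")
    sigmas = np.broadcast_to(np.asarray(component_sigmas, dtype=float), means.shape)
    if np.any(sigmas < 0):
        raise ValidationError("component_sigmas: must be >= 0")
    if n < 0:
        raise ValidationError("n: must be >= 0")

    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(means), size=n, p=fracs)
    z = rng.standard_normal(n)
    volumes = means[assignment] * np.exp(sigmas[assignment] * z)
    return volumes, GroundTruth(component_assignment=assignment)
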