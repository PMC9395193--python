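"""Scalar quantification metrics: densities, fractions, areas, mitochondria
size distributions, and internal-standard metabolite quantitation.

These operate on count/area/volume tables produced by interactive tools
(cell counting, area tracing, 3-D surface segmentation, LC-MS peak
integration); no image segmentation happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError

__all__ = [
    "CellCountRecord",
    "AreaMeasure",
    "MitoMeasure",
    "MetaboliteRecord",
    "density_per_area",
    "subtype_fractions",
    "regenerated_area_metrics",
    "mito_size_distribution",
    "cv_percent",
    "internal_standard_quant",
    "MITO_BIN_LABELS",
]

DENSITY_REFERENCE_AREA = 100.0  # densities are reported per 100 square micrometres


@dataclass(frozen=True)
class CellCountRecord:
    """Marker-combination cell counts from one cryosection region."""

    section_id: str
    counts: Mapping[str, int]
    region_area: float  # square micrometres
    compartment: str = "whole"  # mesenchyme | epidermis | bone | whole

    def __post_init__(self):
        if not self.region_area > 0:
            raise ValidationError("region_area: must be > 0")
        for marker, count in self.counts.items():
            if count < 0:
                raise ValidationError(f"counts['{marker}']: must be >= 0")


@dataclass(frozen=True)
class AreaMeasure:
    """Regenerated area and fin width of one animal."""

    fish_id: str
    regenerated_area: float
    fin_width: float
    group: str = "control"

    def __post_init__(self):
        if self.regenerated_area < 0:
            raise ValidationError("regenerated_area: must be >= 0")
        if not self.fin_width > 0:
            raise ValidationError("fin_width: must be > 0")


MITO_BIN_LABELS = ("<0.1", "[0.1,1)", "[1,10)", ">=10")


@dataclass(frozen=True)
class MitoMeasure:
    """Per-fin mitochondria volume list plus the nucleus count."""

    volumes: Sequence[float]
    n_nuclei: int
    bin_edges: Tuple[float, float, float] = (0.1, 1.0, 10.0)  # cubic micrometres

    def __post_init__(self):
        v = np.asarray(self.volumes, dtype=float)
        if v.size and np.any(v <= 0):
            raise ValidationError("volumes: must be > 0")
        if self.n_nuclei < 1:
            raise ValidationError("n_nuclei: must be >= 1")
        if list(self.bin_edges) != sorted(self.bin_edges) or len(self.bin_edges) != 3:
            raise ValidationError("bin_edges: expected three ascending edges")
        object.__setattr__(self, "volumes", v)


@dataclass(frozen=True)
class MetaboliteRecord:
    """One LC-MS peak-area measurement with its internal standard."""

    sample_id: str
    analyte: str
    peak_area: float
    internal_standard_area: float  # AABA peak area in the same run
    condition: str = "control"

    def __post_init__(self):
        if not self.peak_area > 0:
            raise ValidationError("peak_area: must be > 0")
        if not self.internal_standard_area > 0:
            raise ValidationError("internal_standard_area: must be > 0")


def density_per_area(record: CellCountRecord, marker: str) -> float:
    """Labeled-cell density, in cells per 100 square micrometres."""
    if marker not in record.counts:
        raise ValidationError(f"marker '{marker}' not present in section '{record.section_id}'")
    return record.counts[marker] / record.region_area * DENSITY_REFERENCE_AREA


def subtype_fractions(record: CellCountRecord, markers: Sequence[str]) -> Dict[str, float]:
    """Percentage of each listed marker combination among their total.

    The denominator is the summed count over ``markers`` (the osteoblast
    lineage total when the list covers the lineage); percentages sum to 100.
    """
    for m in markers:
        if m not in record.counts:
            raise ValidationError(f"marker '{m}' not present in section '{record.section_id}'")
    total = sum(record.counts[m] for m in markers)
    if total == 0:
        raise AnalysisError("empty-denominator: all listed marker counts are zero")
    return {m: 100.0 * record.counts[m] / total for m in markers}


def regenerated_area_metrics(
    measures: Sequence[AreaMeasure], control_group: str = "control"
) -> pd.DataFrame:
    """Width-normalized regenerated area and percent-of-control per animal.

    The normalized area is ``regenerated_area / fin_width`` (one value per
    animal, removing animal-size differences); the percentage scales each
    animal by the arithmetic mean of the control group's normalized areas,
    so the control group averages 100%.
    """
    if len(measures) == 0:
        raise ValidationError("measures: empty")
    rows = [
        {
            "fish_id": m.fish_id,
            "group": m.group,
            "normalized_area": m.regenerated_area / m.fin_width,
        }
        for m in measures
    ]
    df = pd.DataFrame(rows)
    control = df[df["group"] == control_group]
    if control.empty:
        raise ValidationError(f"control group '{control_group}' has no measurements")
    control_mean = control["normalized_area"].mean()
    if not control_mean > 0:
        raise AnalysisError("empty-denominator: control group mean normalized area is zero")
    df["percent_of_control"] = 100.0 * df["normalized_area"] / control_mean
    return df


def mito_size_distribution(measure: MitoMeasure) -> Tuple[float, Dict[str, float]]:
    """Mitochondria count per cell and the volume-class fractions.

    Volumes are binned into the four intervals <0.1, [0.1, 1), [1, 10) and
    >=10 cubic micrometres (edges lower-inclusive); fractions sum to 1.
    """
    v = np.asarray(measure.volumes, dtype=float)
    count_per_cell = v.size / measure.n_nuclei
    if v.size == 0:
        raise AnalysisError("empty-set: no mitochondria volumes to bin")
    edges = [0.0, *measure.bin_edges, np.inf]
    hist, _ = np.histogram(v, bins=edges)
    fractions = hist / v.size
    return count_per_cell, dict(zip(MITO_BIN_LABELS, fractions.tolist()))


def cv_percent(values: Sequence[float]) -> float:
    """Relative coefficient of variation: 100 x sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("values: need >= 2 values for a CV")
    mean = v.mean()
    if mean == 0:
        raise AnalysisError("empty-denominator: mean of values is zero")
    return float(100.0 * v.std(ddof=1) / mean)


def internal_standard_quant(
    records: Sequence[MetaboliteRecord], baseline_condition: str
) -> pd.DataFrame:
    """Internal-standard-calibrated metabolite levels and fold changes.

    Each peak area is divided by the AABA internal-standard area of the same
    run; per (analyte, condition) the calibrated values are averaged and the
    fold change taken against the baseline condition's mean.  The CV% column
    reports within-group quantitation variability (NaN for singleton groups).
    """
    if len(records) == 0:
        raise ValidationError("records: empty")
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "analyte": [r.analyte for r in records],
            "condition": [r.condition for r in records],
            "calibrated": [r.peak_area / r.internal_standard_area for r in records],
        }
    )
    grouped = (
        df.groupby(["analyte", "condition"])["calibrated"]
        .agg(
            mean_calibrated="mean",
            n="size",
            cv_percent=lambda v: cv_percent(v) if len(v) >= 2 else np.nan,
        )
        .reset_index()
    )
    base = grouped[grouped["condition"] == baseline_condition][
        ["analyte", "mean_calibrated"]
    ].rename(columns={"mean_calibrated": "baseline_mean"})
    out = grouped.merge(base, on="analyte", how="left")
    if out["baseline_mean"].isna().any():
        analyte = out.loc[out["baseline_mean"].isna(), "analyte"].iloc[0]
        raise ValidationError(
            f"baseline condition '{baseline_condition}' missing for analyte '{analyte}'"
        )
    out["fold_vs_baseline"] = out["mean_calibrated"] / out["baseline_mean"]
    return out[["analyte", "condition", "n", "mean_calibrated", "cv_percent", "fold_vs_baseline"]]
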