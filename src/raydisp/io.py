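"""File I/O, run configuration, provenance, and the end-to-end pipeline.

TIFF layout: one multi-page file per movie with two pages per frame, in
declared channel order (default brightfield then GFP) — pages
``(bf_0, gfp_0, bf_1, gfp_1, ...)``.  The ``channel_order`` flag covers the
swapped dialect.  Tabular outputs are UTF-8 CSV with floats printed at six
significant digits; every run writes a provenance JSON capturing the full
parameter set, sufficient to replay the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .datatypes import DetectionConfig, DEConfig, RayImage
from .displacement import quantify_timelapse
from .errors import RaydispError, ValidationError
from .exprstats import ExpressionDataset
from .synthetic import GroundTruth

__all__ = [
    "RunConfig",
    "read_image_series",
    "write_image_series",
    "write_ground_truth",
    "run_displacement_pipeline",
    "read_expression_tsv",
    "read_series_matrix",
    "read_ct_csv",
]

logger = logging.getLogger("raydisp")

FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class RunConfig:
    """Full parameter set of a displacement-pipeline run."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    de: DEConfig = field(default_factory=DEConfig)
    pixel_size: float = 1.0
    proximal_left: bool = True
    amputation_column: Optional[int] = None
    channel_order: str = "bf_first"
    boundary_mode: str = "first_frame"
    segment_mode: str = "complete"
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if isinstance(data.get("detection"), dict):
            data["detection"] = DetectionConfig(**data["detection"])
        if isinstance(data.get("de"), dict):
            data["de"] = DEConfig(**data["de"])
        return cls(**data)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def write_image_series(
    path: Union[str, Path],
    frames: Sequence[RayImage],
    channel_order: str = "bf_first",
) -> None:
    """Write frames as a multi-page TIFF, two pages per frame."""
    if channel_order not in ("bf_first", "gfp_first"):
        raise ValidationError("channel_order: must be 'bf_first' or 'gfp_first'")
    pages = []
    for frame in frames:
        pair = (frame.bf, frame.gfp) if channel_order == "bf_first" else (frame.gfp, frame.bf)
        pages.extend(pair)
    tifffile.imwrite(
        str(path), np.stack(pages).astype(np.float32), photometric="minisblack"
    )


def read_image_series(
    path: Union[str, Path],
    channel_order: str = "bf_first",
    pixel_size: float = 1.0,
    proximal_left: bool = True,
    amputation_column: Optional[int] = None,
) -> List[RayImage]:
    """Read a two-pages-per-frame TIFF back into RayImage frames."""
    if channel_order not in ("bf_first", "gfp_first"):
        raise ValidationError("channel_order: must be 'bf_first' or 'gfp_first'")
    try:
        data = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise RaydispError(f"could not read TIFF '{path}': {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValidationError(f"'{path}': expected a stack of 2-D pages")
    if data.shape[0] % 2 != 0:
        raise ValidationError(
            f"channel-mismatch: '{path}' has {data.shape[0]} pages, expected bf/gfp pairs"
        )
    frames = []
    for t in range(data.shape[0] // 2):
        first, second = data[2 * t].astype(float), data[2 * t + 1].astype(float)
        bf, gfp = (first, second) if channel_order == "bf_first" else (second, first)
        frames.append(
            RayImage(
                bf=bf,
                gfp=gfp,
                pixel_size=pixel_size,
                proximal_left=proximal_left,
                amputation_column=amputation_column,
            )
        )
    return frames


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth(
    path: Union[str, Path], truth: Union[GroundTruth, Sequence[GroundTruth]]
) -> None:
    """Write generator ground truth as a JSON sidecar."""
    if isinstance(truth, GroundTruth):
        payload = _jsonable(dataclasses.asdict(truth))
    else:
        payload = [_jsonable(dataclasses.asdict(t)) for t in truth]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def run_displacement_pipeline(
    config: RunConfig, tiff_path: Union[str, Path]
) -> pd.DataFrame:
    """Read a movie, detect boundaries, quantify displacement, write outputs.

    Writes ``results.csv`` (long format: image_id, frame, segment_label,
    x_start, x_end, com_column, ratio, total_gfp), ``provenance.json`` with
    the tool version and every parameter, and ``run.log`` into
    ``config.output_dir``.  Identical input and config produce byte-identical
    CSVs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        stage = "read"
        logger.info("reading %s", tiff_path)
        frames = read_image_series(
            tiff_path,
            channel_order=config.channel_order,
            pixel_size=config.pixel_size,
            proximal_left=config.proximal_left,
            amputation_column=config.amputation_column,
        )
        stage = "quantify"
        logger.info("quantifying %d frame(s)", len(frames))
        table = quantify_timelapse(
            frames,
            config=config.detection,
            boundary_mode=config.boundary_mode,
            segment_mode=config.segment_mode,
        )
        table.insert(0, "image_id", Path(tiff_path).stem)
        stage = "write"
        results_path = out_dir / "results.csv"
        table.to_csv(results_path, index=False, float_format=FLOAT_FORMAT)
        provenance = {
            "tool": "raydisp",
            "version": __version__,
            "input": str(tiff_path),
            "config": _jsonable(config.to_dict()),
        }
        with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        logger.info("wrote %s", results_path)
        return table
    except Exception as exc:
        logger.error("stage '%s' failed: %s", stage, exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def read_expression_tsv(
    matrix_path: Union[str, Path],
    groups_path: Union[str, Path],
    reference_label: Optional[str] = None,
) -> ExpressionDataset:
    """Read a genes x samples TSV plus a two-column sample,group CSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path)
    if groups.shape[1] < 2:
        raise ValidationError("groups file: expected columns sample,group")
    mapping = dict(zip(groups.iloc[:, 0].astype(str), groups.iloc[:, 1].astype(str)))
    missing = [s for s in matrix.columns if s not in mapping]
    if missing:
        raise ValidationError(f"groups file: no group for sample(s) {missing}")
    return ExpressionDataset(
        gene_ids=[str(g) for g in matrix.index],
        intensities=matrix.to_numpy(dtype=float),
        group_labels=[mapping[s] for s in matrix.columns],
        reference_label=reference_label,
    )


def read_series_matrix(path: Union[str, Path]) -> pd.DataFrame:
    """Parse the data table of a GEO series-matrix text file.

    Returns the probes x samples matrix between the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers.
    Convenience only; expression values are whatever the series deposits.
    """
    lines: List[str] = []
    inside = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token == "!series_matrix_table_begin":
                inside = True
                continue
            if token == "!series_matrix_table_end":
                break
            if inside:
                lines.append(line)
    if not lines:
        raise ValidationError(f"'{path}': no series-matrix table found")
    from io import StringIO

    return pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)


def read_ct_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a long-format Ct table (sample_id, condition, gene, ct) CSV."""
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "condition", "gene", "ct") if c not in df.columns]
    if missing:
        raise ValidationError(f"'{path}': missing columns {missing}")
    return df
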