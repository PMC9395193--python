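"""Microarray differential-expression statistics and qPCR quantification.

The array workflow is: quantile normalization onto the rank-mean
distribution, a log2 transform, per-gene Welch (unequal-variance) t-tests
between the two groups, false-discovery-rate adjustment (two-stage adaptive
Benjamini-Hochberg by default, plain BH selectable), and a combined call
requiring both significance and ``|log2FC|`` above a threshold.

qPCR relative quantification follows the 2^-ΔΔCt method with an assumed
amplification efficiency of exactly 2: technical replicates are averaged,
ΔCt is taken against a housekeeping reference gene per sample, ΔΔCt against
a baseline condition, and the fold change is ``2**(-ΔΔCt)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DEConfig
from .errors import AnalysisError, ValidationError

__all__ = [
    "ExpressionDataset",
    "quantile_normalize",
    "quantile_normalize_matrix",
    "welch_test",
    "bh_adjust",
    "adaptive_bh",
    "de_table",
    "ddct_relative_expression",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x samples intensity matrix with a two-level group factor."""

    gene_ids: List[str]
    intensities: np.ndarray
    group_labels: List[str]
    reference_label: Optional[str] = None

    def __post_init__(self):
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 2:
            raise ValidationError("intensities: expected genes x samples 2-D matrix")
        if x.shape[0] != len(self.gene_ids):
            raise ValidationError("gene_ids: length must match intensity rows")
        if x.shape[1] != len(self.group_labels):
            raise ValidationError("group_labels: length must match intensity columns")
        if not np.all(np.isfinite(x)) or np.any(x <= 0):
            raise ValidationError("intensities: must be positive and finite")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids: duplicates present")
        levels = list(dict.fromkeys(self.group_labels))
        if len(levels) != 2:
            raise ValidationError("group_labels: exactly two levels required")
        for lvl in levels:
            if self.group_labels.count(lvl) < 2:
                raise ValidationError(f"group_labels: level '{lvl}' has fewer than 2 samples")
        ref = self.reference_label if self.reference_label is not None else levels[0]
        if ref not in levels:
            raise ValidationError(f"reference_label: '{ref}' not among group labels")
        object.__setattr__(self, "intensities", x)
        object.__setattr__(self, "reference_label", ref)

    @property
    def levels(self) -> Tuple[str, str]:
        """(reference, treatment) label pair."""
        other = next(l for l in dict.fromkeys(self.group_labels) if l != self.reference_label)
        return (self.reference_label, other)

    def group_columns(self, label: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.group_labels) if g == label])


def quantile_normalize_matrix(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a 2-D matrix.

    Each column's sorted values are replaced by the across-column mean of
    sorted values, preserving within-column ranks; values tied within a
    column receive the mean of the target values their sorted positions span.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError("intensities: expected a 2-D matrix")
    if x.shape[1] < 2:
        raise ValidationError("intensities: quantile normalization needs >= 2 samples")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        sorted_vals = x[order, j]
        target = reference.copy()
        # average the reference over each run of tied input values
        start = 0
        for i in range(1, len(sorted_vals) + 1):
            if i == len(sorted_vals) or sorted_vals[i] != sorted_vals[start]:
                if i - start > 1:
                    target[start:i] = target[start:i].mean()
                start = i
        out[order, j] = target
    return out


def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Rank-mean quantile normalization of an expression dataset.

    See :func:`quantile_normalize_matrix` for the column-wise definition.
    """
    return ExpressionDataset(
        gene_ids=list(dataset.gene_ids),
        intensities=quantile_normalize_matrix(dataset.intensities),
        group_labels=list(dataset.group_labels),
        reference_label=dataset.reference_label,
    )


def welch_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns ``(t, df, two-sided p)``.

    ``t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny)`` with
    Welch-Satterthwaite degrees of freedom.  Two degenerate inputs with zero
    variance in both groups: equal means give ``(0, nx+ny-2, 1)`` by
    convention; different means are an error (``degenerate-variance``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_test: each group needs >= 2 values")
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    mx, my = x.mean(), y.mean()
    if vx == 0 and vy == 0:
        if mx == my:
            return 0.0, float(nx + ny - 2), 1.0
        raise AnalysisError("degenerate-variance: zero variance in both groups, means differ")
    se2 = vx / nx + vy / ny
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _welch_matrix(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch test for a genes x samples split into two groups."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    se2 = va / na + vb / nb
    degenerate = se2 == 0
    if np.any(degenerate & (ma != mb)):
        idx = int(np.nonzero(degenerate & (ma != mb))[0][0])
        raise AnalysisError(f"degenerate-variance: gene row {idx} has zero variance in both groups")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, (ma - mb) / np.sqrt(se2))
        df = np.where(
            degenerate,
            na + nb - 2,
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)),
        )
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, df, p


def _validate_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values: expected a non-empty 1-D list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p_values: must lie in (0, 1]")
    return p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Plain Benjamini-Hochberg step-up adjusted p-values."""
    p = _validate_pvalues(p_values)
    return multipletests(p, method="fdr_bh")[1]


def adaptive_bh(
    p_values: Sequence[float], alpha: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-stage adaptive Benjamini-Hochberg adjustment.

    Stage 1 runs plain BH at ``alpha/(1+alpha)`` to estimate the number of
    true nulls ``m0 = m - r1``; stage 2 scales the BH-adjusted p-values by
    ``m0/m``.  Returns ``(p_adjusted, reject)`` with
    ``reject = p_adjusted <= alpha``.  Rejections are always a superset of
    plain BH at the same level.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha: must be in (0,1)")
    p = _validate_pvalues(p_values)
    adjusted = bh_adjust(p)
    m = len(p)
    r1 = int(np.sum(adjusted <= alpha / (1.0 + alpha)))
    m0 = m - r1
    p_adj = np.clip(adjusted * m0 / m, 0.0, 1.0)
    return p_adj, p_adj <= alpha


def de_table(
    dataset: ExpressionDataset, config: Optional[DEConfig] = None
) -> pd.DataFrame:
    """Differential-expression table for a two-group expression dataset.

    Pipeline: quantile normalization -> log2 -> per-gene
    ``log2FC = mean(log2 treatment) - mean(log2 reference)`` -> Welch test
    -> FDR adjustment per ``config.adjust_method`` -> call "up"/"down" when
    the (adjusted, by default) p-value is below ``alpha`` *and* ``|log2FC|``
    exceeds ``lfc_threshold``, else "ns".

    Returns a DataFrame indexed by gene id with columns
    ``log2fc, t, df, p, p_adjusted, call``.
    """
    config = config or DEConfig()
    normalized = quantile_normalize(dataset)
    log2x = np.log2(normalized.intensities)
    ref_label, treat_label = normalized.levels
    ref_cols = normalized.group_columns(ref_label)
    treat_cols = normalized.group_columns(treat_label)

    log2fc = log2x[:, treat_cols].mean(axis=1) - log2x[:, ref_cols].mean(axis=1)
    t, df, p = _welch_matrix(log2x[:, treat_cols], log2x[:, ref_cols])
    # floating underflow guard: p of 0 is outside the adjusters' domain
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    if config.adjust_method == "adaptive_bh":
        p_adjusted, _ = adaptive_bh(p, config.alpha)
    else:
        p_adjusted = bh_adjust(p)

    p_for_call = p_adjusted if config.p_basis == "adjusted" else p
    significant = p_for_call < config.alpha
    call = np.where(
        significant & (log2fc > config.lfc_threshold),
        "up",
        np.where(significant & (log2fc < -config.lfc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "p_adjusted": p_adjusted,
            "call": call,
        },
        index=pd.Index(dataset.gene_ids, name="gene"),
    )


_CT_COLUMNS = ("sample_id", "condition", "gene", "ct")


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    baseline_condition: str,
    reference_gene: str = "ef1a",
) -> pd.DataFrame:
    """Per-gene fold changes by the 2^-ΔΔCt method.

    ``ct_table`` is a long-format table with columns
    ``sample_id, condition, gene, ct`` (technical replicates as repeated
    rows).  Replicates are averaged per (sample, gene); ΔCt is the target Ct
    minus the housekeeping reference Ct within each sample; ΔΔCt is the mean
    ΔCt of a condition minus the mean ΔCt of the baseline condition; the
    fold change is ``2**(-ΔΔCt)``.

    Returns a DataFrame with columns ``gene, condition, ddct, fold`` (the
    baseline condition appears with fold 1 by construction).
    """
    missing = [c for c in _CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValidationError(f"ct_table: missing columns {missing}")
    if not np.all(np.isfinite(ct_table["ct"].to_numpy(dtype=float))):
        raise ValidationError("ct_table: non-finite Ct values")
    if baseline_condition not in set(ct_table["condition"]):
        raise ValidationError(f"baseline condition '{baseline_condition}' absent from table")

    rep = (
        ct_table.groupby(["sample_id", "condition", "gene"], as_index=False)["ct"].mean()
    )
    ref = rep[rep["gene"] == reference_gene][["sample_id", "ct"]].rename(
        columns={"ct": "ref_ct"}
    )
    for sample_id in rep["sample_id"].unique():
        if sample_id not in set(ref["sample_id"]):
            raise ValidationError(
                f"reference gene '{reference_gene}' missing for sample '{sample_id}'"
            )
    targets = rep[rep["gene"] != reference_gene].merge(ref, on="sample_id")
    targets["dct"] = targets["ct"] - targets["ref_ct"]

    mean_dct = targets.groupby(["gene", "condition"], as_index=False)["dct"].mean()
    base = mean_dct[mean_dct["condition"] == baseline_condition][["gene", "dct"]].rename(
        columns={"dct": "base_dct"}
    )
    out = mean_dct.merge(base, on="gene", how="left")
    if out["base_dct"].isna().any():
        gene = out.loc[out["base_dct"].isna(), "gene"].iloc[0]
        raise ValidationError(
            f"baseline condition '{baseline_condition}' missing for gene '{gene}'"
        )
    out["ddct"] = out["dct"] - out["base_dct"]
    out["fold"] = np.power(2.0, -out["ddct"])
    return out[["gene", "condition", "ddct", "fold"]]
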