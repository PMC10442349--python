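"""Per-gene error and correlation evaluation of expression predictions.

For every gene, the Pearson correlation between predicted and true (log)
expression is computed across the test spots within each evaluation *unit*
(by default each cross-validation fold model; alternatively each tissue
section) and the median is taken across units.  MAE and RMSE are pooled over
all test predictions of the gene; aMAE/aRMSE average them over genes.  Median
correlations are binned into the conventional classes: strong (> 0.5),
medium (0.3, 0.5], weak (0.1, 0.3], negligible (0, 0.1], and non-positive.

Genes whose truth or prediction is constant within a unit have no defined
correlation there; units with undefined correlation are excluded from that
gene's median (and a gene with no defined unit is reported as undefined, not
silently zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ValidationError

__all__ = [
    "EvalReport",
    "mae_rmse",
    "pearson",
    "classify_pcc",
    "evaluate",
    "CLASS_NAMES",
]

CLASS_NAMES = ("strong", "medium", "weak", "negligible", "non_positive")


def mae_rmse(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Mean absolute error and root mean squared error of a prediction vector."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValidationError("empty vectors")
    diff = y_true - y_pred
    return float(np.mean(np.abs(diff))), float(np.sqrt(np.mean(diff**2)))


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    Returns ``nan`` when either vector is constant (undefined correlation);
    callers treat that as missing rather than zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValidationError("pearson needs n >= 2")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((da @ db) / denom, -1.0, 1.0))


def classify_pcc(pcc: float) -> str:
    """Correlation-strength class of a PCC value (strict at 0.5: strong means
    strictly greater than 0.50)."""
    if not -1.0 - 1e-12 <= pcc <= 1.0 + 1e-12:
        raise ValidationError(f"PCC {pcc} outside [-1, 1]")
    if pcc > 0.5:
        return "strong"
    if pcc > 0.3:
        return "medium"
    if pcc > 0.1:
        return "weak"
    if pcc > 0.0:
        return "negligible"
    return "non_positive"


@dataclass
class EvalReport:
    """Per-gene metrics with median-over-unit correlations and aggregates."""

    per_gene: pd.DataFrame  # index: gene; columns: median_pcc, mae, rmse, pcc_class, n_units
    unit_pccs: pd.DataFrame  # genes x units PCC matrix (NaN where undefined)
    aggregates: dict = field(default_factory=dict)
    grouping: str = "fold_model"

    @property
    def class_counts(self) -> dict[str, int]:
        return {c: int((self.per_gene["pcc_class"] == c).sum()) for c in CLASS_NAMES}

    def positive_pccs(self) -> np.ndarray:
        vals = self.per_gene["median_pcc"].dropna().to_numpy()
        return vals[vals > 0]

    def histogram(self, bin_width: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Counts of positively correlated genes in PCC bins over (0, 1]."""
        edges = np.arange(0.0, 1.0 + bin_width, bin_width)
        counts, _ = np.histogram(self.positive_pccs(), bins=edges)
        return counts, edges

    def to_tsv(self, path: str | Path) -> None:
        self.per_gene.to_csv(path, sep="\t", index_label="gene")

    def summary(self) -> dict:
        return {**self.aggregates, "class_counts": self.class_counts}


def evaluate(
    predictions: pd.DataFrame,
    targets: pd.DataFrame,
    grouping: str = "fold_model",
) -> EvalReport:
    """Score a table of per-unit predictions against the true expression.

    predictions
        Tidy frame indexed by (unit, spot) — a MultiIndex or columns named
        ``unit`` and ``spot`` — with one column per gene.
    targets
        Frame indexed by spot with the same gene columns (log expression).
    grouping
        Label recorded in the report: ``fold_model`` (default) or ``section``.
    """
    if not isinstance(predictions.index, pd.MultiIndex):
        if {"unit", "spot"}.issubset(predictions.columns):
            predictions = predictions.set_index(["unit", "spot"])
        else:
            raise ValidationError(
                "predictions need a (unit, spot) MultiIndex or unit/spot columns"
            )
    genes = list(predictions.columns)
    missing = [g for g in genes if g not in targets.columns]
    if missing:
        raise ValidationError(f"genes missing from targets: {missing[:5]}")

    units = predictions.index.get_level_values(0).unique()
    pcc_matrix = pd.DataFrame(index=genes, columns=units, dtype=float)
    abs_err_sums = np.zeros(len(genes))
    sq_err_sums = np.zeros(len(genes))
    n_pooled = 0
    for unit in units:
        pred_u = predictions.xs(unit, level=0)
        truth_u = targets.loc[pred_u.index, genes]
        p = pred_u[genes].to_numpy(dtype=float)
        t = truth_u.to_numpy(dtype=float)
        diff = t - p
        abs_err_sums += np.abs(diff).sum(axis=0)
        sq_err_sums += (diff**2).sum(axis=0)
        n_pooled += len(pred_u)
        dp = p - p.mean(axis=0)
        dt = t - t.mean(axis=0)
        denom = np.sqrt((dp**2).sum(axis=0) * (dt**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (dp * dt).sum(axis=0) / denom
        r[denom == 0] = np.nan
        pcc_matrix[unit] = np.clip(r, -1.0, 1.0)

    median_pcc = pcc_matrix.median(axis=1, skipna=True)
    mae = abs_err_sums / n_pooled
    rmse = np.sqrt(sq_err_sums / n_pooled)
    per_gene = pd.DataFrame(
        {
            "median_pcc": median_pcc,
            "mae": mae,
            "rmse": rmse,
            "n_units": pcc_matrix.notna().sum(axis=1),
        },
        index=pd.Index(genes, name="gene"),
    )
    per_gene["pcc_class"] = [
        classify_pcc(v) if np.isfinite(v) else "undefined"
        for v in per_gene["median_pcc"]
    ]
    defined = per_gene["median_pcc"].dropna()
    aggregates = {
        "aMAE": float(per_gene["mae"].mean()),
        "aRMSE": float(per_gene["rmse"].mean()),
        "n_genes": len(genes),
        "n_undefined_pcc": int(per_gene["median_pcc"].isna().sum()),
        "n_positive": int((defined > 0).sum()),
        "n_strong": int((defined > 0.5).sum()),
        "median_pcc_overall": float(defined.median()) if len(defined) else float("nan"),
    }
    return EvalReport(
        per_gene=per_gene,
        unit_pccs=pcc_matrix,
        aggregates=aggregates,
        grouping=grouping,
    )
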