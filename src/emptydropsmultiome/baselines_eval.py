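"""Baseline callers and evaluation against simulation ground truth.

The library-size baseline emulates the count step of CellRanger-arc's cell
calling: a k=2 k-means clustering in (log10 ATAC, log10 RNA) count space
whose decision line, optionally shifted parallel to itself, separates
called from rejected droplets. (The FRiP-based filter of CellRanger-arc
requires fragment-level data and is not emulated; the baseline is a partial
surrogate for the count filter only.) The RNA-only baseline thresholds the
``FDR_RNA`` column of the multiome call table, i.e. applies the
single-modality test with the soup profiled from the RNA ambient cluster.

ROC curves sweep the caller's own ordering: achieved adjusted p-values for
the FDR-based callers, the parallel intercept shift for the line caller.
Positives are nuclei (``nucleus`` and ``small_nucleus``); every other
barcode — including technical-error and amplified empties — counts as a
negative a caller must reject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .calling import kmeans_direction
from .errors import ValidationError
from .synthetic import LABEL_NUCLEUS, LABEL_SMALL, SimTruth

logger = logging.getLogger(__name__)

POSITIVE_LABELS = frozenset({LABEL_NUCLEUS, LABEL_SMALL})


@dataclass
class RocCurve:
    """ROC sweep of one caller: thresholds with per-threshold TPR/FPR."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    positive_labels: frozenset


# ---------------------------------------------------------------------------
# Baseline callers
# ---------------------------------------------------------------------------

def line_caller_scores(
    t_a: np.ndarray, t_r: np.ndarray, seed: int = 0, fit_mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Signed k-means-line offset of every barcode, plus the line's offset.

    ``fit_mask`` restricts the k-means *fit* (not the scoring) to a subset
    of barcodes, emulating the low-count exclusion the production count
    filter applies before clustering; by default every barcode with
    positive totals in both modalities is used. Barcodes with a zero total
    in either modality cannot be placed in log space and receive ``-inf``
    (never called).
    """
    t_a = np.asarray(t_a, dtype=float)
    t_r = np.asarray(t_r, dtype=float)
    ok = (t_a > 0) & (t_r > 0)
    fit = ok if fit_mask is None else (ok & np.asarray(fit_mask, dtype=bool))
    if int(fit.sum()) < 2:
        raise ValidationError("need at least 2 barcodes with positive totals in both modalities")
    _, normal, offset = kmeans_direction(
        np.log10(t_a[fit]), np.log10(t_r[fit]), seed=seed
    )
    scores = np.full(t_a.size, -np.inf)
    scores[ok] = normal[0] * np.log10(t_a[ok]) + normal[1] * np.log10(t_r[ok])
    return scores, offset


def kmeans_line_caller(
    t_a: np.ndarray,
    t_r: np.ndarray,
    intercept_shift: float = 0.0,
    seed: int = 0,
    fit_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Count-threshold baseline: call the high-count side of the k-means line.

    ``intercept_shift`` moves the line parallel to itself (in log10 units
    along the line normal); shift 0 is the unmodified baseline, negative
    shifts call more droplets, positive shifts fewer.
    """
    scores, offset = line_caller_scores(t_a, t_r, seed=seed, fit_mask=fit_mask)
    return scores >= offset + intercept_shift


def rna_only_caller(call_table: pd.DataFrame, fdr_threshold: float = 1e-3) -> np.ndarray:
    """Single-modality baseline: threshold the FDR_RNA column."""
    if "FDR_RNA" not in call_table.columns:
        raise ValidationError("call table lacks the FDR_RNA column")
    fdr = call_table["FDR_RNA"].to_numpy(dtype=float)
    return np.nan_to_num(fdr, nan=np.inf) <= fdr_threshold


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def roc_curve(
    scores: np.ndarray,
    truth: SimTruth,
    positive_labels: frozenset = POSITIVE_LABELS,
) -> RocCurve:
    """ROC curve of a per-barcode score (higher = more nucleus-like).

    ``scores`` must be aligned with ``truth.barcodes``. Thresholds are the
    achieved score values (step-function ROC); AUC is the trapezoid of
    (FPR, TPR).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != truth.barcodes.size:
        raise ValidationError("scores and truth are not aligned")
    if np.any(np.isnan(scores)):
        raise ValidationError("scores contain NaN")
    y = np.isin(truth.labels, list(positive_labels))
    if y.all() or not y.any():
        raise ValidationError("truth must contain both positive and negative barcodes")
    # "never called" sentinels (-inf) become a finite floor below every
    # achieved score so sklearn's sweep keeps them at the end.
    finite = np.isfinite(scores)
    if not finite.all():
        floor = scores[finite].min() - 1.0 if finite.any() else -1.0
        scores = np.where(finite, scores, floor)
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return RocCurve(
        thresholds=thr,
        tpr=tpr,
        fpr=fpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        positive_labels=positive_labels,
    )


def fdr_scores(
    call_table: pd.DataFrame, truth: SimTruth, column: str = "FDR"
) -> np.ndarray:
    """Map a call table's FDR column onto the truth barcode order as scores.

    Scores are ``1 - FDR``; untested barcodes (absent from the table or NaN)
    score 0, i.e. are never called before any tested barcode.
    """
    fdr = pd.Series(
        call_table[column].to_numpy(dtype=float),
        index=call_table["barcode"].to_numpy(dtype=object),
    )
    aligned = fdr.reindex(truth.barcodes).to_numpy(dtype=float)
    return 1.0 - np.nan_to_num(aligned, nan=1.0)


def confusion_rates(
    called: np.ndarray, truth: SimTruth, positive_labels: frozenset = POSITIVE_LABELS
) -> dict:
    """TPR, FPR and empirical false-discovery proportion of one called set."""
    called = np.asarray(called, dtype=bool)
    if called.size != truth.barcodes.size:
        raise ValidationError("called mask and truth are not aligned")
    pos = np.isin(truth.labels, list(positive_labels))
    n_called = int(called.sum())
    tp = int((called & pos).sum())
    fp = n_called - tp
    return {
        "n_called": n_called,
        "tpr": tp / max(int(pos.sum()), 1),
        "fpr": fp / max(int((~pos).sum()), 1),
        "fdp": fp / n_called if n_called else 0.0,
    }


def group_tpr(called: np.ndarray, truth: SimTruth, label: str) -> float:
    """Fraction of barcodes with a given truth label that were called."""
    mask = truth.labels == label
    if not mask.any():
        raise ValidationError(f"no barcodes with label {label!r}")
    return float(np.asarray(called, dtype=bool)[mask].mean())


def evaluate_call_table(
    call_table: pd.DataFrame, truth: SimTruth, fdr_threshold: float = 1e-3
) -> dict:
    """Metrics of a multiome call table against simulation truth."""
    table_bc = set(call_table["barcode"])
    missing = [bc for bc in table_bc if bc not in set(truth.barcodes)]
    if missing:
        raise ValidationError(
            f"{len(missing)} call-table barcode(s) absent from the truth table"
        )
    is_cell = pd.Series(
        call_table["is_cell"].to_numpy(dtype=bool),
        index=call_table["barcode"].to_numpy(dtype=object),
    )
    called = is_cell.reindex(truth.barcodes, fill_value=False).to_numpy(dtype=bool)
    metrics = confusion_rates(called, truth)
    metrics["auc"] = roc_curve(fdr_scores(call_table, truth), truth).auc
    metrics["auc_rna_only"] = roc_curve(
        fdr_scores(call_table, truth, column="FDR_RNA"), truth
    ).auc
    return metrics
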