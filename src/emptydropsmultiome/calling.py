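"""Aggregation, FDR control, retention lines and the final droplet call table.

Per-droplet RNA and ATAC p-values are aggregated by their arithmetic mean
(valid under arbitrary dependence, optionally with the factor-2 correction
that makes the averaged p-value a bona fide p-value) and adjusted across
droplets with Benjamini-Hochberg. Two retention lines parallel to the k=2
k-means decision line in (log10 ATAC, log10 RNA) count space then override
the adjusted values: droplets below the line through ``(log10 l_A,
log10 l_R)`` are forced to FDR 1 (they sit inside the ambient clusters), and
droplets above a line two thirds of the way from the k-means line to the top
percentile of the distribution can optionally be forced to FDR 0 so that
very large droplets are always retained in homogeneous samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .ambient import AmbientProfile, LibrarySizeModel
from .dm_test import ModalityPValues
from .errors import ValidationError
from .io_matrix import MultiomeCounts, library_sizes

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 1e-3
DEFAULT_TOP_PERCENTILE = 99.0


# ---------------------------------------------------------------------------
# p-value aggregation and multiplicity correction
# ---------------------------------------------------------------------------

def aggregate_pvalues(
    p_rna: float | None, p_atac: float | None, multiplier: float = 1.0
) -> float:
    """Arithmetic-mean aggregation of the two modality p-values.

    A modality that was not tested (None/NaN) is treated as p = 1 before
    averaging, penalizing single-modality evidence. ``multiplier`` defaults
    to 1 (plain mean); 2 gives the dependence-robust averaged p-value that
    is valid at any level. The result is capped at 1.
    """
    vals = []
    for p in (p_rna, p_atac):
        if p is None or (isinstance(p, float) and np.isnan(p)):
            vals.append(None)
        else:
            if not 0 < p <= 1:
                raise ValidationError(f"p-values must lie in (0, 1], got {p}")
            vals.append(float(p))
    if vals[0] is None and vals[1] is None:
        raise ValidationError("barcode tested in neither modality")
    a = 1.0 if vals[0] is None else vals[0]
    b = 1.0 if vals[1] is None else vals[1]
    return min(1.0, multiplier * (a + b) / 2.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Retention lines
# ---------------------------------------------------------------------------

@dataclass
class RetentionLines:
    """The k-means decision line and its two parallel retention lines.

    Lines live in (x, y) = (log10 t_A, log10 t_R) space and are stored both
    as slope/intercepts and as a unit normal ``(nx, ny)`` (pointing towards
    the high-count cluster) with scalar offsets; a point is *below* a line of
    offset ``o`` when ``nx*x + ny*y < o``.
    """

    slope: float
    kmeans_intercept: float
    lower_intercept: float
    upper_intercept: float
    centroids: np.ndarray
    normal: np.ndarray
    kmeans_offset: float
    lower_offset: float
    upper_offset: float

    def signed_offset(self, log_t_a: np.ndarray, log_t_r: np.ndarray) -> np.ndarray:
        return self.normal[0] * np.asarray(log_t_a) + self.normal[1] * np.asarray(log_t_r)

    def below_lower(self, log_t_a: np.ndarray, log_t_r: np.ndarray) -> np.ndarray:
        return self.signed_offset(log_t_a, log_t_r) < self.lower_offset

    def above_upper(self, log_t_a: np.ndarray, log_t_r: np.ndarray) -> np.ndarray:
        return self.signed_offset(log_t_a, log_t_r) > self.upper_offset

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "kmeans_intercept": self.kmeans_intercept,
            "lower_intercept": self.lower_intercept,
            "upper_intercept": self.upper_intercept,
            "centroids": np.asarray(self.centroids).tolist(),
        }


def kmeans_direction(
    log_t_a: np.ndarray, log_t_r: np.ndarray, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """k=2 k-means in log-count space; returns (centroids, unit normal, offset).

    The decision line is the perpendicular bisector of the two centroids;
    the normal points from the low- to the high-count centroid.
    """
    points = np.column_stack([np.asarray(log_t_a), np.asarray(log_t_r)])
    if points.shape[0] < 2:
        raise ValidationError("need at least 2 barcodes to fit the k-means line")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    km.fit(points)
    c = km.cluster_centers_
    order = np.argsort(c.sum(axis=1))
    low, high = c[order[0]], c[order[1]]
    direction = high - low
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise ValidationError(
            "degenerate k-means clustering (coincident centroids); "
            "specify the line manually"
        )
    normal = direction / norm
    offset = float(normal @ ((low + high) / 2.0))
    return c[order], normal, offset


def fit_retention_lines(
    t_a: np.ndarray,
    t_r: np.ndarray,
    models: tuple[LibrarySizeModel, LibrarySizeModel],
    top_percentile: float = DEFAULT_TOP_PERCENTILE,
    seed: int = 0,
) -> RetentionLines:
    """Fit the k-means line and its two parallel retention lines.

    ``models`` is the (ATAC, RNA) pair of library-size models. The fit is
    restricted to barcodes above both technical-error boundaries. The lower
    line passes through ``(log10 l_A, log10 l_R)``; the upper line offset is
    2/3 of the way from the k-means offset to the ``top_percentile``-th
    percentile of the droplets' signed offsets.
    """
    model_a, model_r = models
    t_a = np.asarray(t_a, dtype=float)
    t_r = np.asarray(t_r, dtype=float)
    mask = (t_a > model_a.b) & (t_r > model_r.b)
    if int(mask.sum()) < 2:
        raise ValidationError(
            "fewer than 2 barcodes above both technical-error boundaries"
        )
    la = np.log10(t_a[mask])
    lr = np.log10(t_r[mask])
    centroids, normal, kmeans_offset = kmeans_direction(la, lr, seed=seed)
    if abs(normal[1]) < 1e-9:
        raise ValidationError(
            "k-means line is vertical in (log ATAC, log RNA) space; "
            "specify the line manually"
        )

    anchor = (np.log10(model_a.l), np.log10(model_r.l))
    lower_offset = float(normal[0] * anchor[0] + normal[1] * anchor[1])
    offsets = normal[0] * la + normal[1] * lr
    top_offset = float(np.percentile(offsets, top_percentile))
    upper_offset = kmeans_offset + (2.0 / 3.0) * (top_offset - kmeans_offset)

    slope = -normal[0] / normal[1]
    lines = RetentionLines(
        slope=slope,
        kmeans_intercept=kmeans_offset / normal[1],
        lower_intercept=lower_offset / normal[1],
        upper_intercept=upper_offset / normal[1],
        centroids=centroids,
        normal=normal,
        kmeans_offset=kmeans_offset,
        lower_offset=lower_offset,
        upper_offset=upper_offset,
    )
    logger.info(
        "retention lines: slope=%.3f, offsets lower/kmeans/upper = %.3f/%.3f/%.3f",
        slope, lower_offset, kmeans_offset, upper_offset,
    )
    return lines


# ---------------------------------------------------------------------------
# Final call table
# ---------------------------------------------------------------------------

def call_cells(
    mc: MultiomeCounts,
    profiles: tuple[AmbientProfile, AmbientProfile],
    models: tuple[LibrarySizeModel, LibrarySizeModel],
    pvals_rna: ModalityPValues,
    pvals_atac: ModalityPValues,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    retain_large: bool = False,
    multiplier: float = 1.0,
    lines: RetentionLines | None = None,
    drop_missing_modality: bool = False,
    top_percentile: float = DEFAULT_TOP_PERCENTILE,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the per-droplet call table.

    The test universe is every barcode tested in at least one modality
    (technical-error barcodes are never tested and are excluded from the BH
    correction entirely). ``FDR`` is the BH-adjusted aggregated p-value over
    that universe; ``FDR_RNA`` the BH-adjusted RNA p-value over the
    RNA-tested subset. Retention-line overrides are applied to the adjusted
    values: below the lower line FDR := 1; above the upper line FDR := 0
    when ``retain_large``. ``is_cell`` is FDR <= threshold, never True below
    the lower line (unless rescued by ``retain_large``).

    With ``drop_missing_modality`` the aggregation averages only the tested
    modalities instead of substituting p = 1 for the missing one.
    """
    t_a, t_r = library_sizes(mc)
    universe = pvals_rna.tested_mask | pvals_atac.tested_mask
    idx = np.flatnonzero(universe)
    if idx.size == 0:
        raise ValidationError("empty test universe: no droplet exceeds either b")

    p_r = pvals_rna.p_values[idx]
    p_a = pvals_atac.p_values[idx]
    if drop_missing_modality:
        p_agg = np.where(
            np.isnan(p_r), p_a, np.where(np.isnan(p_a), p_r, (p_r + p_a) / 2.0)
        )
        p_agg = np.minimum(1.0, multiplier * p_agg)
    else:
        p_agg = np.minimum(
            1.0, multiplier * (np.nan_to_num(p_r, nan=1.0) + np.nan_to_num(p_a, nan=1.0)) / 2.0
        )

    fdr = bh_adjust(p_agg)

    fdr_rna = np.full(idx.size, np.nan)
    rna_tested = ~np.isnan(p_r)
    if rna_tested.any():
        fdr_rna[rna_tested] = bh_adjust(p_r[rna_tested])

    if lines is None:
        lines = fit_retention_lines(
            t_a, t_r, models, top_percentile=top_percentile, seed=seed
        )
    with np.errstate(divide="ignore"):
        log_a = np.log10(t_a[idx].astype(float))
        log_r = np.log10(t_r[idx].astype(float))
    below = lines.below_lower(log_a, log_r)
    above = lines.above_upper(log_a, log_r)

    fdr = fdr.copy()
    fdr[below] = 1.0
    if retain_large:
        fdr[above] = 0.0

    is_cell = fdr <= fdr_threshold
    is_cell[below] = False
    if retain_large:
        is_cell[above] = True

    table = pd.DataFrame(
        {
            "barcode": mc.barcodes[idx],
            "t_rna": t_r[idx],
            "t_atac": t_a[idx],
            "p_rna": p_r,
            "p_atac": p_a,
            "p_agg": p_agg,
            "FDR": fdr,
            "FDR_RNA": fdr_rna,
            "below_lower": below,
            "above_upper": above,
            "is_cell": is_cell,
        }
    )
    logger.info(
        "called %d of %d tested droplets at FDR <= %g",
        int(is_cell.sum()), idx.size, fdr_threshold,
    )
    return table


def write_call_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_call_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
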