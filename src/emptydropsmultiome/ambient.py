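"""Ambient ("soup") profiling from the library-size structure of a run.

A raw multiome barcode list decomposes, per modality, into three library-size
clusters: a technical-error cluster (~1 count, chimeric molecules and
uncorrected barcode errors), an ambient cluster (tens of counts of
encapsulated cell-free fragments) and the nuclei-containing droplets. A
three-component Gaussian mixture in log10 count space locates the clusters;
the boundary ``b`` ending the technical-error cluster is the count where the
technical and ambient components are equally responsible, and ``l`` ending
the ambient cluster sits ``l_sigmas`` standard deviations above the ambient
mean (1.5 for RNA, 2 for ATAC by default).

The soup profile pools the counts of the ambient-cluster droplets
(``b <= t <= l``) and converts them into posterior expected per-feature
proportions with the Simple Good-Turing estimator, which reserves probability
mass for features never observed in the soup so that no observed droplet
count can have zero likelihood under the null.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .errors import BoundaryError, ModelFitError, ValidationError
from .io_matrix import MultiomeCounts

logger = logging.getLogger(__name__)

#: Default width (in fitted log10 standard deviations) of the ambient cluster
#: above its mean, per modality.
DEFAULT_L_SIGMAS = {"RNA": 1.5, "ATAC": 2.0}


@dataclass
class LibrarySizeModel:
    """Three-component Gaussian mixture over log10 library sizes.

    Components are ordered by increasing mean: technical-error, ambient,
    nuclei. ``b`` and ``l`` are on the linear count scale.
    """

    modality: str
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    b: float
    l: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.weights.shape != (3,) or self.means.shape != (3,) or self.sds.shape != (3,):
            raise ValidationError("mixture must have exactly 3 components")
        if not np.isclose(self.weights.sum(), 1.0) or np.any(self.weights <= 0):
            raise ValidationError("mixture weights must be positive and sum to 1")
        if np.any(self.sds <= 0):
            raise ValidationError("mixture sds must be positive")
        if not np.all(np.diff(self.means) > 0):
            raise ValidationError("mixture means must be strictly increasing")
        if not 0 < self.b <= self.l:
            raise ValidationError(f"boundaries must satisfy 0 < b <= l, got b={self.b}, l={self.l}")

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "b": self.b,
            "l": self.l,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LibrarySizeModel":
        return cls(
            modality=d["modality"],
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            b=float(d["b"]),
            l=float(d["l"]),
        )


@dataclass
class AmbientProfile:
    """Good-Turing posterior proportions of the soup, per modality.

    ``alpha`` (the Dirichlet-multinomial over-dispersion) is unset until
    estimated from the soup droplets (see :mod:`~emptydropsmultiome.dm_test`).
    """

    modality: str
    raw_counts: np.ndarray
    proportions: np.ndarray
    n_soup_droplets: int
    alpha: float | None = None

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.raw_counts.shape != self.proportions.shape:
            raise ValidationError("raw_counts and proportions must have equal length")
        if np.any(self.proportions < 0):
            raise ValidationError("proportions must be non-negative")
        if not np.isclose(self.proportions.sum(), 1.0, atol=1e-9):
            raise ValidationError("proportions must sum to 1 after renormalization")
        if self.alpha is not None and self.alpha <= 0:
            raise ValidationError("alpha must be positive")


# ---------------------------------------------------------------------------
# Library-size mixture fitting and cluster boundaries
# ---------------------------------------------------------------------------

def fit_library_size_model(
    totals: np.ndarray,
    modality: str,
    l_sigmas: float | None = None,
    seed: int = 0,
    b_override: float | None = None,
    l_override: float | None = None,
    max_restarts: int = 5,
) -> LibrarySizeModel:
    """Fit the 3-Gaussian mixture of log10 library sizes and derive b and l.

    Zeros (and any totals < 1) are excluded before fitting. EM is initialized
    at the 10th/50th/90th percentiles of the log10 totals with equal weights
    and a common spread, and restarted with jitter on non-convergence.
    ``b_override``/``l_override`` (count scale) replace the derived
    boundaries, for samples where the automatic choice fails.
    """
    totals = np.asarray(totals, dtype=float)
    if l_sigmas is None:
        try:
            l_sigmas = DEFAULT_L_SIGMAS[modality]
        except KeyError:
            raise ValidationError(f"unknown modality {modality!r}") from None
    log_totals = np.log10(totals[totals >= 1])
    if len(np.unique(log_totals)) < 3:
        raise ModelFitError(
            f"{modality}: fewer than 3 distinct positive library sizes; "
            "supply b/l overrides manually"
        )

    x = log_totals.reshape(-1, 1)
    # Library sizes are integers, so the low end of the log10 axis is a few
    # discrete spikes (1, 2, 3 counts) and an unregularized EM happily drops
    # two components onto neighbouring spikes. The fit therefore (a) floors
    # the component sd at 0.1 log10 units (reg_covar = sd^2), narrower than
    # any real library-size cluster, and (b) tries a sequence of inits,
    # accepting the first converged fit whose sorted means are separated by
    # at least 0.3 log10 units and that yields a valid b < l.
    p1, p10, p50, p90, p99 = np.percentile(log_totals, [1, 10, 50, 90, 99])
    rng = np.random.default_rng(seed)
    inits = [np.linspace(p1, p99, 3), np.array([p10, p50, p90])]
    span = max(p99 - p1, 0.5)
    for _ in range(max_restarts):
        inits.append(np.sort(p1 + span * rng.random(3)))
    base_sd = max(np.std(log_totals) / 3.0, 0.1)

    last_error: Exception | None = None
    converged_any = False
    for means_init in inits:
        candidate = GaussianMixture(
            n_components=3,
            covariance_type="spherical",
            weights_init=np.full(3, 1 / 3),
            means_init=np.sort(means_init).reshape(-1, 1),
            precisions_init=np.full(3, 1 / base_sd**2),
            max_iter=500,
            tol=1e-6,
            reg_covar=0.01,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            candidate.fit(x)
        if not candidate.converged_:
            continue
        converged_any = True

        order = np.argsort(candidate.means_.ravel())
        weights = candidate.weights_[order]
        means = _break_mean_ties(candidate.means_.ravel()[order])
        sds = np.sqrt(candidate.covariances_[order])
        if np.min(np.diff(means)) < 0.3:
            last_error = BoundaryError(
                f"{modality}: mixture components closer than 0.3 log10 units "
                "(likely two components on one cluster)"
            )
            continue
        try:
            if b_override is not None:
                b = float(b_override)
            else:
                b = 10 ** _density_crossing(weights, means, sds, modality)
            l = float(l_override) if l_override is not None else 10 ** (
                means[1] + l_sigmas * sds[1]
            )
            model = LibrarySizeModel(
                modality=modality, weights=weights, means=means, sds=sds, b=b, l=l
            )
        except (BoundaryError, ValidationError) as exc:
            last_error = exc
            continue
        logger.info(
            "%s library-size model: means(log10)=%s, weights=%s, b=%.3g, l=%.3g",
            modality, np.round(means, 3), np.round(weights, 3), b, l,
        )
        return model

    if not converged_any:
        raise ModelFitError(
            f"{modality}: mixture EM failed to converge for any initialization; "
            "supply b/l overrides manually"
        )
    assert last_error is not None
    raise last_error


def _break_mean_ties(means: np.ndarray) -> np.ndarray:
    means = means.copy()
    for i in range(1, 3):
        if means[i] <= means[i - 1]:
            means[i] = means[i - 1] + 1e-9
    return means


def _density_crossing(
    weights: np.ndarray, means: np.ndarray, sds: np.ndarray, modality: str
) -> float:
    """log10 count where technical- and ambient-component posteriors are equal.

    Equal responsibilities means equal weighted densities
    ``w1 N(x; m1, s1) = w2 N(x; m2, s2)``; the root is located on a 10,000
    point grid between the two means and refined by bisection to 1e-6 log10
    units. Only a closed form for equal variances exists, hence the numeric
    search.
    """
    def diff(x: float) -> float:
        return (
            weights[0] * norm.pdf(x, means[0], sds[0])
            - weights[1] * norm.pdf(x, means[1], sds[1])
        )

    grid = np.linspace(means[0], means[1], 10_000)
    values = (
        weights[0] * norm.pdf(grid, means[0], sds[0])
        - weights[1] * norm.pdf(grid, means[1], sds[1])
    )
    signs = np.sign(values)
    changes = np.flatnonzero(np.diff(signs) != 0)
    if len(changes) == 0:
        raise BoundaryError(
            f"{modality}: no density crossing between the technical and "
            "ambient components (degenerate mixture); supply a b override"
        )
    i = changes[0]
    return float(brentq(diff, grid[i], grid[i + 1], xtol=1e-6))


def soup_droplets(totals: np.ndarray, model: LibrarySizeModel) -> np.ndarray:
    """Indices of the ambient-cluster barcodes: ``{c : b <= t[c] <= l}``."""
    totals = np.asarray(totals)
    index = np.flatnonzero((totals >= model.b) & (totals <= model.l))
    if index.size == 0:
        raise ValidationError(
            f"{model.modality}: no droplets in the ambient interval "
            f"[{model.b:.3g}, {model.l:.3g}]"
        )
    return index


# ---------------------------------------------------------------------------
# Simple Good-Turing proportions
# ---------------------------------------------------------------------------

def _sgt_smoothed_counts(r: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, float]:
    """Gale-Sampson smoothed adjusted counts r* for each distinct count r.

    ``r`` are the distinct observed counts (ascending) with frequencies-of-
    frequencies ``n``. Returns (r_star, P0) where P0 = n1/N is the total
    probability reserved for unseen features. Uses the Turing estimate while
    it differs significantly (1.96 sd) from the linear-Good-Turing estimate,
    then switches to LGT for all larger counts.
    """
    N = float(np.sum(r * n))
    P0 = float(n[0] / N) if r[0] == 1 else 0.0

    # Z_r: frequencies averaged over the gap to the neighbouring counts.
    q = np.concatenate(([0.0], r[:-1].astype(float)))
    t = np.concatenate((r[1:].astype(float), [2.0 * r[-1] - q[-1]]))
    z = 2.0 * n / (t - q)

    # Linear fit of log Z on log r.
    lx = np.log(r.astype(float))
    ly = np.log(z)
    slope, intercept = np.polyfit(lx, ly, 1)
    if slope > -1.0:
        logger.warning(
            "Good-Turing log-log slope %.3f > -1; smoothing may be unreliable", slope
        )

    n_map = dict(zip(r.tolist(), n.tolist()))
    r_star = np.empty(len(r))
    use_lgt = False
    for j, rj in enumerate(r):
        r_lgt = rj * (1.0 + 1.0 / rj) ** (slope + 1.0)
        n_next = n_map.get(rj + 1)
        if not use_lgt:
            if n_next is None:
                use_lgt = True
            else:
                r_turing = (rj + 1.0) * n_next / n_map[rj]
                sd = np.sqrt(
                    (rj + 1.0) ** 2 * (n_next / n_map[rj] ** 2) * (1.0 + n_next / n_map[rj])
                )
                if abs(r_turing - r_lgt) <= 1.96 * sd:
                    use_lgt = True
                else:
                    r_star[j] = r_turing
                    continue
        r_star[j] = r_lgt
    return r_star, P0


def good_turing_proportions(raw_counts: np.ndarray) -> np.ndarray:
    """Posterior expected per-feature proportions from pooled soup counts.

    Features with a zero pooled count share the Good-Turing unseen mass
    uniformly; when every feature was observed the unseen mass is
    renormalized away. If there are no singletons or the log-log regression
    is degenerate (fewer than two distinct counts) the estimator falls back
    to add-0.1 pseudocount proportions. The result always sums to 1.
    """
    raw = np.asarray(raw_counts)
    if np.any(raw < 0):
        raise ValidationError("raw counts must be non-negative")
    total = raw.sum()
    if total <= 0:
        raise ValidationError("all-zero soup: cannot build an ambient profile")

    positive = raw[raw > 0].astype(np.int64)
    r, n = np.unique(positive, return_counts=True)
    n1 = int(n[0]) if r[0] == 1 else 0
    if n1 == 0 or len(r) < 2:
        logger.warning(
            "Good-Turing fallback (singletons=%d, distinct counts=%d): "
            "using add-0.1 pseudocount proportions", n1, len(r)
        )
        props = (raw + 0.1) / (total + 0.1 * raw.size)
        return props / props.sum()

    r_star, p0 = _sgt_smoothed_counts(r, n)
    n_star = float(np.sum(n * r_star))
    p_of_r = dict(zip(r.tolist(), ((1.0 - p0) * r_star / n_star).tolist()))

    props = np.zeros(raw.size, dtype=float)
    seen = raw > 0
    props[seen] = [p_of_r[int(c)] for c in raw[seen]]
    n_zero = int(np.sum(~seen))
    if n_zero > 0:
        props[~seen] = p0 / n_zero
    return props / props.sum()


def build_ambient_profile(
    mc: MultiomeCounts, soup_set: np.ndarray, modality: str
) -> AmbientProfile:
    """Pool the soup droplets of one modality into an :class:`AmbientProfile`.

    ``raw_counts`` are the per-feature sums over the soup barcodes;
    ``proportions`` the Simple Good-Turing posterior expectations (alpha is
    left unset).
    """
    soup_set = np.asarray(soup_set)
    if soup_set.size == 0:
        raise ValidationError("soup droplet set is empty")
    if modality == "RNA":
        matrix = mc.rna_counts
    elif modality == "ATAC":
        matrix = mc.atac_counts
    else:
        raise ValidationError(f"unknown modality {modality!r}")
    raw = np.asarray(matrix[:, soup_set].sum(axis=1)).ravel().astype(np.int64)
    props = good_turing_proportions(raw)
    return AmbientProfile(
        modality=modality,
        raw_counts=raw,
        proportions=props,
        n_soup_droplets=int(soup_set.size),
    )


# ---------------------------------------------------------------------------
# Profile persistence
# ---------------------------------------------------------------------------

def write_ambient_profile(
    profile: AmbientProfile,
    model: LibrarySizeModel,
    feature_ids: np.ndarray,
    prefix: str,
) -> None:
    """Export a profile as ``<prefix>.tsv`` (feature, proportion) plus a JSON
    sidecar ``<prefix>.json`` holding b, l, alpha and the mixture parameters."""
    with open(prefix + ".tsv", "wt") as fh:
        for fid, p in zip(feature_ids, profile.proportions):
            fh.write(f"{fid}\t{p:.17g}\n")
    sidecar = model.to_dict()
    sidecar["alpha"] = profile.alpha
    sidecar["n_soup_droplets"] = profile.n_soup_droplets
    with open(prefix + ".json", "wt") as fh:
        json.dump(sidecar, fh, indent=1)


def read_ambient_profile(prefix: str) -> tuple[AmbientProfile, LibrarySizeModel, np.ndarray]:
    """Inverse of :func:`write_ambient_profile`.

    Raw counts are not persisted; the returned profile carries zeros there.
    """
    feature_ids, props = [], []
    with open(prefix + ".tsv", "rt") as fh:
        for line in fh:
            fid, p = line.rstrip("\n").split("\t")
            feature_ids.append(fid)
            props.append(float(p))
    with open(prefix + ".json", "rt") as fh:
        sidecar = json.load(fh)
    model = LibrarySizeModel.from_dict(sidecar)
    profile = AmbientProfile(
        modality=sidecar["modality"],
        raw_counts=np.zeros(len(props), dtype=np.int64),
        proportions=np.asarray(props),
        n_soup_droplets=int(sidecar["n_soup_droplets"]),
        alpha=sidecar["alpha"],
    )
    return profile, model, np.array(feature_ids, dtype=object)
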