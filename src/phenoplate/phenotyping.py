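"""Microbial phenotype analytics: growth rates, fermentation yields,
plate anaerobicity QC, and phenotype clustering.

The scale-down workflow compares anaerobic E. coli phenotypes between pH
controlled bioreactors and 96-well microplates.  Each culture is reduced to
a seven-analyte vector — specific growth rate plus yields of acetate,
formate, lactate, pyruvate, succinate and biomass on glucose — which is
standardised and embedded with PCA (components chosen to explain >= 90% of
variance) and t-SNE (hyperparameters chosen to minimise the KL divergence
across seeded restarts).  Cluster agreement against known strain labels is
scored with the adjusted Rand index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigError, QualityError, ValidationError

#: Analyte order of the phenotype vector.
ANALYTES = ("growth_rate", "acetate", "formate", "lactate", "pyruvate",
            "succinate", "biomass")


@dataclass
class GrowthCurve:
    """OD600 time course of one culture; times in hours."""

    culture_id: str
    times: np.ndarray
    od600: np.ndarray
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape:
            raise ValidationError("times and od600 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")


@dataclass
class PhenotypeRecord:
    """One culture's condition plus its 7-analyte phenotype vector."""

    strain: str
    scale: str  # "bioreactor" | "microplate"
    initial_glucose: float  # g/L
    additive: str = ""
    growth_rate: float = np.nan  # h^-1
    yields: dict[str, float] = field(default_factory=dict)  # per mol glucose

    def vector(self) -> np.ndarray:
        return np.array([self.growth_rate] + [self.yields.get(a, np.nan)
                                              for a in ANALYTES[1:]])


def instantaneous_growth_rate(curve: GrowthCurve,
                              smoothing_window: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """mu(t) = d(ln OD)/dt via centred finite differences on a smoothed trace.

    The default 5-point window spans ~50 minutes of a 10-minute-sampled
    curve: wide enough to suppress reader noise where the log-derivative
    amplifies it (low OD), narrow enough to keep phase transitions within
    half a window of their true position.
    The moving average (centred) is applied to ln OD,
    not OD, so a pure exponential — linear in log space — passes through
    unchanged and its rate is recovered exactly.  Points where OD <= 0 are
    masked (NaN) and propagate through the smoothing window, as do the
    trace edges where no full smoothing window exists.  Returns
    ``(times, mu)`` aligned with the input times, NaN where masked.
    """
    if curve.times.size < 3:
        raise ValidationError("need >= 3 points for a growth-rate profile")
    od = curve.od600.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ln = np.where(od > 0, np.log(np.where(od > 0, od, 1.0)), np.nan)
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        smoothed = np.full_like(ln, np.nan)
        smoothed[pad:ln.size - pad] = np.convolve(ln, kernel, mode="valid")
        ln = smoothed
    t = curve.times
    mu = np.full_like(ln, np.nan)
    mu[1:-1] = (ln[2:] - ln[:-2]) / (t[2:] - t[:-2])
    return t, mu


def detect_exponential_phase(times: np.ndarray, mu: np.ndarray,
                             threshold_fraction: float = 0.7,
                             percentile: float = 95.0,
                             min_points: int = 3) -> tuple[float, float]:
    """Longest contiguous window where mu >= threshold_fraction of the
    ``percentile``-th percentile of mu.

    The percentile (rather than the max) makes the reference robust to
    single-point noise spikes.
    """
    mu = np.asarray(mu, dtype=float)
    finite = mu[np.isfinite(mu)]
    if finite.size == 0 or np.nanmax(finite) <= 0:
        raise QualityError("no positive growth rates; cannot detect an exponential phase")
    ref = np.percentile(finite, percentile)
    ok = np.isfinite(mu) & (mu >= threshold_fraction * ref)
    best = (0, -1)
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j + 1 < ok.size and ok[j + 1]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j + 1
        else:
            i += 1
    lo, hi = best
    if hi - lo + 1 < min_points:
        raise QualityError(
            f"longest qualifying window has {max(hi - lo + 1, 0)} points (< {min_points})")
    return float(times[lo]), float(times[hi])


def mean_growth_rate(times: np.ndarray, mu: np.ndarray,
                     window: tuple[float, float]) -> float:
    """Time-averaged mu over the exponential-phase window (trapezoidal)."""
    t = np.asarray(times, dtype=float)
    m = np.asarray(mu, dtype=float)
    lo, hi = window
    sel = (t >= lo) & (t <= hi) & np.isfinite(m)
    if sel.sum() < 2:
        raise ValidationError("phase window must contain >= 2 finite points")
    ts, ms = t[sel], m[sel]
    return float(np.trapezoid(ms, ts) / (ts[-1] - ts[0]))


def growth_rate_from_curve(curve: GrowthCurve, smoothing_window: int = 3) -> float:
    """Convenience: mu profile -> exponential-phase window -> mean rate."""
    t, mu = instantaneous_growth_rate(curve, smoothing_window)
    window = detect_exponential_phase(t, mu)
    return mean_growth_rate(t, mu, window)


def compute_yields(endpoint: dict[str, float], initial: dict[str, float],
                   initial_glucose: float, residual_glucose: float,
                   od_initial: float, od_final: float) -> dict[str, float]:
    """Product yields on glucose from end-point concentrations.

    yield_m = (final_m - initial_m) / (glucose consumed), mol/mol; the
    biomass yield is (OD_final - OD_initial) per mM glucose consumed and
    keeps OD-based units (no OD -> gDW factor is applied).  Negative
    apparent production (evaporation or measurement noise) floors at 0 with
    a warning.
    """
    consumed = initial_glucose - residual_glucose
    if consumed <= 0:
        raise ValidationError(
            f"glucose consumed must be > 0 (initial {initial_glucose}, residual {residual_glucose})")
    yields: dict[str, float] = {}
    for m, final_c in endpoint.items():
        y = (final_c - initial.get(m, 0.0)) / consumed
        if y < 0:
            warnings.warn(f"negative apparent production of {m} ({y:.3g}); flooring at 0",
                          stacklevel=2)
            y = 0.0
        yields[m] = y
    y_x = (od_final - od_initial) / consumed
    if y_x < 0:
        warnings.warn(f"negative apparent biomass yield ({y_x:.3g}); flooring at 0",
                      stacklevel=2)
        y_x = 0.0
    yields["biomass"] = y_x
    return yields


@dataclass
class AnaerobicityMap:
    """Per-well biomass yield ratios and their deviation from the plate median."""

    ratio: np.ndarray  # 8x12, NaN where masked
    deviation: np.ndarray  # ratio - plate median
    median: float
    iqr: float


def anaerobicity_biomass_yield(initial_od: np.ndarray, final_od: np.ndarray) -> AnaerobicityMap:
    """Final/initial OD600 ratio per well; the deviation map flags oxygen leaks.

    Under sustained anaerobiosis every well shows the same modest yield, so
    wells deviating far above the plate median indicate local oxygen
    penetration (e.g. a failing seal near plate edges).  Wells with zero or
    negative initial OD are masked.
    """
    init = np.asarray(initial_od, dtype=float)
    fin = np.asarray(final_od, dtype=float)
    if init.shape != fin.shape:
        raise ValidationError("initial and final OD grids must be aligned")
    ratio = np.where(init > 0, fin / np.where(init > 0, init, 1.0), np.nan)
    med = float(np.nanmedian(ratio))
    q1, q3 = np.nanpercentile(ratio, [25, 75])
    return AnaerobicityMap(ratio=ratio, deviation=ratio - med,
                           median=med, iqr=float(q3 - q1))


@dataclass
class FeatureScaling:
    """Column-wise standardisation parameters, with inverse transform."""

    mean: np.ndarray
    sd: np.ndarray
    kept_columns: list[str]
    dropped_columns: list[str]

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return scaled * self.sd + self.mean


def scale_features(records: pd.DataFrame,
                   columns: tuple[str, ...] = ANALYTES) -> tuple[np.ndarray, FeatureScaling]:
    """Standardise analyte columns to zero mean and unit variance.

    Zero-variance columns carry no information for an embedding and are
    dropped with a warning.
    """
    X = records.loc[:, list(columns)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    # constant columns have sd at rounding level, not exactly zero
    keep = sd > 1e-12 * np.maximum(np.abs(X.mean(axis=0)), 1.0)
    if not np.all(keep):
        dropped = [c for c, k in zip(columns, keep) if not k]
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    else:
        dropped = []
    kept = [c for c, k in zip(columns, keep) if k]
    mean = X[:, keep].mean(axis=0)
    scaled = (X[:, keep] - mean) / sd[keep]
    return scaled, FeatureScaling(mean=mean, sd=sd[keep],
                                  kept_columns=kept, dropped_columns=dropped)


@dataclass
class EmbeddingResult:
    method: str  # "pca" | "tsne"
    coordinates: np.ndarray
    explained_variance: np.ndarray | None = None  # PCA, per retained component
    n_components: int | None = None
    kl_divergence: float | None = None  # t-SNE
    perplexity: float | None = None
    learning_rate: float | None = None
    seed: int | None = None


def run_pca(scaled: np.ndarray, variance_target: float = 0.90) -> EmbeddingResult:
    """PCA retaining the smallest number of components whose cumulative
    explained variance reaches ``variance_target`` (default the 90% rule).

    Component signs follow a deterministic convention: the largest-|loading|
    element of each component is made positive.
    """
    X = np.asarray(scaled, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 records and >= 2 features")
    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
    k = min(k, evr.size)
    comps = pca.components_[:k]
    signs = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    return EmbeddingResult(method="pca", coordinates=scores[:, :k] * signs,
                           explained_variance=evr[:k], n_components=k)


def run_tsne(scaled: np.ndarray, perplexities=(5.0, 10.0),
             learning_rates=(200.0,), restarts: int = 3,
             seed: int = 20210923) -> EmbeddingResult:
    """2-D t-SNE with hyperparameters selected by the KL objective.

    For every (perplexity, learning rate) pair the embedding is fitted
    ``restarts`` times from distinct seeds; the configuration with the
    lowest mean final KL divergence wins ("most robust"), and the single
    restart with the lowest KL under that configuration is returned.
    """
    X = np.asarray(scaled, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValidationError("t-SNE needs >= 5 records")
    feasible = [p for p in perplexities if p < (n - 1) / 3]
    if not feasible:
        raise ConfigError(
            f"no feasible perplexity for n={n}: all of {list(perplexities)} >= (n-1)/3")
    rng = np.random.default_rng(seed)
    run_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=restarts)]
    best_cfg = None  # (mean_kl, perplexity, lr, runs)
    for perp in feasible:
        for lr in learning_rates:
            runs = []
            for s in run_seeds:
                ts = TSNE(n_components=2, perplexity=perp, learning_rate=lr,
                          init="random", random_state=s)
                emb = ts.fit_transform(X)
                runs.append((float(ts.kl_divergence_), s, emb))
            mean_kl = float(np.mean([kl for kl, _, _ in runs]))
            if best_cfg is None or mean_kl < best_cfg[0]:
                best_cfg = (mean_kl, perp, lr, runs)
    _, perp, lr, runs = best_cfg
    kl, s, emb = min(runs, key=lambda r: r[0])
    return EmbeddingResult(method="tsne", coordinates=emb, kl_divergence=kl,
                           perplexity=float(perp), learning_rate=float(lr), seed=s)


def cluster_agreement(coordinates: np.ndarray, reference_labels, k: int,
                      seed: int = 0) -> tuple[float, pd.DataFrame]:
    """k-means the embedding and score it against reference labels.

    Returns the adjusted Rand index (1 = identical partitions, ~0 = chance)
    and the cluster x label contingency table.
    """
    labels = np.asarray(reference_labels)
    if k < 2:
        raise ValidationError("need k >= 2 clusters")
    if labels.size != np.asarray(coordinates).shape[0]:
        raise ValidationError("one reference label per record is required")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assigned = km.fit_predict(np.asarray(coordinates, dtype=float))
    ari = float(adjusted_rand_score(labels, assigned))
    table = pd.crosstab(pd.Series(assigned, name="cluster"),
                        pd.Series(labels, name="label"))
    return ari, table
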