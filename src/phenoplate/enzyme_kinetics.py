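"""Anaerobic enzyme kinetics from kinetic A340 plate reads.

NADPH absorbs at 340 nm, so an NADPH-consuming reaction (here the enoate
reductase YqjM reducing 2-cyclohexen-1-one) shows a falling A340 trace.
The initial rate is the OLS slope over the earliest well-fitting window of
reads, converted to a reaction rate via Beer--Lambert

    rate [umol/min] = |dA/dt| / (epsilon * l) * V

with epsilon = 6.3 mM^-1 cm^-1 for NADPH, path length l = 0.56 cm for a
200 uL fill, and reaction volume V in mL (mM * mL = umol).  Rates across a
substrate titration are fitted to the Michaelis--Menten law
v = V_max * S / (K_M + S) by non-linear least squares; activities across a
pH screen are summarised into a pH--activity profile with its optimum band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, QualityError, ValidationError


@dataclass(frozen=True)
class AssayContext:
    """Physical constants of one photometric assay."""

    epsilon: float = 6.3  # mM^-1 cm^-1, NADPH at 340 nm
    path_length: float = 0.56  # cm, 200 uL in a standard 96-well
    reaction_volume: float = 0.2  # mL
    enzyme_concentration: float = 15.0  # nM
    substrate: str = "2-cyclohexen-1-one"

    def __post_init__(self) -> None:
        if min(self.epsilon, self.path_length, self.reaction_volume,
               self.enzyme_concentration) <= 0:
            raise ValidationError("assay context values must all be positive")


@dataclass
class InitialRate:
    """Initial-rate estimate for one well's kinetic trace."""

    well: str
    slope: float  # dA/min, signed
    window: tuple[float, float]  # [t_start, t_end] minutes
    window_r_squared: float
    rate: float | None = None  # umol/min, filled by rate_to_activity


def _window_ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and r^2 of OLS on one window; a perfect (incl. flat) fit has r^2 = 1."""
    tc = t - t.mean()
    denom = float(np.sum(tc**2))
    slope = float(np.sum(tc * (y - y.mean())) / denom)
    resid = y - (y.mean() + slope * tc)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0.0:
        return slope, 1.0
    return slope, 1.0 - ss_res / ss_tot


def extract_initial_rate(times, values, well: str = "",
                         window_points: int = 5, min_r2: float = 0.98) -> InitialRate:
    """Slope over the earliest window of ``window_points`` consecutive reads
    whose linear fit reaches ``min_r2``.

    The earliest qualifying window (not the globally best one) is used
    because early reads approximate the true initial rate before substrate
    depletion bends the trace.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValidationError("times and values must have equal length")
    if t.size < window_points:
        raise ValidationError(
            f"trace has {t.size} reads, fewer than window_points={window_points}")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    best_r2 = -np.inf
    for i in range(t.size - window_points + 1):
        tw, yw = t[i:i + window_points], y[i:i + window_points]
        slope, r2 = _window_ols(tw, yw)
        if r2 >= min_r2:
            return InitialRate(well=well, slope=slope,
                               window=(float(tw[0]), float(tw[-1])),
                               window_r_squared=r2)
        best_r2 = max(best_r2, r2)
    raise QualityError(
        f"well {well or '?'}: no {window_points}-point window reaches r^2 >= {min_r2} "
        f"(best r^2 = {best_r2:.4f})")


def rate_to_activity(slope: float, ctx: AssayContext) -> float:
    """Convert a photometric slope (dA/min) to a reaction rate in umol/min.

    Depletion assays give negative slopes; activity is reported as the
    magnitude (the sign stays on the InitialRate).
    """
    return abs(slope) / (ctx.epsilon * ctx.path_length) * ctx.reaction_volume


@dataclass
class MMFit:
    """Michaelis--Menten parameters with asymptotic standard errors."""

    K_M: float  # mM
    V_max: float  # umol/min
    se_K_M: float
    se_V_max: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.K_M <= 0 or self.V_max <= 0:
            raise FitError("K_M and V_max must both be positive")

    def predict(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.V_max * S / (self.K_M + S)


def _mm(S, vmax, km):
    return vmax * S / (km + S)


def fit_michaelis_menten(substrate, rates) -> MMFit:
    """Non-linear least-squares fit of v = V_max*S/(K_M+S).

    Initialised at V_max = max observed rate and K_M = the (interpolated)
    substrate concentration at half-maximal rate; both parameters are
    bounded positive.  Standard errors come from the Jacobian-based
    covariance of the fit.
    """
    S = np.asarray(substrate, dtype=float)
    v = np.asarray(rates, dtype=float)
    if S.shape != v.shape:
        raise ValidationError("substrate and rate arrays must match")
    if np.unique(S).size < 4:
        raise FitError(f"need >= 4 distinct substrate concentrations, got {np.unique(S).size}")
    if np.any(v < 0):
        raise ValidationError("rates must be >= 0")
    if np.all(v == 0):
        raise FitError("all rates are zero; nothing to fit")
    vmax0 = float(v.max())
    order = np.argsort(S)
    km0 = float(np.interp(vmax0 / 2.0, v[order], S[order]))
    km0 = max(km0, 1e-6)
    try:
        popt, pcov = curve_fit(_mm, S, v, p0=[vmax0, km0],
                               bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                               maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = map(float, popt)
    se = np.sqrt(np.diag(pcov))
    pred = _mm(S, vmax, km)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((v - pred) ** 2)) / ss_tot
    return MMFit(K_M=km, V_max=vmax, se_K_M=float(se[1]), se_V_max=float(se[0]),
                 r_squared=r2, n_points=int(S.size))


def ph_profile(activities_by_ph: dict[float, np.ndarray] | pd.DataFrame,
               optimum_fraction: float = 0.9) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Mean +/- sd activity per pH level plus the optimum band.

    The optimum band is the contiguous run of pH levels, containing the
    argmax, whose mean activity stays within ``1 - optimum_fraction`` (10%
    by default) of the maximum mean.
    """
    if isinstance(activities_by_ph, pd.DataFrame):
        grouped = {float(ph): g["activity"].to_numpy()
                   for ph, g in activities_by_ph.groupby("ph")}
    else:
        grouped = {float(ph): np.asarray(a, dtype=float)
                   for ph, a in activities_by_ph.items()}
    if len(grouped) < 2:
        raise ValidationError("a pH profile needs >= 2 pH levels")
    phs = np.array(sorted(grouped))
    means = np.array([grouped[p].mean() for p in phs])
    sds = np.array([grouped[p].std(ddof=1) if grouped[p].size > 1 else 0.0 for p in phs])
    table = pd.DataFrame({"ph": phs, "mean_activity": means, "sd_activity": sds,
                          "n": [grouped[p].size for p in phs]})
    cutoff = optimum_fraction * means.max()
    qualifies = means >= cutoff
    peak = int(np.argmax(means))
    lo = peak
    while lo > 0 and qualifies[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(phs) - 1 and qualifies[hi + 1]:
        hi += 1
    return table, (float(phs[lo]), float(phs[hi]))
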