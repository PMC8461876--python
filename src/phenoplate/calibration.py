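"""Photometric pipette calibration for fixed-tip liquid handlers.

A potassium-dichromate standard obeys Beer--Lambert at 350 nm, so absorbance
is linear in dispensed volume within each of three working ranges
(low 3--10, mid 10--50, high 50--200 uL).  A standard curve fitted on
manually pipetted levels converts robot-dispensed absorbances back into
volumes; per-tip linear fits of actual on programmed volume then yield
calibration parameters ``actual = a * programmed + b`` whose inversion gives
the volume to program for a desired dispense.  Accuracy is summarised as
systematic error and coefficient of variation per (tip, volume) group and
checked against user-supplied limits (e.g. ISO 8655, which publishes them
but we do not hard-code).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, FitError, ValidationError
from .plate_io import PlateLayout, ReaderData


@dataclass(frozen=True)
class VolumeRangeSpec:
    """One of the three pipetting ranges, with its calibration design."""

    name: str
    bounds: tuple[float, float]  # uL
    levels: tuple[float, ...]
    replicates: int = 3
    standard_concentration: float | None = None  # mM, associated via layout

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not lo < hi:
            raise ValidationError(f"range {self.name}: lower bound must be < upper")
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError(f"range {self.name}: levels must be distinct")
        for v in self.levels:
            if not lo <= v <= hi:
                raise ValidationError(f"range {self.name}: level {v} uL outside bounds {self.bounds}")


def _levels(lo: float, hi: float, n: int = 8) -> tuple[float, ...]:
    return tuple(np.round(np.linspace(lo, hi, n), 3))


#: The three working ranges with eight levels each, pipetted in triplicate.
#: Each range uses its own dichromate stock (0.4 / 1 / 2 mM).
DEFAULT_RANGES: dict[str, VolumeRangeSpec] = {
    "low": VolumeRangeSpec("low", (3.0, 10.0), _levels(3, 10), 3, 2.0),
    "mid": VolumeRangeSpec("mid", (10.0, 50.0), _levels(10, 50), 3, 1.0),
    "high": VolumeRangeSpec("high", (50.0, 200.0), _levels(50, 200), 3, 0.4),
}


@dataclass
class StandardCurve:
    """Linear absorbance-vs-volume fit of manually pipetted standards."""

    slope: float  # absorbance per uL
    intercept: float  # absorbance
    r_squared: float
    valid_volume_range: tuple[float, float]
    wavelength: float = 350.0
    standard_concentration: float | None = None
    absorbance_span: tuple[float, float] = (-np.inf, np.inf)
    se_slope: float = 0.0
    se_intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise FitError(f"standard curve slope must be > 0, got {self.slope}")


@dataclass
class ErrorReport:
    """Accuracy summary for one (tip, programmed volume) replicate group."""

    tip_id: int
    programmed_volume: float
    mean_estimated_volume: float
    systematic_error: float  # % = 100*(mean - programmed)/programmed
    cv: float | None  # % = 100*sd/mean; None when n_replicates == 1
    n_replicates: int
    range_name: str = ""


@dataclass
class TipCalibration:
    """Per-tip, per-range linear map: actual = a * programmed + b."""

    tip_id: int
    range_name: str
    a: float
    b: float  # uL
    residual_sd: float
    r_squared: float
    se_a: float = np.nan
    se_b: float = np.nan
    programmed_range: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise FitError(f"tip {self.tip_id}: calibration slope must be > 0, got {self.a}")

    def forward(self, programmed: float) -> float:
        """Volume actually dispensed when ``programmed`` is requested."""
        return self.a * programmed + self.b


@dataclass
class AccuracyLimits:
    """Volume-indexed accuracy limits: volume -> (max |systematic error| %, max cv %)."""

    limits: dict[float, tuple[float, float]]
    source: str = "user-supplied"

    def __post_init__(self) -> None:
        if not self.limits:
            raise ConfigError("accuracy limits table is empty")
        for v, (e, c) in self.limits.items():
            if e <= 0 or c <= 0:
                raise ConfigError(f"limits at {v} uL must be positive")

    def lookup(self, volume: float) -> tuple[float, float]:
        """Limits at the nearest defined volume at or below; else the smallest defined."""
        defined = sorted(self.limits)
        at_or_below = [v for v in defined if v <= volume]
        key = at_or_below[-1] if at_or_below else defined[0]
        return self.limits[key]


def _ols_line(x: np.ndarray, y: np.ndarray):
    """OLS of y on x returning slope, intercept, r^2, se_slope, se_intercept, residual sd."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise FitError(f"need >= 3 points for a linear fit, got {x.size}")
    if np.unique(x).size < 2:
        raise FitError("degenerate design: no variance in the predictor")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    resid = y - pred
    dof = max(x.size - 2, 1)
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return (float(res.slope), float(res.intercept), r2,
            float(res.stderr), float(res.intercept_stderr), resid_sd)


def fit_standard_curve(known_volumes, absorbances,
                       range_spec: VolumeRangeSpec | None = None,
                       wavelength: float = 350.0) -> StandardCurve:
    """OLS fit of absorbance on manually pipetted volume.

    Requires >= 3 distinct volumes.  The curve records the volume and
    absorbance spans of its inputs so later estimates can be flagged as
    extrapolated.
    """
    v = np.asarray(known_volumes, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if v.shape != a.shape:
        raise ValidationError("volumes and absorbances must have the same length")
    if not np.all(np.isfinite(a)):
        raise ValidationError("absorbances must be finite")
    if np.unique(v).size < 3:
        raise FitError(f"need >= 3 distinct volumes, got {np.unique(v).size}")
    slope, intercept, r2, se_s, se_i, _ = _ols_line(v, a)
    return StandardCurve(
        slope=slope, intercept=intercept, r_squared=r2,
        valid_volume_range=(float(v.min()), float(v.max())),
        wavelength=wavelength,
        standard_concentration=range_spec.standard_concentration if range_spec else None,
        absorbance_span=(float(a.min()), float(a.max())),
        se_slope=se_s, se_intercept=se_i,
    )


@dataclass
class VolumeEstimate:
    well: str
    volume: float  # uL
    absorbance: float
    extrapolated: bool


def estimate_volumes(curve: StandardCurve, reader: ReaderData,
                     layout: PlateLayout, blank_correct: bool = True) -> dict[str, VolumeEstimate]:
    """Invert the standard curve on each sample well: v = (A - intercept)/slope.

    The mean absorbance of layout-designated blank wells is subtracted first
    (the intercept absorbs any residual offset).  Wells whose absorbance
    falls outside the curve's fitted span are flagged extrapolated.
    """
    if reader.mode != "endpoint":
        raise ValidationError("volume estimation expects an endpoint read")
    blank = 0.0
    blanks = [reader.values[w] for w in layout.wells_with_role("blank") if w in reader.values]
    if blank_correct and blanks:
        blank = float(np.mean(blanks))
    lo_a, hi_a = curve.absorbance_span
    out: dict[str, VolumeEstimate] = {}
    for addr, spec in layout.wells_with_role("sample").items():
        if addr not in reader.values:
            continue
        a = float(reader.values[addr]) - blank
        v = (a - curve.intercept) / curve.slope
        out[addr] = VolumeEstimate(addr, v, a, not (lo_a <= a <= hi_a))
    return out


def pipetting_error(groups: pd.DataFrame) -> list[ErrorReport]:
    """Summarise accuracy per (tip_id, range, programmed_volume) group.

    ``groups`` needs columns tip_id, programmed_volume, estimated_volume and
    optionally range_name.  Systematic error is the percent deviation of the
    replicate mean from the programmed volume; CV uses the sample (n-1)
    standard deviation and is None for singleton groups.
    """
    df = groups.copy()
    if "range_name" not in df.columns:
        df["range_name"] = ""
    reports: list[ErrorReport] = []
    for (tip, rng, prog), g in df.groupby(["tip_id", "range_name", "programmed_volume"], sort=True):
        if prog == 0:
            raise ValidationError("systematic error undefined at programmed volume 0")
        est = g["estimated_volume"].to_numpy(dtype=float)
        mean = float(est.mean())
        cv = None
        if est.size > 1:
            sd = float(est.std(ddof=1))
            cv = 100.0 * sd / mean if mean != 0 else np.inf
        reports.append(ErrorReport(
            tip_id=int(tip), programmed_volume=float(prog), mean_estimated_volume=mean,
            systematic_error=100.0 * (mean - prog) / prog, cv=cv,
            n_replicates=int(est.size), range_name=str(rng)))
    return reports


def fit_tip_calibration(programmed, estimated, tip_id: int,
                        range_name: str = "") -> TipCalibration:
    """OLS of estimated (actual) volume on programmed volume for one tip."""
    p = np.asarray(programmed, dtype=float)
    if np.unique(p).size < 3:
        raise FitError(f"tip {tip_id}: need >= 3 distinct programmed volumes")
    a, b, r2, se_a, se_b, resid_sd = _ols_line(p, np.asarray(estimated, dtype=float))
    return TipCalibration(tip_id=tip_id, range_name=range_name, a=a, b=b,
                          residual_sd=resid_sd, r_squared=r2, se_a=se_a, se_b=se_b,
                          programmed_range=(float(p.min()), float(p.max())))


def corrected_volume(cal: TipCalibration, desired: float) -> float:
    """Volume to program so that ``desired`` uL is actually dispensed.

    Inverts actual = a*programmed + b.  A result outside the calibrated
    programmed range is clipped to it with a warning rather than trusted.
    """
    prog = (desired - cal.b) / cal.a
    lo, hi = cal.programmed_range
    if prog < lo or prog > hi:
        warnings.warn(
            f"tip {cal.tip_id}: corrected volume {prog:.2f} uL outside calibrated "
            f"range [{lo}, {hi}]; clipping", stacklevel=2)
        prog = float(np.clip(prog, lo, hi))
    return float(prog)


def compliance_check(reports: list[ErrorReport], limits: AccuracyLimits) -> pd.DataFrame:
    """Pass/fail each group: |systematic error| <= limit AND cv <= limit (inclusive)."""
    rows = []
    for r in reports:
        max_err, max_cv = limits.lookup(r.programmed_volume)
        ok_err = abs(r.systematic_error) <= max_err
        ok_cv = True if r.cv is None else r.cv <= max_cv
        rows.append({
            "tip_id": r.tip_id, "range_name": r.range_name,
            "programmed_volume": r.programmed_volume,
            "systematic_error": r.systematic_error, "cv": r.cv,
            "limit_error": max_err, "limit_cv": max_cv,
            "pass": bool(ok_err and ok_cv),
        })
    return pd.DataFrame(rows)


def calibrate_plates(curve: StandardCurve,
                     plates: list[tuple[PlateLayout, ReaderData]],
                     range_spec: VolumeRangeSpec | None = None) -> tuple[
                         list[ErrorReport], list[TipCalibration]]:
    """Calibrate every tip from one or more sample plates sharing a curve.

    Used when the standard curve was fitted separately (e.g. on manually
    pipetted standards of the same dichromate stock).

    Every volume estimate inherits the curve's own uncertainty: an error in
    the curve slope rescales all estimates, one in the curve intercept
    shifts them.  Both are propagated into the reported per-tip standard
    errors (in quadrature with the OLS errors), without which the nominal
    coverage of the tip parameters would be overstated.
    """
    rows = []
    for layout, reader in plates:
        for addr, est in estimate_volumes(curve, reader, layout).items():
            spec = layout.wells[addr]
            if spec.tip_id is None or spec.programmed_volume is None:
                raise ValidationError(f"sample well {addr} lacks tip_id or programmed_volume")
            rows.append({"tip_id": spec.tip_id, "programmed_volume": spec.programmed_volume,
                         "estimated_volume": est.volume,
                         "range_name": range_spec.name if range_spec else ""})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no sample wells found on the given plates")
    reports = pipetting_error(df)
    rel_slope = curve.se_slope / curve.slope
    shift = curve.se_intercept / curve.slope
    cals = []
    for tip, g in df.groupby("tip_id"):
        c = fit_tip_calibration(g["programmed_volume"], g["estimated_volume"],
                                tip_id=int(tip),
                                range_name=range_spec.name if range_spec else "")
        c.se_a = float(np.hypot(c.se_a, abs(c.a) * rel_slope))
        c.se_b = float(np.sqrt(c.se_b**2 + shift**2 + (c.b * rel_slope) ** 2))
        cals.append(c)
    return reports, cals


def calibrate_plate(layout: PlateLayout, reader: ReaderData,
                    range_spec: VolumeRangeSpec | None = None) -> tuple[
                        StandardCurve, list[ErrorReport], list[TipCalibration]]:
    """Full photometric calibration of one plate.

    Standard wells (manually pipetted, volume in ``programmed_volume``)
    define the curve; sample wells are inverted to volumes, summarised per
    (tip, programmed volume), and fitted per tip.
    """
    std = layout.wells_with_role("standard")
    if not std:
        raise ValidationError("layout has no standard wells to fit a curve on")
    blanks = [reader.values[w] for w in layout.wells_with_role("blank") if w in reader.values]
    blank = float(np.mean(blanks)) if blanks else 0.0
    vols = [s.programmed_volume for s in std.values()]
    if any(v is None for v in vols):
        raise ValidationError("every standard well needs its manually pipetted volume")
    absorb = [float(reader.values[w]) - blank for w in std]
    curve = fit_standard_curve(vols, absorb, range_spec, wavelength=reader.wavelength)
    estimates = estimate_volumes(curve, reader, layout)
    rows = []
    for addr, est in estimates.items():
        spec = layout.wells[addr]
        if spec.tip_id is None or spec.programmed_volume is None:
            raise ValidationError(f"sample well {addr} lacks tip_id or programmed_volume")
        rows.append({"tip_id": spec.tip_id, "programmed_volume": spec.programmed_volume,
                     "estimated_volume": est.volume,
                     "range_name": range_spec.name if range_spec else ""})
    df = pd.DataFrame(rows)
    reports = pipetting_error(df)
    cals = []
    for tip, g in df.groupby("tip_id"):
        cals.append(fit_tip_calibration(
            g["programmed_volume"], g["estimated_volume"], tip_id=int(tip),
            range_name=range_spec.name if range_spec else ""))
    return curve, reports, cals
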