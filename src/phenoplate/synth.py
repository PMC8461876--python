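"""Synthetic-data generators with the statistical structure each pipeline
stage assumes, so every analysis is testable without instruments.

Every generator is a pure function of its parameters and a seed (identical
seeds give identical outputs) and returns its ground truth alongside the
data, so tests never have to re-infer truth from the data they check.

What is emulated, per generator:

* calibration plates — per-tip linear pipetting bias (actual = a*programmed
  + b) read through a linear absorbance standard with Gaussian noise;
* decontamination outcomes — Bernoulli growth per well at a per-condition
  sterile probability;
* NADPH-depletion traces — falling A340 at an initial slope set by the
  Michaelis--Menten rate at each substrate level, flattening when NADPH
  runs out;
* anaerobic growth curves — three growth-rate regimes (dissolved oxygen,
  oxygen transfer, anaerobic) with saturation and OD noise;
* strain phenotype datasets — 7-analyte archetype means with glucose
  response slopes, multivariate noise, and cluster structure (two evolved
  mutants drawn from one distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import DEFAULT_RANGES, VolumeRangeSpec
from .enzyme_kinetics import AssayContext
from .errors import ConfigError, ValidationError
from .phenotyping import ANALYTES, GrowthCurve
from .plate_io import N_COLS, N_ROWS, PlateLayout, ReaderData, WellSpec, index_to_well
from .sterility_qc import ContaminationOutcome


@dataclass
class TipBiasModel:
    """Per-tip linear pipetting bias plus the photometric read-out model.

    Default slopes span the degraded-accuracy regime seen after enlarging
    the pipetting air-gap, where systematic errors reach tens of percent
    (up to ~40%) and differ strongly between tips.
    """

    slopes: dict[int, float] = field(default_factory=lambda: {
        1: 0.62, 2: 0.78, 3: 0.88, 4: 0.97, 5: 1.05, 6: 1.14, 7: 1.26, 8: 1.38})
    intercepts: dict[int, float] = field(default_factory=lambda: {
        1: 0.6, 2: -0.4, 3: 0.3, 4: 0.0, 5: -0.2, 6: 0.4, 7: -0.5, 8: 0.2})
    noise_sd: float = 0.003  # absorbance units
    curve_slope: float | None = None  # absorbance per uL; None -> ~2 AU at range top
    curve_intercept: float = 0.05

    def __post_init__(self) -> None:
        for tip, a in self.slopes.items():
            if not 0.5 < a < 1.5:
                raise ValidationError(f"tip {tip}: bias slope {a} outside (0.5, 1.5)")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")

    def actual_volume(self, tip: int, programmed: float) -> float:
        return self.slopes[tip] * programmed + self.intercepts[tip]


@dataclass
class CalibrationSim:
    """One simulated calibration experiment for a single volume range."""

    plates: list[tuple[PlateLayout, ReaderData]]
    standard_volumes: np.ndarray
    standard_absorbances: np.ndarray
    truth: pd.DataFrame  # tip_id, programmed_volume, actual_volume, well, plate
    curve_slope: float
    curve_intercept: float


def gen_calibration_plate(bias: TipBiasModel, range_spec: VolumeRangeSpec | None = None,
                          seed: int = 0) -> CalibrationSim:
    """Simulate the calibration design: 8 tips x 8 levels x 3 replicates.

    Each tip owns one plate row; levels x replicates fill the 12 columns,
    splitting across as many plates as needed (24 combinations -> 2 plates).
    Absorbance = curve(actual volume) + Gaussian noise.  Manually pipetted
    standards (no tip bias) at the same levels are returned for curve
    fitting, and the per-well truth table records every actual volume.
    """
    if range_spec is None:
        range_spec = DEFAULT_RANGES["high"]
    rng = np.random.default_rng(seed)
    levels = list(range_spec.levels)
    reps = range_spec.replicates
    combos = [(v, r) for v in levels for r in range(reps)]
    if len(combos) > 4 * N_COLS:
        raise ConfigError(
            f"{len(levels)} levels x {reps} replicates = {len(combos)} wells per tip "
            "cannot be laid out")
    c_slope = bias.curve_slope
    if c_slope is None:
        c_slope = 2.0 / range_spec.bounds[1]
    n_plates = int(np.ceil(len(combos) / N_COLS))
    tips = sorted(bias.slopes)

    std_v = np.repeat(levels, reps).astype(float)
    std_a = c_slope * std_v + bias.curve_intercept + rng.normal(0, bias.noise_sd, std_v.size)

    plates: list[tuple[PlateLayout, ReaderData]] = []
    truth_rows = []
    for p in range(n_plates):
        chunk = combos[p * N_COLS:(p + 1) * N_COLS]
        wells: dict[str, WellSpec] = {}
        values: dict[str, float] = {}
        pid = f"{range_spec.name}-cal-{p + 1}"
        for row, tip in enumerate(tips[:N_ROWS]):
            for col, (vol, rep) in enumerate(chunk):
                addr = index_to_well(row, col)
                actual = bias.actual_volume(tip, vol)
                a = c_slope * actual + bias.curve_intercept + rng.normal(0, bias.noise_sd)
                wells[addr] = WellSpec(role="sample", content="K2Cr2O7", tip_id=tip,
                                       programmed_volume=float(vol),
                                       replicate_id=str(rep + 1))
                values[addr] = float(a)
                truth_rows.append({"plate_id": pid, "well": addr, "tip_id": tip,
                                   "programmed_volume": float(vol),
                                   "actual_volume": float(actual)})
        plates.append((PlateLayout(pid, wells),
                       ReaderData(pid, 350.0, "endpoint", values)))
    return CalibrationSim(plates=plates, standard_volumes=std_v,
                          standard_absorbances=std_a,
                          truth=pd.DataFrame(truth_rows),
                          curve_slope=float(c_slope),
                          curve_intercept=float(bias.curve_intercept))


def gen_contamination_outcomes(p_sterile: dict[tuple, float] | list[tuple[dict, float]],
                               n_wells: int, seed: int = 0) -> list[tuple[ContaminationOutcome, float]]:
    """Bernoulli growth outcomes per condition.

    ``p_sterile`` is a list of (condition dict, sterile probability) pairs.
    Returns (outcome, true p_sterile) pairs so the truth travels with the
    data.
    """
    rng = np.random.default_rng(seed)
    if isinstance(p_sterile, dict):
        p_sterile = [(dict(cond) if isinstance(cond, dict) else {"condition": cond}, p)
                     for cond, p in p_sterile.items()]
    out = []
    for cond, p in p_sterile:
        if not 0 <= p <= 1:
            raise ValidationError(f"p_sterile must be in [0,1], got {p}")
        grew = rng.random(n_wells) >= p  # grew = not sterile
        out.append((ContaminationOutcome(condition=dict(cond), outcomes=grew), float(p)))
    return out


@dataclass
class MMTraceSim:
    reader: ReaderData
    layout: dict[str, float]  # well -> substrate mM
    true_K_M: float
    true_V_max: float
    true_slopes: dict[str, float]  # dA/min per well, signed


def gen_mm_traces(K_M: float, V_max: float, substrate_levels,
                  ctx: AssayContext | None = None, noise_sd: float = 0.0,
                  seed: int = 0, replicates: int = 3, nadph0: float = 0.15,
                  t_end: float = 2.0, n_reads: int = 21) -> MMTraceSim:
    """Kinetic A340 traces of an NADPH-depletion assay across a substrate
    titration.

    Each trace starts at A0 = epsilon*l*[NADPH]0 (0.15 mM NADPH) and falls
    at the Michaelis--Menten rate for its substrate level until NADPH is
    exhausted, plus Gaussian read noise.  Wells fill row-major, one row per
    substrate level.  The default 6-second read interval over 2 minutes
    resolves the initial slope even at saturating substrate, where NADPH is
    gone within the first minute.
    """
    ctx = ctx or AssayContext()
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_end, n_reads)
    el = ctx.epsilon * ctx.path_length
    a0 = el * nadph0
    values: dict[str, np.ndarray] = {}
    layout: dict[str, float] = {}
    slopes: dict[str, float] = {}
    levels = list(substrate_levels)
    if len(levels) > N_ROWS or replicates > N_COLS:
        raise ConfigError("substrate titration does not fit one plate")
    for row, S in enumerate(levels):
        v = V_max * S / (K_M + S)  # umol/min
        d_nadph = v / ctx.reaction_volume  # mM/min
        for rep in range(replicates):
            addr = index_to_well(row, rep)
            nadph = np.clip(nadph0 - d_nadph * times, 0.0, None)
            trace = el * nadph + rng.normal(0, noise_sd, times.size)
            values[addr] = trace
            layout[addr] = float(S)
            slopes[addr] = -d_nadph * el
    reader = ReaderData("mm-assay", 340.0, "kinetic", values, times=times)
    return MMTraceSim(reader=reader, layout=layout, true_K_M=float(K_M),
                      true_V_max=float(V_max), true_slopes=slopes)


def gen_mm_rates(K_M: float, V_max: float, substrate_levels,
                 replicates: int = 3, noise_fraction: float = 0.05,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Initial rates across a substrate titration, with Gaussian rate noise.

    Noise sd is ``noise_fraction * V_max`` (a homoscedastic 5% of the
    maximal rate by default, the usual error scale of a well-run photometric
    assay); negative draws clip at zero.  Returns ``(S, v)`` with
    ``len(levels) * replicates`` points.
    """
    rng = np.random.default_rng(seed)
    S = np.repeat(np.asarray(substrate_levels, dtype=float), replicates)
    v = V_max * S / (K_M + S) + rng.normal(0, noise_fraction * V_max, S.size)
    return S, np.clip(v, 0.0, None)


@dataclass
class GrowthSim:
    curves: list[GrowthCurve]
    truth: pd.DataFrame  # culture_id, condition, mu1, mu2, mu3, t1, t2


def gen_growth_curves(conditions=("oil_anaerobic", "oil_aerobic", "no_oil_aerobic"),
                      mu1: float = 0.55, mu2: float = 0.75, mu3: float = 0.30,
                      t1: float = 2.0, t2: float = 4.0, od0: float = 0.05,
                      carrying_capacity: float = 1.2, noise_sd: float = 0.0,
                      t_end: float = 10.0, dt_min: float = 10.0,
                      seed: int = 0) -> GrowthSim:
    """Three-regime anaerobic growth curves.

    Regime I (t < t1) consumes dissolved oxygen at rate mu1; regime II
    (t1..t2) at mu2 exists only for the un-sealed aerobic condition where
    surface oxygen transfer accelerates growth; regime III grows
    anaerobically at mu3 < mu1 until the carrying capacity.  OD noise is
    Gaussian.
    """
    if not mu3 < mu1:
        raise ValidationError("anaerobic rate mu3 must be below the initial rate mu1")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end + 1e-9, dt_min / 60.0)
    curves, rows = [], []
    for cond in conditions:
        has_mu2 = cond == "no_oil_aerobic"
        mu_t = np.where(times < t1, mu1,
                        np.where(times < t2, mu2 if has_mu2 else mu3, mu3))
        ln_od = np.log(od0) + np.concatenate(
            [[0.0], np.cumsum(0.5 * (mu_t[1:] + mu_t[:-1]) * np.diff(times))])
        od = np.minimum(np.exp(ln_od), carrying_capacity)
        noisy = od + rng.normal(0, noise_sd, od.size)
        curves.append(GrowthCurve(culture_id=cond, times=times,
                                  od600=np.clip(noisy, 1e-4, None),
                                  blank_corrected=True))
        rows.append({"culture_id": cond, "condition": cond, "mu1": mu1,
                     "mu2": mu2 if has_mu2 else np.nan, "mu3": mu3,
                     "t1": t1, "t2": t2})
    return GrowthSim(curves=curves, truth=pd.DataFrame(rows))


@dataclass
class StrainArchetype:
    """Mean 7-analyte phenotype of one strain plus its glucose response.

    The glucose response is log-linear: the mean of analyte ``a`` at
    ``glucose`` g/L is ``means[a] * exp(rate_a * (glucose - reference))``.
    A multiplicative response keeps every yield positive and strictly
    monotone in glucose by construction.
    """

    label: str
    means: dict[str, float]  # over ANALYTES, at reference_glucose
    noise_fraction: float = 0.05  # sd as a fraction of each condition mean
    glucose_rates: dict[str, float] = field(default_factory=dict)  # ln fold change per g/L
    reference_glucose: float = 10.0  # g/L

    def __post_init__(self) -> None:
        missing = set(ANALYTES) - set(self.means)
        if missing:
            raise ValidationError(f"archetype {self.label}: missing analytes {sorted(missing)}")
        if any(v < 0 for v in self.means.values()):
            raise ValidationError(f"archetype {self.label}: means must be >= 0")

    def mean_vector(self, glucose: float) -> np.ndarray:
        dg = glucose - self.reference_glucose
        return np.array([
            self.means[a] * np.exp(self.glucose_rates.get(a, 0.0) * dg)
            for a in ANALYTES])


# More initial glucose lengthens the fermentation and acidifies the medium,
# pushing flux toward lactate at the expense of formate, acetate, biomass and
# growth.  The wild type responds strongly; the lactate-overproducing
# deletion mutants are already lactate-dominated and barely move.
_WT_RATES = {"growth_rate": -0.012, "acetate": -0.05, "formate": -0.05,
             "lactate": 0.15, "biomass": -0.012}
_MUTANT_RATES = {"growth_rate": -0.006, "acetate": -0.01, "formate": -0.02,
                 "lactate": 0.01, "biomass": -0.006}

#: Synthetic archetypes (not measured values): wild type prefers mixed-acid
#: formate/acetate; the adhE/pta deletion mutants shunt to lactate with
#: acetate near zero; later-evolution D59 grows faster than D1/D28.
#: D1 and D28 share one distribution by construction.
_D1_MEANS = {"growth_rate": 0.16, "acetate": 0.02, "formate": 0.45,
             "lactate": 1.45, "pyruvate": 0.06, "succinate": 0.10,
             "biomass": 0.010}
DEFAULT_ARCHETYPES: tuple[StrainArchetype, ...] = (
    StrainArchetype("WT", {"growth_rate": 0.32, "acetate": 0.60, "formate": 1.05,
                           "lactate": 0.15, "pyruvate": 0.02, "succinate": 0.15,
                           "biomass": 0.014}, glucose_rates=_WT_RATES),
    StrainArchetype("D1", dict(_D1_MEANS), glucose_rates=_MUTANT_RATES),
    StrainArchetype("D28", dict(_D1_MEANS), glucose_rates=_MUTANT_RATES),
    StrainArchetype("D59", {"growth_rate": 0.27, "acetate": 0.03, "formate": 0.15,
                            "lactate": 1.80, "pyruvate": 0.12, "succinate": 0.05,
                            "biomass": 0.011}, glucose_rates=_MUTANT_RATES),
)

#: Merged labelling in which the distribution-identical D1/D28 pair is one group.
MERGED_LABELS = {"WT": "WT", "D1": "D1+D28", "D28": "D1+D28", "D59": "D59"}


def gen_strain_dataset(archetypes: tuple[StrainArchetype, ...] = DEFAULT_ARCHETYPES,
                       glucose_levels=(2.5, 5.0, 10.0, 20.0), replicates: int = 2,
                       seed: int = 0) -> pd.DataFrame:
    """Strain-phenotype records across initial glucose levels, with truth labels.

    Each record = archetype mean shifted by its glucose response plus
    independent Gaussian noise (sd = noise_fraction of each mean).  One
    noiseless-mean "bioreactor" record per archetype at its reference
    glucose is appended, mirroring the single reference fermentation each
    strain gets at scale.  Columns: strain, merged_label, scale,
    initial_glucose, replicate, and the 7 analytes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for arch in archetypes:
        for g in glucose_levels:
            mean = arch.mean_vector(g)
            sd = mean * arch.noise_fraction
            for rep in range(replicates):
                vec = np.clip(mean + rng.normal(0, 1, len(ANALYTES)) * sd, 0, None)
                rows.append({"strain": arch.label, "merged_label": MERGED_LABELS.get(arch.label, arch.label),
                             "scale": "microplate", "initial_glucose": float(g),
                             "replicate": rep + 1,
                             **dict(zip(ANALYTES, vec))})
        bio = arch.mean_vector(arch.reference_glucose)
        rows.append({"strain": arch.label, "merged_label": MERGED_LABELS.get(arch.label, arch.label),
                     "scale": "bioreactor", "initial_glucose": arch.reference_glucose,
                     "replicate": 1, **dict(zip(ANALYTES, bio))})
    return pd.DataFrame(rows)
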