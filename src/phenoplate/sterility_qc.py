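"""Decontamination QC: growth/no-growth classification and effectiveness statistics.

A decontamination run is scored by re-pipetting sterile medium with the
washed tips and incubating: any surviving cells show up as growth.
Effectiveness is the percentage of wells that stayed sterile, with an exact
(Clopper--Pearson) binomial confidence interval, and factorial wash
experiments (disinfectant x concentration x washes x hold time x air-gap)
are summarised per condition with marginal means per factor level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError


@dataclass
class ContaminationOutcome:
    """Growth outcomes of the wells of one decontamination condition.

    ``outcomes[i]`` is True when well i grew (i.e. was contaminated).
    ``condition`` maps factor names (disinfectant, concentration, n_washes,
    hold_time, air_gap, ...) to their levels.
    """

    condition: dict[str, object]
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=bool)
        if self.outcomes.size < 1:
            raise ValidationError("a contamination outcome needs at least one well")

    @property
    def n_wells(self) -> int:
        return int(self.outcomes.size)

    @property
    def n_grew(self) -> int:
        return int(self.outcomes.sum())


def classify_growth(endpoint_od: dict[str, float] | np.ndarray, blank_od: float,
                    threshold_delta: float = 0.1):
    """Grew iff OD600 exceeds blank + threshold (strict >, default delta 0.1).

    Saturated LB cultures sit far above blank + 0.1 while reader noise stays
    well below it, so the default separates cleanly; it remains configurable.
    """
    if threshold_delta <= 0:
        raise ValidationError("threshold_delta must be > 0")
    cutoff = blank_od + threshold_delta
    if isinstance(endpoint_od, dict):
        return {w: bool(od > cutoff) for w, od in endpoint_od.items()}
    return np.asarray(endpoint_od, dtype=float) > cutoff


@dataclass
class EffectivenessResult:
    effectiveness: float  # % of wells that stayed sterile
    ci_low: float  # exact binomial 95% CI on the sterile proportion, in %
    ci_high: float
    n_wells: int
    n_grew: int


def effectiveness(outcome: ContaminationOutcome, alpha: float = 0.05) -> EffectivenessResult:
    """Sterilization effectiveness = 100 * (1 - contaminated fraction).

    A condition where every well grew (e.g. a water wash) scores 0%; one
    where no well grew scores 100%.  The Clopper--Pearson interval on the
    sterile proportion quantifies the small per-condition well counts.
    """
    n, grew = outcome.n_wells, outcome.n_grew
    sterile = n - grew
    lo, hi = proportion_confint(sterile, n, alpha=alpha, method="beta")
    return EffectivenessResult(
        effectiveness=100.0 * sterile / n,
        ci_low=100.0 * float(lo), ci_high=100.0 * float(hi),
        n_wells=n, n_grew=grew)


def factorial_summary(outcomes: list[ContaminationOutcome],
                      alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effectiveness per factor combination plus marginal means per factor level.

    Returns ``(table, marginals)``: one row per condition with effectiveness,
    CI and n; and one row per (factor, level) with the unweighted mean
    effectiveness over the conditions at that level.
    """
    if not outcomes:
        raise ValidationError("no outcomes to summarise")
    schema = tuple(sorted(outcomes[0].condition))
    rows = []
    for o in outcomes:
        if tuple(sorted(o.condition)) != schema:
            raise ValidationError(
                f"inconsistent factor schema: {sorted(o.condition)} vs {list(schema)}")
        res = effectiveness(o, alpha=alpha)
        rows.append({**o.condition,
                     "effectiveness": res.effectiveness,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "n_wells": res.n_wells, "n_grew": res.n_grew})
    table = pd.DataFrame(rows)
    marg_rows = []
    for factor in schema:
        for level, g in table.groupby(factor, sort=True):
            marg_rows.append({"factor": factor, "level": level,
                              "mean_effectiveness": float(g["effectiveness"].mean()),
                              "n_conditions": int(len(g))})
    return table, pd.DataFrame(marg_rows)
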