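"""Seeded generators for SI curves, von Frey sessions and group cohorts.

These generators supply ground-truth-annotated inputs for the MRI,
behaviour and statistics layers so the whole pipeline runs without animal
data.  Every generator is a pure function of its config: the same config
(including seed) reproduces bit-identical output.

The contrast-agent curve is the simplest shape with identifiable
(S0, Sp, tp): flat baseline at time 0, linear rise to the peak, exponential
decay after it.  Von Frey responses follow a logistic psychometric function
in log10 force, the standard model in the up-down literature.  Cohort
draws default to the study's printed four-group means and SDs (MRI summary
table and polarization results); group peak times are back-calculated from
the printed SIMR values since no peak-time row is printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mri import SIMetrics, SITimeSeries
from .vonfrey import (
    DEFAULT_FILAMENTS_G,
    VonFreyTrialSequence,
    run_updown_protocol,
)

__all__ = [
    "SICurveConfig",
    "SICurveTruth",
    "BehaviorConfig",
    "CohortConfig",
    "DEFAULT_SCAN_TIMES_MIN",
    "DEFAULT_GROUP_PARAMS",
    "generate_si_curve",
    "generate_vonfrey_session",
    "generate_cohort",
    "cohort_to_si_metrics",
]

DEFAULT_SCAN_TIMES_MIN: tuple[float, ...] = (0, 5, 15, 30, 60, 120, 180, 360)

# Four-group defaults: (mean, SD) per measure.  MRI rows from the study's
# SI summary table; polarization from the AQP4 results; peak times
# back-calculated from the printed group SIMR (SD taken as 10% of the
# mean); PWT levels are plausible week-16 values consistent with the
# reported behaviour (healthy animals near 20 g, untreated neuropathy
# below 10 g), declared rather than printed.
DEFAULT_GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "C":   {"initial_si": (4172.0, 344.67), "si_5min": (4659.0, 223.65),
            "peak_si": (6025.0, 339.94), "peak_time_h": (1.00, 0.10),
            "polarization": (72.41, 7.92), "pwt": (20.0, 3.0)},
    "PDN": {"initial_si": (6738.0, 675.07), "si_5min": (8414.0, 1789.05),
            "peak_si": (12347.0, 1541.10), "peak_time_h": (6.00, 0.60),
            "polarization": (38.97, 9.00), "pwt": (6.0, 2.0)},
    "OMT": {"initial_si": (4355.54, 396.68), "si_5min": (4912.0, 225.305),
            "peak_si": (7685.0, 1138.17), "peak_time_h": (1.15, 0.115),
            "polarization": (64.74, 8.33), "pwt": (15.0, 3.0)},
    "PMA": {"initial_si": (5395.0, 500.18), "si_5min": (6727.0, 265.42),
            "peak_si": (9779.0, 1374.68), "peak_time_h": (1.48, 0.148),
            "polarization": (48.10, 6.59), "pwt": (12.0, 3.0)},
}

KNOWN_MEASURES = ("initial_si", "si_5min", "peak_si", "peak_time_h",
                  "polarization", "pwt")


# ---------------------------------------------------------------------------
# SI curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SICurveConfig:
    """Shape parameters of one synthetic contrast-enhancement curve."""

    baseline_si: float = 4172.0
    peak_si: float = 6025.0
    peak_time_h: float = 1.0
    decay_halflife_h: float = 2.0
    scan_times_min: tuple[float, ...] = DEFAULT_SCAN_TIMES_MIN
    noise_sd: float = 0.0
    seed: int = 0
    animal_id: str = "sim"
    group: str = "C"

    def validate(self) -> None:
        if self.peak_si < self.baseline_si:
            raise ValueError("peak_si must be >= baseline_si")
        if self.baseline_si < 0 or self.noise_sd < 0 or self.decay_halflife_h <= 0:
            raise ValueError("invalid baseline, noise_sd or halflife")
        t = np.asarray(self.scan_times_min, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("scan times must be strictly increasing")
        if not (0 < self.peak_time_h * 60.0 <= t[-1]):
            raise ValueError("peak time must lie inside the scan window")


@dataclass(frozen=True)
class SICurveTruth:
    baseline_si: float
    peak_si: float
    peak_time_h: float


def generate_si_curve(config: SICurveConfig) -> tuple[SITimeSeries, SICurveTruth]:
    """Sample the noise-free curve at the scan times and add Gaussian noise.

    The noise-free curve passes through (0, S0) and (tp, Sp) exactly:
    baseline at 0, linear rise to the peak, exponential decay after.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.scan_times_min, dtype=float)
    s0, sp = config.baseline_si, config.peak_si
    tp = config.peak_time_h * 60.0
    hl = config.decay_halflife_h * 60.0
    si = np.where(
        t <= tp,
        s0 + (sp - s0) * t / tp,
        s0 + (sp - s0) * np.exp2(-(t - tp) / hl),
    )
    if config.noise_sd > 0:
        si = np.clip(si + rng.normal(0.0, config.noise_sd, si.shape), 0, None)
    series = SITimeSeries(animal_id=config.animal_id, group=config.group,
                          time_min=t, si=si)
    return series, SICurveTruth(s0, sp, config.peak_time_h)


# ---------------------------------------------------------------------------
# von Frey sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorConfig:
    """Psychometric ground truth of one simulated animal.

    Response probability at force F is logistic in log10 force:
    p = 1 / (1 + exp(-(log10 F - log10 theta)/slope)); slope 0 gives a
    deterministic step responder (withdraw iff F > theta).
    """

    true_threshold_g: float = 8.0
    psychometric_slope: float = 0.1
    filament_forces_g: tuple[float, ...] = DEFAULT_FILAMENTS_G
    cutoff_g: float = 26.0
    seed: int = 0
    start_index: int | None = None

    def validate(self) -> None:
        if not self.filament_forces_g:
            raise ValueError("filament set is empty")
        if self.true_threshold_g <= 0:
            raise ValueError("true_threshold_g must be positive")
        if self.psychometric_slope < 0:
            raise ValueError("psychometric_slope must be >= 0")
        if abs(self.cutoff_g - max(self.filament_forces_g)) > 1e-9:
            raise ValueError("cutoff_g must equal the strongest filament")


def generate_vonfrey_session(
    config: BehaviorConfig,
) -> tuple[VonFreyTrialSequence, float]:
    """Simulate one up-down session; returns the sequence and true theta."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    log_theta = np.log10(config.true_threshold_g)

    def responder(force: float) -> bool:
        if config.psychometric_slope == 0:
            return force > config.true_threshold_g
        z = (np.log10(force) - log_theta) / config.psychometric_slope
        p = 1.0 / (1.0 + np.exp(-z))
        return bool(rng.random() < p)

    seq = run_updown_protocol(
        responder, config.filament_forces_g, start_index=config.start_index
    )
    return seq, config.true_threshold_g


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Four-group cohort draw: per-group (mean, SD) per measure."""

    groups: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_GROUP_PARAMS
    )
    n_animals: int = 10
    measures: tuple[str, ...] = KNOWN_MEASURES
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        unknown = [m for m in self.measures if m not in KNOWN_MEASURES]
        if unknown:
            raise ValueError(f"unknown measures {unknown}; known: {KNOWN_MEASURES}")
        for grp, params in self.groups.items():
            for m in self.measures:
                if m not in params:
                    raise ValueError(f"group {grp!r} lacks parameters for {m!r}")
                if params[m][1] < 0:
                    raise ValueError(f"negative SD for {grp}/{m}")


def generate_cohort(config: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """Draw per-animal endpoint values from group normal distributions.

    Returns a long-format table (animal_id, group, measure, value);
    physically non-negative measures are truncated at zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for grp, params in config.groups.items():
        for i in range(config.n_animals):
            aid = f"{grp}{i + 1:02d}"
            for m in config.measures:
                mean, sd = params[m]
                val = float(rng.normal(mean, sd))
                if m != "polarization":       # polarization may be negative
                    val = max(val, 0.0)
                rows.append({"animal_id": aid, "group": grp,
                             "measure": m, "value": val})
    return pd.DataFrame(rows)


def cohort_to_si_metrics(cohort: pd.DataFrame) -> list[SIMetrics]:
    """Reshape a cohort table's MRI measures into per-animal SIMetrics."""
    wide = cohort.pivot_table(index=["animal_id", "group"], columns="measure",
                              values="value").reset_index()
    needed = {"initial_si", "si_5min", "peak_si", "peak_time_h"}
    if not needed <= set(wide.columns):
        raise ValueError(f"cohort lacks MRI measures {sorted(needed)}")
    return [
        SIMetrics(
            animal_id=r.animal_id, group=r.group,
            initial_si=r.initial_si, si_5min=r.si_5min, peak_si=r.peak_si,
            peak_time_h=r.peak_time_h, si_change=r.peak_si - r.initial_si,
        )
        for r in wide.itertuples()
    ]
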