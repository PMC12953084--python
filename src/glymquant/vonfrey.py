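"""Up-down von Frey estimation of the 50% paw-withdrawal threshold (PWT).

Filaments of graded bending force are applied in an adaptive staircase:
after a withdrawal the next weaker filament is presented, after no response
the next stronger one, and testing continues until four stimuli after the
first response reversal.  The 50% threshold follows the standard up-down
formula

    PWT50 (g) = 10^(X_f + k * delta) / 10^4

with X_f the log10 of the final filament force (in log10(force x 10^4)
units, the conventional filament-label scale), delta the mean log10
inter-filament spacing, and k a pattern coefficient looked up from a
shipped table keyed by the six-response window that starts one trial before
the first reversal.  Sessions that run off either end of the filament range
without reversing are censored: the cutoff (26 g) for persistent
non-responders, the weakest filament for persistent responders.

The packaged k-table (data/updown_k_table.csv) tabulates, for each of the
32 possible six-response windows, the maximum-likelihood offset of a
normal-tolerance staircase with spread equal to one filament step — the
derivation underlying the published up-down tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_FILAMENTS_G",
    "VonFreyTrialSequence",
    "ThresholdEstimate",
    "run_updown_protocol",
    "estimate_50pwt",
    "load_k_table",
]

# Touch-Test rat filament series (target forces in grams), truncated at the
# study's 26 g safety cutoff.
DEFAULT_FILAMENTS_G: tuple[float, ...] = (
    0.4, 0.6, 1.0, 1.4, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 26.0,
)


@dataclass
class VonFreyTrialSequence:
    """Ordered (force, response) pairs from one up-down session.

    ``response`` is True for withdrawal/licking (positive), False for no
    response.  ``censored`` marks sessions that ran off the filament range
    before a reversal ("low" or "high").
    """

    trials: list[tuple[float, bool]]
    filament_set: tuple[float, ...] = DEFAULT_FILAMENTS_G
    cutoff_g: float = 26.0
    censored: str | None = None
    animal_id: str | None = None
    session: int | None = None

    def __post_init__(self):
        if not self.filament_set:
            raise ValueError("filament set is empty")
        if any(f <= 0 for f in self.filament_set):
            raise ValueError("filament forces must be positive")
        fs = set(np.round(self.filament_set, 6))
        for force, _ in self.trials:
            if round(force, 6) not in fs:
                raise ValueError(f"trial force {force} g not in filament set")

    @property
    def pattern(self) -> str:
        """Response string, X = withdrawal, O = no response."""
        return "".join("X" if r else "O" for _, r in self.trials)


@dataclass(frozen=True)
class ThresholdEstimate:
    """50% PWT in grams with the quantities entering the up-down formula."""

    pwt50_g: float
    censored: bool
    x_f: float | None = None       # log10(final force x 10^4)
    k: float | None = None         # pattern coefficient
    delta: float | None = None     # mean log10 inter-filament spacing
    pattern: str | None = None


def run_updown_protocol(
    responder: Callable[[float], bool],
    filament_set: Sequence[float] = DEFAULT_FILAMENTS_G,
    start_index: int | None = None,
    n_after_first_reversal: int = 4,
    max_trials: int = 50,
) -> VonFreyTrialSequence:
    """Run one adaptive up-down session against a responder callable.

    The stimulus steps one filament down after a positive response and one
    up after a negative one; the session ends ``n_after_first_reversal``
    trials after the first reversal.  Running off the weak end before any
    reversal censors low; a non-response at the strongest filament (the
    cutoff) before any reversal censors high.  After a reversal the index
    clamps at the range ends.
    """
    filaments = tuple(sorted(filament_set))
    if not filaments:
        raise ValueError("filament set is empty")
    i = len(filaments) // 2 if start_index is None else start_index
    if not 0 <= i < len(filaments):
        raise ValueError(f"start_index {i} outside filament set")

    trials: list[tuple[float, bool]] = []
    censored = None
    target_len: int | None = None
    while len(trials) < max_trials:
        force = filaments[i]
        resp = bool(responder(force))
        trials.append((force, resp))
        if target_len is None and len(trials) >= 2 and resp != trials[-2][1]:
            target_len = len(trials) + n_after_first_reversal
        if target_len is not None and len(trials) >= target_len:
            break
        step = -1 if resp else 1
        j = i + step
        if j < 0:
            if target_len is None:
                censored = "low"
                break
            j = 0
        elif j >= len(filaments):
            if target_len is None:
                censored = "high"
                break
            j = len(filaments) - 1
        i = j
    return VonFreyTrialSequence(
        trials=trials,
        filament_set=filaments,
        cutoff_g=filaments[-1],
        censored=censored,
    )


def load_k_table() -> dict[str, float]:
    """Load the packaged pattern-coefficient table."""
    text = resources.files("glymquant.data").joinpath("updown_k_table.csv").read_text()
    table = {}
    for row in csv.DictReader(text.splitlines()):
        table[row["pattern"]] = float(row["k"])
    return table


_K_TABLE: dict[str, float] | None = None


def _k_table() -> dict[str, float]:
    global _K_TABLE
    if _K_TABLE is None:
        _K_TABLE = load_k_table()
    return _K_TABLE


def estimate_50pwt(
    seq: VonFreyTrialSequence, k_table: dict[str, float] | None = None
) -> ThresholdEstimate:
    """Estimate the 50% PWT from one up-down session.

    Censored sessions return the boundary value (cutoff or weakest
    filament).  Otherwise the six-response window starting one trial before
    the first reversal indexes the k-table, and the estimate is
    10^(X_f + k*delta)/10^4, clipped to the assignable range.
    """
    filaments = tuple(sorted(seq.filament_set))
    if seq.censored == "high":
        return ThresholdEstimate(pwt50_g=seq.cutoff_g, censored=True,
                                 pattern=seq.pattern)
    if seq.censored == "low":
        return ThresholdEstimate(pwt50_g=filaments[0], censored=True,
                                 pattern=seq.pattern)
    responses = [r for _, r in seq.trials]
    change = next(
        (c for c in range(1, len(responses)) if responses[c] != responses[c - 1]),
        None,
    )
    if change is None:
        raise ValueError(
            f"sequence has no reversal and no censoring flag: {seq.pattern}"
        )
    window = seq.trials[change - 1 : change + 5]
    if len(window) < 6:
        raise ValueError(
            f"sequence too short after first reversal: {seq.pattern}"
        )
    pattern = "".join("X" if r else "O" for _, r in window)
    table = k_table if k_table is not None else _k_table()
    if pattern not in table:
        raise KeyError(f"response pattern {pattern!r} not in the k-table")
    k = table[pattern]
    log_forces = np.log10(np.asarray(filaments))
    delta = float(np.mean(np.diff(log_forces)))
    x_f = float(np.log10(window[-1][0] * 1e4))
    pwt = 10.0 ** (x_f + k * delta) / 1e4
    pwt = float(np.clip(pwt, filaments[0], seq.cutoff_g))
    return ThresholdEstimate(pwt50_g=pwt, censored=False, x_f=x_f, k=k,
                             delta=delta, pattern=pattern)
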