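"""Regenerate the packaged up-down pattern-coefficient table.

For each six-response window (one response before the first reversal, the
reversal, four after) the staircase levels are fixed by the stepping rule,
so the coefficient k depends only on the response pattern.  k is the
maximum-likelihood location, in filament-step units relative to the final
level, of a normal tolerance distribution with spread one step:
P(withdraw at level x) = Phi(x - mu).  This is the derivation underlying
the published up-down tables.

Usage: python scripts/make_k_table.py
Writes src/glymquant/data/updown_k_table.csv.
"""

from __future__ import annotations

import csv
import itertools
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm


def levels_for(pattern: str) -> list[int]:
    lv = [0]
    for ch in pattern[:-1]:
        lv.append(lv[-1] + (-1 if ch == "X" else 1))
    return lv


def k_for(pattern: str) -> float:
    lv = np.array(levels_for(pattern), dtype=float)
    resp = np.array([ch == "X" for ch in pattern])

    def nll(mu: float) -> float:
        p = norm.cdf(lv - mu)
        p = np.clip(np.where(resp, p, 1.0 - p), 1e-12, 1.0)
        return -np.log(p).sum()

    res = minimize_scalar(nll, bounds=(lv.min() - 6, lv.max() + 6),
                          method="bounded", options={"xatol": 1e-10})
    return float(res.x - lv[-1])


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "src/glymquant/data/updown_k_table.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for first in "OX":
        second = "X" if first == "O" else "O"
        for tail in itertools.product("OX", repeat=4):
            pattern = first + second + "".join(tail)
            rows.append({"pattern": pattern, "k": f"{k_for(pattern):.4f}"})
    with out.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["pattern", "k"])
        writer.writeheader()
        writer.writerows(rows)
    print(f"wrote {len(rows)} patterns to {out}")


if __name__ == "__main__":
    main()
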