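"""The two-observer, three-AOI worked example and its printed-value checks.

Two observers view the same painting under one task; their dwell times over
the AOIs (Visitor, Persons, Background) are proportional to within a few
percent, yet differ four-fold in magnitude. The fixture reproduces every
headline number of that example — percentage closures, Aitchison versus
Euclidean distances, the modified-distribution ratio shifts, and the two
ways of realising a halved Background share (fixed-total redistribution
versus unconstrained reduction) — and compares each against the reference
value at its printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coda import aitchison_distance, close

__all__ = ["AOIS", "P101", "P74", "example_table", "worked_example_check"]

AOIS = ["Visitor", "Persons", "Background"]
P74 = np.array([8323.0, 5353.0, 4319.0])    # ms per AOI, observer 1
P101 = np.array([2187.0, 1377.3, 1036.0])   # ms per AOI, observer 2

#: modified relative distribution discussed in the example: Background share
#: halved, Visitor:Persons ratio preserved (printed as percentages)
MODIFIED_PCT = np.array([53.6, 34.4, 12.0])


def example_table() -> pd.DataFrame:
    """The fixture as a long fixation table (single task)."""
    rows = []
    for pid, vec in (("P74", P74), ("P101", P101)):
        for aoi, v in zip(AOIS, vec):
            rows.append((pid, 1, aoi, v))
    return pd.DataFrame(rows, columns=["participant", "task", "aoi", "tdof_ms"])


@dataclass
class Check:
    name: str
    computed: float
    reference: float
    tol: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.reference) <= self.tol

    def __str__(self) -> str:
        mark = "ok " if self.passed else "FAIL"
        return (f"[{mark}] {self.name}: computed {self.computed:.6g}, "
                f"reference {self.reference:g} (tol {self.tol:g})")


def _modified_distribution(x: np.ndarray) -> np.ndarray:
    """Halve the third part's share, rescaling the first two proportionally."""
    s = close(x, 1.0)
    third = s[2] / 2.0
    f = (1.0 - third) / (s[0] + s[1])
    return np.array([s[0] * f, s[1] * f, third])


def worked_example_check(p74: np.ndarray = P74, p101: np.ndarray = P101) -> list[Check]:
    """Recompute every printed quantity of the worked example.

    Returns one :class:`Check` per quantity; all pass on the canonical
    fixture, and perturbing a single millisecond value breaks exactly the
    checks that depend on it. Deterministic and seed-free.
    """
    checks: list[Check] = []

    def add(name, computed, reference, decimals):
        # half a unit in the last printed digit, padded for float roundoff
        checks.append(Check(name, float(computed), reference,
                            0.5 * 10.0 ** (-decimals) + 1e-9))

    pct74 = close(p74, 100.0)
    pct101 = close(p101, 100.0)
    for label, vec, ref in (
        ("P74 closure", pct74, (46.3, 29.7, 24.0)),
        ("P101 closure", pct101, (47.5, 29.9, 22.5)),
    ):
        for aoi, c, r in zip(AOIS, vec, ref):
            add(f"{label} {aoi} (%)", c, r, 1)

    add("Aitchison distance", aitchison_distance(p74, p101), 0.068, 3)
    add("Euclidean distance, raw ms", np.linalg.norm(p74 - p101), 8014.66, 2)
    add("Euclidean distance, percentages", np.linalg.norm(pct74 - pct101), 1.97, 2)

    mod = _modified_distribution(p74)
    for aoi, c, r in zip(AOIS, mod * 100.0, MODIFIED_PCT):
        add(f"modified share {aoi} (%)", c, r, 1)

    # ratio shifts, computed from the printed percentage representation
    add("modified Visitor/Background", MODIFIED_PCT[0] / MODIFIED_PCT[2], 4.47, 2)
    add("modified Persons/Background", MODIFIED_PCT[1] / MODIFIED_PCT[2], 2.87, 2)
    add("modified Visitor/Persons", MODIFIED_PCT[0] / MODIFIED_PCT[1], 1.56, 2)

    total = p74.sum()
    redistributed = mod * total
    for aoi, c, r in zip(AOIS, redistributed, (9637.0, 6198.0, 2159.0)):
        add(f"fixed-total redistribution {aoi} (ms)", c, r, 0)

    # unconstrained variant: Background share halved with the other two fixed
    target_share = close(p74, 1.0)[2] / 2.0
    bg = target_share * (p74[0] + p74[1]) / (1.0 - target_share)
    add("unconstrained Background (ms)", bg, 1865.0, 0)

    return checks
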