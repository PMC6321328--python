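"""Dual-activity-difference (DAD) maps for two-target selectivity analysis.

A DAD map plots, for every unordered compound pair, the activity difference
on target X against the activity difference on target Y.  With a threshold
``t_act`` (default 1 log unit) on both axes each pair is labeled:

* ``DUAL`` — the structural change shifts potency strongly on both targets;
* ``SELECTIVE_X`` / ``SELECTIVE_Y`` — it shifts potency on one target only,
  the signature of a selectivity switch;
* ``SILENT`` — it leaves both activities essentially unchanged.

Default axes carry absolute differences; signed differences (A_i − A_j with
the fixed i-before-j table orientation) are kept alongside, enabling the
quadrant reading in which a sign flip between axes marks an inversion of
target preference.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import itertools

import pandas as pd

from .io import ActivityTable
from .landscape import DEFAULT_T_ACT

__all__ = [
    "DADLabel",
    "DADPoint",
    "DADMap",
    "classify_dad_point",
    "build_dad_map",
    "compound_selectivity_profile",
]


class DADLabel(str, Enum):
    DUAL = "DUAL"
    SELECTIVE_X = "SELECTIVE_X"
    SELECTIVE_Y = "SELECTIVE_Y"
    SILENT = "SILENT"


def classify_dad_point(dx: float, dy: float, t_act: float = DEFAULT_T_ACT) -> DADLabel:
    """Label one pair from its absolute activity differences on two targets."""
    if dx < 0 or dy < 0:
        raise ValueError(f"absolute differences must be >= 0, got ({dx}, {dy})")
    large_x = dx > t_act
    large_y = dy > t_act
    if large_x and large_y:
        return DADLabel.DUAL
    if large_x:
        return DADLabel.SELECTIVE_X
    if large_y:
        return DADLabel.SELECTIVE_Y
    return DADLabel.SILENT


@dataclass
class DADPoint:
    """One pair on the DAD map (i precedes j in table order)."""

    i: str
    j: str
    dx: float
    dy: float
    signed_dx: float
    signed_dy: float
    label: DADLabel


@dataclass
class DADMap:
    points: list[DADPoint]
    target_x: str
    target_y: str
    t_act: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "i": p.i,
                    "j": p.j,
                    "dx": p.dx,
                    "dy": p.dy,
                    "signed_dx": p.signed_dx,
                    "signed_dy": p.signed_dy,
                    "label": p.label.value,
                }
                for p in self.points
            ]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def label_counts(self) -> dict[DADLabel, int]:
        counts = {label: 0 for label in DADLabel}
        for p in self.points:
            counts[p.label] += 1
        return counts


def build_dad_map(
    table: ActivityTable,
    target_x: str,
    target_y: str,
    t_act: float = DEFAULT_T_ACT,
) -> DADMap:
    """Build the DAD map over all n(n-1)/2 pairs of one activity table."""
    if target_x == target_y:
        raise ValueError("DAD map requires two distinct targets")
    for t in (target_x, target_y):
        if t not in table.targets:
            raise KeyError(f"unknown target {t!r}")
    ax = [rec.activities[target_x] for rec in table.compounds]
    ay = [rec.activities[target_y] for rec in table.compounds]
    points = []
    for ii, jj in itertools.combinations(range(len(table)), 2):
        sdx = ax[ii] - ax[jj]
        sdy = ay[ii] - ay[jj]
        points.append(
            DADPoint(
                i=table.ids[ii],
                j=table.ids[jj],
                dx=abs(sdx),
                dy=abs(sdy),
                signed_dx=sdx,
                signed_dy=sdy,
                label=classify_dad_point(abs(sdx), abs(sdy), t_act),
            )
        )
    return DADMap(points=points, target_x=target_x, target_y=target_y, t_act=t_act)


def compound_selectivity_profile(
    dad: DADMap, compound_id: str
) -> dict[str, dict[str, float]]:
    """Per-label counts and fractions for the pairs containing one compound.

    A compound whose pairs are dominated by ``SELECTIVE_X`` labels is a
    candidate selectivity switch toward target X; a ``DUAL``-dominated
    profile marks a compound whose structural neighborhood shifts both
    activities at once.
    """
    mine = [p for p in dad.points if compound_id in (p.i, p.j)]
    if not mine:
        raise KeyError(f"compound {compound_id!r} appears in no pair")
    counts = {label.value: 0 for label in DADLabel}
    for p in mine:
        counts[p.label.value] += 1
    total = len(mine)
    return {
        "counts": counts,
        "fractions": {k: v / total for k, v in counts.items()},
    }
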