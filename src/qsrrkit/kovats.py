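"""Retention indices from retention times and an n-alkane ladder.

A retention index places a peak on a column-specific but instrument-
independent scale anchored by the n-alkanes (alkane Cn ≡ 100·n).  Two
classical variants are provided:

* temperature-programmed (van den Dool–Kratz): linear interpolation of the
  raw retention time between the bracketing alkanes;
* isothermal (Kovats): logarithmic interpolation of dead-time-corrected
  (adjusted) retention times.

No extrapolation beyond the ladder is performed — a time outside the ladder
range is an error, mirroring the applicability-domain philosophy used for
the structure-based predictions.
"""

from __future__ import annotations

import csv
import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["AlkaneLadder", "ri_programmed", "ri_isothermal"]


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane calibration ladder: (carbon number, retention time/min)."""

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("ladder needs at least 2 alkanes")
        carbons = [c for c, _ in self.entries]
        times = [t for _, t in self.entries]
        if sorted(set(carbons)) != carbons:
            raise ValueError("carbon numbers must be distinct and increasing")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("retention times must be strictly increasing")

    @property
    def carbons(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.entries)

    def bracket(self, t_r: float) -> tuple[tuple[int, float], tuple[int, float]]:
        """The ladder pair whose times enclose ``t_r``."""
        times = self.times
        if not times[0] <= t_r <= times[-1]:
            raise ValueError(
                f"retention time {t_r} outside ladder range "
                f"[{times[0]}, {times[-1]}]; extrapolation is not supported"
            )
        k = min(bisect_right(times, t_r), len(times) - 1)
        return self.entries[k - 1], self.entries[k]

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlkaneLadder":
        """Read ``carbon_n,t_r`` CSV (header required)."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            entries = tuple(
                (int(row["carbon_n"]), float(row["t_r"])) for row in reader
            )
        return cls(entries)


def ri_programmed(t_r: float, ladder: AlkaneLadder) -> float:
    """Temperature-programmed (van den Dool–Kratz) retention index.

    ``RI = 100·[n + (t_r − t_n)/(t_{n+1} − t_n)]`` with the bracketing
    alkane pair (Cn, Cn+1); carbon numbers in the bracket need not be
    consecutive — the interpolation spans the gap.
    """
    (c_lo, t_lo), (c_hi, t_hi) = ladder.bracket(t_r)
    frac = (t_r - t_lo) / (t_hi - t_lo)
    return 100.0 * (c_lo + frac * (c_hi - c_lo))


def ri_isothermal(t_r_adjusted: float, ladder: AlkaneLadder) -> float:
    """Isothermal (Kovats) retention index from adjusted retention times.

    ``RI = 100·[n + (log t′ − log t′_n)/(log t′_{n+1} − log t′_n)]``; all
    times must be positive dead-time-corrected values.
    """
    if t_r_adjusted <= 0 or any(t <= 0 for t in ladder.times):
        raise ValueError("adjusted retention times must be positive")
    (c_lo, t_lo), (c_hi, t_hi) = ladder.bracket(t_r_adjusted)
    frac = (math.log(t_r_adjusted) - math.log(t_lo)) / (
        math.log(t_hi) - math.log(t_lo))
    return 100.0 * (c_lo + frac * (c_hi - c_lo))


def index_chromatogram(peaks: Iterable[tuple[str, float]],
                       ladder: AlkaneLadder,
                       isothermal: bool = False) -> list[tuple[str, float]]:
    """Index a list of ``(compound_id, t_r)`` peaks against a ladder."""
    fn = ri_isothermal if isothermal else ri_programmed
    return [(cid, fn(t, ladder)) for cid, t in peaks]
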