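"""Two-group metabolite change statistics for processing studies.

Given relative abundances of metabolites before and after a treatment
(here: extrusion of a composite flour), this module computes fold changes,
two-sample t-tests with Benjamini–Hochberg FDR correction, and the
significance/direction classification used in GC–MS metabolomics reports:
a metabolite changes significantly if its FDR-adjusted p-value is below
0.05 **or** its (externally supplied) OPLS-DA VIP score exceeds 1; the
direction follows the sign of the log2 fold change.

A bundled reference table (``load_extrusion_table``) carries the published
summary statistics of 72 flour metabolites before/after extrusion —
relative-abundance group means, BH-adjusted p-values, VIP scores (censored
entries kept verbatim, e.g. ``">0.05"``), and the assigned change labels —
and serves as a realistic worked example and regression fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceRecord",
    "fold_change",
    "group_test",
    "bh_fdr",
    "classify_change",
    "load_extrusion_table",
    "analyze_replicates",
]

INCREASE, DECREASE, NO_CHANGE = "Increase", "Decrease", "No change"


@dataclass
class AbundanceRecord:
    """One metabolite's replicate (or mean) abundances in two groups."""

    metabolite: str
    before: tuple[float, ...]
    after: tuple[float, ...]
    vip: float | None = None

    def __post_init__(self) -> None:
        if not self.before or not self.after:
            raise ValueError("each group needs at least one abundance")
        if min(self.before) <= 0 or min(self.after) <= 0:
            raise ValueError("abundances must be positive")


def fold_change(before_mean: float, after_mean: float
                ) -> tuple[float, float]:
    """(ratio, log2 fold change) of after vs before group means."""
    if before_mean <= 0 or after_mean <= 0:
        raise ValueError("group means must be positive")
    ratio = after_mean / before_mean
    return ratio, math.log2(ratio)


def group_test(before_reps: Sequence[float], after_reps: Sequence[float],
               pooled: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default).

    Returns ``(t, p)``.  ``pooled=True`` switches to the equal-variance
    (Student) statistic.
    """
    if len(before_reps) < 2 or len(after_reps) < 2:
        raise ValueError("need at least 2 replicates per group")
    t, p = stats.ttest_ind(before_reps, after_reps, equal_var=pooled)
    return float(t), float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_change(p_adj: float, vip: float | None, log2fc: float) -> str:
    """Label a metabolite change as Increase / Decrease / No change.

    Significant iff ``p_adj < 0.05`` or ``vip > 1``; a NaN/None entry (a
    censored value such as ">0.05" or "<1.00") fails its criterion.  The
    direction is the sign of the log2 fold change; a significant metabolite
    with exactly zero fold change is reported as No change.
    """
    if not math.isfinite(log2fc):
        raise ValueError("log2 fold change must be finite")
    p_ok = p_adj is not None and not math.isnan(p_adj) and p_adj < 0.05
    vip_ok = vip is not None and not math.isnan(vip) and vip > 1
    if not (p_ok or vip_ok) or log2fc == 0:
        return NO_CHANGE
    return INCREASE if log2fc > 0 else DECREASE


def _parse_censored(value: str) -> float:
    """Censored table entries (">0.05", "<1.00") parse to NaN."""
    value = str(value).strip()
    if value.startswith((">", "<")):
        return float("nan")
    return float(value)


def load_extrusion_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the bundled (or a user-supplied) metabolite summary table.

    Columns: metabolite, before_mean, after_mean, log2fc_printed, label,
    p_adj, vip — plus recomputed ``ratio`` and ``log2fc`` from the means.
    Censored p/VIP entries become NaN.
    """
    if path is None:
        source = resources.files("qsrrkit.data") / "extrusion_metabolites.csv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, dtype={"p_adj": str, "vip": str})
    else:
        df = pd.read_csv(path, dtype={"p_adj": str, "vip": str})
    df["p_adj"] = df["p_adj"].map(_parse_censored)
    df["vip"] = df["vip"].map(_parse_censored)
    fc = [fold_change(b, a) for b, a in zip(df["before_mean"],
                                            df["after_mean"])]
    df["ratio"] = [r for r, _ in fc]
    df["log2fc"] = [l for _, l in fc]
    return df


def analyze_replicates(records: Iterable[AbundanceRecord],
                       pooled: bool = False) -> pd.DataFrame:
    """Full pipeline on replicate data: t-tests, BH-FDR, classification."""
    records = list(records)
    rows = []
    for rec in records:
        ratio, lfc = fold_change(float(np.mean(rec.before)),
                                 float(np.mean(rec.after)))
        t, p = group_test(rec.before, rec.after, pooled=pooled)
        rows.append({"metabolite": rec.metabolite, "ratio": ratio,
                     "log2fc": lfc, "t": t, "p": p, "vip": rec.vip})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_fdr(df["p"].to_numpy())
    df["label"] = [
        classify_change(row.p_adj,
                        row.vip if row.vip is not None else float("nan"),
                        row.log2fc)
        for row in df.itertuples()
    ]
    return df
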