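"""Synthetic inputs for exercising every pipeline stage without downloads.

Four generators, each a pure function of its parameters and seed:

* ``gen_molecules`` — small C/N/O molecule libraries (linear/branched
  alkanes decorated as alcohols, acids, esters, amines; C2–C12) from a
  miniature combinatorial SMILES grammar, used as descriptor probe sets;
* ``gen_descriptor_dataset`` — descriptor/response tables with a known
  sparse linear signal hidden among correlated decoy columns and Gaussian
  noise, the harness for variable-selection and validation machinery;
* ``gen_chromatogram`` — n-alkane ladders plus analyte retention times
  constructed as the exact inverse of the temperature-programmed retention
  index, so indices round-trip;
* ``gen_abundance_table`` — two-group log-normal replicate abundance tables
  with specified log2 effects and coefficient of variation, emulating
  post-normalization GC–MS metabolomics data (QC CV below ~20 %).

These emulate the *shape* of real data (scales, noise structure,
correlation), not chromatographic physics or mass spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .kovats import AlkaneLadder
from .molecules import parse_smiles

__all__ = [
    "PlantedSignalSpec",
    "gen_molecules",
    "gen_descriptor_dataset",
    "gen_chromatogram",
    "gen_abundance_table",
]


# ---------------------------------------------------------------------------
# molecule libraries


_FUNCTIONAL_SUFFIX = {
    "alkane": "",
    "alcohol": "O",
    "acid": "C(=O)O",
    "ester": "C(=O)OC",
    "amine": "N",
}


def gen_molecules(n: int, seed: int = 0,
                  classes: Sequence[str] = ("alkane", "alcohol", "acid",
                                            "ester", "amine")) -> list[str]:
    """Generate ``n`` distinct, parseable SMILES (C2–C12 skeletons, C/N/O).

    Random branched carbon skeletons (random trees over 2–12 carbons) are
    decorated with one functional group.  Uniqueness is enforced on the
    canonical structure, so no two outputs encode the same molecule.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        n_c = int(rng.integers(2, 13))
        smiles = _random_skeleton(n_c, rng)
        cls = classes[int(rng.integers(len(classes)))]
        smiles = smiles + _FUNCTIONAL_SUFFIX[cls]
        mol = parse_smiles(smiles)
        if mol.canonical_key not in seen:
            seen.add(mol.canonical_key)
            out.append(smiles)
    return out


def _random_skeleton(n_c: int, rng: np.random.Generator) -> str:
    """SMILES of a random carbon tree with ``n_c`` atoms (max degree 4)."""
    # random recursive tree: attach each new carbon to a random earlier one
    children: dict[int, list[int]] = {0: []}
    degree = {0: 0}
    for node in range(1, n_c):
        candidates = [v for v in children if degree[v] < 3]
        parent = int(candidates[rng.integers(len(candidates))])
        children[parent].append(node)
        children[node] = []
        degree[parent] += 1
        degree[node] = 1

    def emit(v: int) -> str:
        parts = ["C"]
        kids = children[v]
        for k in kids[:-1]:
            parts.append("(" + emit(k) + ")")
        if kids:
            parts.append(emit(kids[-1]))
        return "".join(parts)

    return emit(0)


# ---------------------------------------------------------------------------
# planted-signal descriptor datasets


@dataclass
class PlantedSignalSpec:
    """Recipe for a descriptor table with a known sparse linear signal.

    ``coefficients`` are (intercept, b1..bk) on the response scale;
    ``true_means``/``true_sds`` set the scale of the signal columns
    (standard normal by default); decoys share correlation
    ``decoy_correlation`` with a random signal column.
    """

    n: int = 150
    coefficients: tuple[float, ...] = (0.0, 5.0, 4.0, 3.0)
    k_decoy: int = 47
    decoy_correlation: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0
    true_means: tuple[float, ...] | None = None
    true_sds: tuple[float, ...] | None = None

    @property
    def k_true(self) -> int:
        return len(self.coefficients) - 1

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("need an intercept plus >= 1 coefficient")
        if self.n <= self.k_true + 1:
            raise ValueError("n must exceed k_true + 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 <= self.decoy_correlation < 1:
            raise ValueError("decoy correlation must be in [0, 1)")


def gen_descriptor_dataset(spec: PlantedSignalSpec
                           ) -> tuple[DescriptorMatrix, np.ndarray]:
    """Build the planted-signal (matrix, response) pair.

    Signal columns are named ``true1..trueK``, decoys ``decoy1..decoyM``;
    the response is ``b0 + Σ b_j x_j + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k_true
    Z = rng.standard_normal((spec.n, k))
    means = np.array(spec.true_means if spec.true_means is not None
                     else [0.0] * k)
    sds = np.array(spec.true_sds if spec.true_sds is not None
                   else [1.0] * k)
    Xtrue = means + sds * Z
    rho = spec.decoy_correlation
    decoys = np.empty((spec.n, spec.k_decoy))
    for j in range(spec.k_decoy):
        anchor = Z[:, int(rng.integers(k))]
        decoys[:, j] = (rho * anchor
                        + np.sqrt(1 - rho**2) * rng.standard_normal(spec.n))
    b0, *bs = spec.coefficients
    y = b0 + Xtrue @ np.array(bs) + rng.normal(0, spec.noise_sd, spec.n)
    names = ([f"true{j + 1}" for j in range(k)]
             + [f"decoy{j + 1}" for j in range(spec.k_decoy)])
    df = pd.DataFrame(np.column_stack([Xtrue, decoys]),
                      index=[f"c{i + 1}" for i in range(spec.n)],
                      columns=names)
    return DescriptorMatrix(df), y


# ---------------------------------------------------------------------------
# chromatograms


def gen_chromatogram(carbon_lo: int, carbon_hi: int,
                     analyte_ris: Sequence[float], seed: int = 0,
                     t0: float = 2.0, minutes_per_carbon: float = 1.6,
                     jitter_sd: float = 0.0
                     ) -> tuple[AlkaneLadder, list[float]]:
    """Ladder + analyte times that invert the programmed retention index.

    The ladder follows a linear heating-rate model ``t(Cn) = t0 +
    minutes_per_carbon·n`` with optional seeded strictly-monotone jitter;
    each requested RI is converted to the unique retention time whose
    programmed index equals it.
    """
    if carbon_hi <= carbon_lo:
        raise ValueError("carbon_hi must exceed carbon_lo")
    rng = np.random.default_rng(seed)
    carbons = list(range(carbon_lo, carbon_hi + 1))
    first = t0 + minutes_per_carbon * carbon_lo
    gaps = np.full(len(carbons) - 1, minutes_per_carbon)
    if jitter_sd > 0:
        # jitter inter-alkane gaps, keeping the ladder strictly increasing
        gaps = np.maximum(0.05, gaps + rng.normal(0, jitter_sd, len(gaps)))
    times = list(first + np.concatenate([[0.0], np.cumsum(gaps)]))
    ladder = AlkaneLadder(tuple(zip(carbons, times)))
    lo, hi = 100.0 * carbon_lo, 100.0 * carbon_hi
    analyte_times = []
    for ri in analyte_ris:
        if not lo <= ri <= hi:
            raise ValueError(f"requested RI {ri} outside ladder range "
                             f"[{lo}, {hi}]")
        pos = ri / 100.0
        k = min(int(pos) - carbon_lo, len(carbons) - 2)
        frac = pos - carbons[k]
        analyte_times.append(times[k] + frac * (times[k + 1] - times[k]))
    return ladder, analyte_times


# ---------------------------------------------------------------------------
# two-group abundance tables


def gen_abundance_table(n_metabolites: int, n_reps: int,
                        log2_effects: Sequence[float] | float = 0.0,
                        cv: float = 0.15, seed: int = 0,
                        baseline_range: tuple[float, float] = (0.01, 10.0)
                        ) -> pd.DataFrame:
    """Log-normal two-group replicate table in long format.

    Columns ``metabolite, group, replicate, abundance`` with groups
    ``before``/``after``; metabolite j's after-group mean is its
    before-group mean times ``2**log2_effects[j]``.  Replicate noise is
    log-normal with the requested coefficient of variation, mimicking
    QC-filtered relative abundances (which are positive and
    CV-characterised).
    """
    if cv <= 0:
        raise ValueError("cv must be > 0")
    if n_reps < 3:
        raise ValueError("need at least 3 replicates per group")
    effects = (np.full(n_metabolites, float(log2_effects))
               if np.isscalar(log2_effects)
               else np.asarray(log2_effects, dtype=float))
    if len(effects) != n_metabolites:
        raise ValueError("one log2 effect per metabolite required")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    lo, hi = baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), n_metabolites))
    rows = []
    for j in range(n_metabolites):
        name = f"m{j + 1}"
        for group, mean in (("before", baselines[j]),
                            ("after", baselines[j] * 2.0 ** effects[j])):
            # log-normal with the requested arithmetic mean and CV
            mu = np.log(mean) - sigma**2 / 2
            for r in range(n_reps):
                rows.append({
                    "metabolite": name, "group": group, "replicate": r + 1,
                    "abundance": float(np.exp(rng.normal(mu, sigma))),
                })
    return pd.DataFrame(rows)
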