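"""Topological molecular descriptors and descriptor-matrix handling.

Three 2D descriptors carry the retention model:

* ``Eta_betaS`` — extended topochemical atom (ETA) sigma valence-electron-
  mobility count: a sum of contributions over the sigma framework of the
  hydrogen-depleted graph, sensitive to the number of electronegative atoms.
* ``MDEC-22`` — molecular distance edge between secondary carbons:
  ``n22 / d̄²`` where ``d̄`` is the geometric mean of the topological
  distances between all unordered pairs of secondary carbons.
* ``MATS1p`` — Moran autocorrelation of topological lag 1 weighted by
  carbon-scaled atomic polarizability.

All conventions (electronegativity gap, geometric-mean exponent, hydrogen
handling) are frozen in :mod:`qsrrkit.constants`.

The module also provides the matrix-level plumbing used before variable
selection: assembling descriptor matrices with explicit missing-value
markers, dropping constant and incomplete columns, and a correlation-
threshold redundancy reduction.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    CARBON_POLARIZABILITY,
    ELECTRONEGATIVITY,
    ETA_ELECTRONEGATIVITY_GAP,
    ETA_SIGMA_DISSIMILAR,
    ETA_SIGMA_SIMILAR,
    POLARIZABILITY,
)
from .molecules import Molecule

__all__ = [
    "DescriptorMatrix",
    "topological_distances",
    "eta_beta_s",
    "mdec22",
    "mats1p",
    "build_matrix",
    "filter_constant_missing",
    "correlation_reduce",
    "MODEL_DESCRIPTORS",
    "DESCRIPTOR_REGISTRY",
]


class UnknownElementError(KeyError):
    def __init__(self, element: str, table: str):
        self.element = element
        super().__init__(f"element {element!r} missing from the {table} table")


# ---------------------------------------------------------------------------
# graph substrate


def topological_distances(mol: Molecule) -> np.ndarray:
    """Bond-count shortest-path distance matrix of the H-depleted graph.

    Breadth-first search from each atom; raises ``ValueError`` for
    disconnected graphs.
    """
    n = mol.n_atoms
    adj = mol.neighbors()
    dist = np.full((n, n), -1, dtype=int)
    for start in range(n):
        dist[start, start] = 0
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if dist[start, v] < 0:
                    dist[start, v] = dist[start, u] + 1
                    queue.append(v)
    if (dist < 0).any():
        raise ValueError("molecule graph is disconnected")
    return dist


# ---------------------------------------------------------------------------
# the three model descriptors


def eta_beta_s(mol: Molecule) -> float:
    """ETA sigma VEM count over the hydrogen-depleted sigma framework.

    Every bond between heavy atoms contributes through its sigma component
    exactly once: 0.5 when the endpoints have similar Pauling
    electronegativity (|Δχ| ≤ 0.3), 0.75 otherwise.
    """
    total = 0.0
    for i, j, _order in mol.bonds:
        ei, ej = mol.atoms[i][0], mol.atoms[j][0]
        for e in (ei, ej):
            if e not in ELECTRONEGATIVITY:
                raise UnknownElementError(e, "electronegativity")
        gap = abs(ELECTRONEGATIVITY[ei] - ELECTRONEGATIVITY[ej])
        total += (ETA_SIGMA_SIMILAR if gap <= ETA_ELECTRONEGATIVITY_GAP
                  else ETA_SIGMA_DISSIMILAR)
    return total


def _secondary_carbons(mol: Molecule) -> list[int]:
    """Carbon atoms bonded to exactly two heavy-atom neighbours."""
    degree = [0] * mol.n_atoms
    for i, j, _ in mol.bonds:
        degree[i] += 1
        degree[j] += 1
    return [idx for idx, (el, _c, _ar) in enumerate(mol.atoms)
            if el == "C" and degree[idx] == 2]


def mdec22(mol: Molecule) -> float:
    """Molecular distance edge between all secondary carbons.

    ``n22 / d̄²`` with ``d̄ = (Π d_ij)^(1/(2·n22))`` over all unordered
    secondary-carbon pairs; 0 when fewer than two secondary carbons exist.
    """
    sec = _secondary_carbons(mol)
    if len(sec) < 2:
        return 0.0
    dist = topological_distances(mol)
    log_prod = 0.0
    n_pairs = 0
    for a in range(len(sec)):
        for b in range(a + 1, len(sec)):
            log_prod += math.log(dist[sec[a], sec[b]])
            n_pairs += 1
    dbar = math.exp(log_prod / (2 * n_pairs))
    return n_pairs / dbar**2


def mats1p(mol: Molecule,
           weights: Mapping[str, float] | None = None) -> float:
    """Moran autocorrelation at lag 1, polarizability weighted.

    ``MATS1 = [(1/P1) Σ_{d_ij=1} (w_i−w̄)(w_j−w̄)] / [(1/N) Σ_i (w_i−w̄)²]``
    with carbon-scaled polarizability weights on the hydrogen-depleted graph.
    Returns 0 when the weight variance is zero or no bonded pair exists.
    """
    if weights is None:
        weights = POLARIZABILITY
    try:
        w = np.array([weights[el] for el, _c, _ar in mol.atoms], dtype=float)
    except KeyError as exc:
        raise UnknownElementError(exc.args[0], "polarizability") from exc
    w = w / CARBON_POLARIZABILITY
    n = len(w)
    if n == 0 or mol.n_bonds == 0:
        return 0.0
    wc = w - w.mean()
    denom = float(wc @ wc) / n
    if denom == 0.0:
        return 0.0
    num = sum(wc[i] * wc[j] for i, j, _ in mol.bonds) / mol.n_bonds
    return float(num / denom)


# auxiliary descriptors used to pad native matrices


def _heavy_atom_count(mol: Molecule) -> float:
    return float(mol.n_atoms)


_ATOMIC_MASS = {"H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
                "F": 18.998, "Si": 28.085, "P": 30.974, "S": 32.06,
                "Cl": 35.45, "Br": 79.904, "I": 126.904}

_DEFAULT_VALENCE = {"B": 3, "C": 4, "N": 3, "O": 2, "F": 1, "Si": 4, "P": 3,
                    "S": 2, "Cl": 1, "Br": 1, "I": 1}


def _molecular_weight(mol: Molecule) -> float:
    """Molecular weight including implicit hydrogens (valence-rule count)."""
    bond_order = [0.0] * mol.n_atoms
    for i, j, order in mol.bonds:
        o = 1.5 if order == "ar" else float(order)
        bond_order[i] += o
        bond_order[j] += o
    mw = 0.0
    for idx, (el, charge, _ar) in enumerate(mol.atoms):
        mw += _ATOMIC_MASS[el]
        valence = _DEFAULT_VALENCE.get(el, 0) + charge
        implicit_h = max(0, int(round(valence - bond_order[idx])))
        mw += implicit_h * _ATOMIC_MASS["H"]
    return mw


def _ring_count(mol: Molecule) -> float:
    """Cyclomatic number (bonds − atoms + 1 for a connected graph)."""
    return float(mol.n_bonds - mol.n_atoms + 1)


MODEL_DESCRIPTORS = ("Eta_betaS", "MDEC-22", "MATS1p")

DESCRIPTOR_REGISTRY: dict[str, Callable[[Molecule], float]] = {
    "Eta_betaS": eta_beta_s,
    "MDEC-22": mdec22,
    "MATS1p": mats1p,
    "nHeavy": _heavy_atom_count,
    "MW": _molecular_weight,
    "nRing": _ring_count,
}


# ---------------------------------------------------------------------------
# descriptor matrices


@dataclass
class DescriptorMatrix:
    """Compounds × descriptors table with explicit missing values.

    A thin wrapper over a float DataFrame (NaN marks a failed or missing
    computation) plus optional per-descriptor block labels, mirroring the
    block structure vendor descriptor suites attach to their output.
    """

    values: pd.DataFrame
    block_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate descriptor names: {list(dups)}")
        self.values = self.values.astype(float)

    @property
    def compound_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, names: Sequence[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"descriptors not in matrix: {missing}")
        return DescriptorMatrix(
            self.values[list(names)].copy(),
            {n: b for n, b in self.block_labels.items() if n in names},
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the CSV dialect: ``compound_id`` first column, optional
        ``block:`` second header row when block labels are present."""
        with open(path, "w", newline="") as fh:
            cols = self.descriptor_names
            fh.write(",".join(["compound_id"] + cols) + "\n")
            if self.block_labels:
                fh.write(",".join(
                    ["block:"] + [self.block_labels.get(c, "") for c in cols]
                ) + "\n")
            for cid, row in self.values.iterrows():
                cells = ["" if pd.isna(v) else repr(float(v)) for v in row]
                fh.write(",".join([str(cid)] + cells) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")
            if header[0] != "compound_id":
                raise ValueError("first column must be 'compound_id'")
            names = header[1:]
            pos = fh.tell()
            second = fh.readline().rstrip("\n").split(",")
            blocks: dict[str, str] = {}
            if second and second[0] == "block:":
                blocks = {n: b for n, b in zip(names, second[1:]) if b}
            else:
                fh.seek(pos)
            ids, rows = [], []
            for line in fh:
                cells = line.rstrip("\n").split(",")
                if not cells or cells == [""]:
                    continue
                ids.append(cells[0])
                rows.append([float(c) if c != "" else np.nan
                             for c in cells[1:]])
        df = pd.DataFrame(rows, index=ids, columns=names)
        return cls(df, blocks)


def build_matrix(mols: Sequence[Molecule],
                 descriptor_names: Sequence[str] = MODEL_DESCRIPTORS,
                 compound_ids: Sequence[str] | None = None) -> DescriptorMatrix:
    """Compute native descriptors for each molecule, in input order.

    A computation failure (e.g. an element outside a weight table) is
    recorded as a missing value, never silently as zero.
    """
    unknown = [n for n in descriptor_names if n not in DESCRIPTOR_REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown descriptors {unknown}; available: "
            f"{sorted(DESCRIPTOR_REGISTRY)}"
        )
    if compound_ids is None:
        compound_ids = [m.canonical_key for m in mols]
    rows = []
    for mol in mols:
        row = []
        for name in descriptor_names:
            try:
                row.append(DESCRIPTOR_REGISTRY[name](mol))
            except (UnknownElementError, ValueError):
                row.append(np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, index=list(compound_ids),
                      columns=list(descriptor_names), dtype=float)
    return DescriptorMatrix(df)


def filter_constant_missing(
    m: DescriptorMatrix,
) -> tuple[DescriptorMatrix, int, int]:
    """Drop constant columns, then columns containing any missing value.

    Returns the reduced matrix and the two removal counts.  A column that is
    both constant and incomplete counts as constant (removed first).
    """
    df = m.values
    nunique = df.nunique(dropna=False)
    constant = df.columns[nunique <= 1]
    df2 = df.drop(columns=constant)
    with_missing = df2.columns[df2.isna().any()]
    df3 = df2.drop(columns=with_missing)
    kept = DescriptorMatrix(
        df3.copy(),
        {n: b for n, b in m.block_labels.items() if n in df3.columns},
    )
    return kept, len(constant), len(with_missing)


def correlation_reduce(m: DescriptorMatrix,
                       threshold: float = 0.95) -> DescriptorMatrix:
    """Greedy pairwise-correlation redundancy reduction.

    Scans columns left to right; a column whose absolute Pearson correlation
    with any retained earlier column reaches ``threshold`` is dropped.  A
    simple deterministic stand-in for distance-based pool-reduction schemes —
    it only pre-conditions variable selection, it is not the model.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    df = m.values
    if df.isna().any().any():
        raise ValueError("matrix contains missing values; "
                         "run filter_constant_missing first")
    stds = df.std(ddof=0)
    if (stds == 0).any():
        bad = list(df.columns[stds == 0])
        raise ValueError(f"zero-variance columns present: {bad}; "
                         "run filter_constant_missing first")
    corr = np.corrcoef(df.to_numpy(), rowvar=False)
    n = len(df.columns)
    keep: list[int] = []
    for j in range(n):
        if all(abs(corr[j, k]) < threshold for k in keep):
            keep.append(j)
    cols = [df.columns[j] for j in keep]
    return m.subset(cols)
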