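"""Frozen element tables and descriptor conventions.

The three model descriptors (Eta_betaS, MDEC-22, MATS1p) are defined in the
literature with minor convention differences between software vendors.  The
conventions used by this package are fixed here, versioned, and never changed
silently; ``CONVENTION_VERSION`` is printed by ``qsrrkit --version`` so that
serialized models can be tied to the descriptor conventions they were built
with.

Conventions
-----------
* ``Eta_betaS``: sum over the sigma framework of the hydrogen-depleted graph,
  each bond counted once; a bond contributes ``ETA_SIGMA_SIMILAR`` (0.5) when
  the Pauling electronegativity difference of its endpoints is at most
  ``ETA_ELECTRONEGATIVITY_GAP`` (0.3) and ``ETA_SIGMA_DISSIMILAR`` (0.75)
  otherwise.
* ``MDEC-22``: geometric mean of pairwise topological distances between
  secondary carbons uses the exponent ``1 / (2 * n_pairs)`` (the convention of
  the original molecular-distance-edge formulation and of CDK/PaDEL).
* ``MATS1p``: Moran autocorrelation at topological lag 1 on the
  hydrogen-depleted graph; atomic weights are static polarizabilities scaled
  by the carbon value; implicit hydrogens do not contribute.
"""

from __future__ import annotations

CONVENTION_VERSION = "1.0"

# Pauling electronegativities.
ELECTRONEGATIVITY: dict[str, float] = {
    "H": 2.20,
    "B": 2.04,
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "F": 3.98,
    "Si": 1.90,
    "P": 2.19,
    "S": 2.58,
    "Cl": 3.16,
    "Br": 2.96,
    "I": 2.66,
}

# Static atomic polarizabilities, cubic angstroms (CRC Handbook values, the
# table used by common 2D-autocorrelation implementations).
POLARIZABILITY: dict[str, float] = {
    "H": 0.667,
    "B": 3.03,
    "C": 1.76,
    "N": 1.10,
    "O": 0.802,
    "F": 0.557,
    "Si": 5.38,
    "P": 3.63,
    "S": 2.90,
    "Cl": 2.18,
    "Br": 3.05,
    "I": 5.35,
}

CARBON_POLARIZABILITY = POLARIZABILITY["C"]

ETA_SIGMA_SIMILAR = 0.5
ETA_SIGMA_DISSIMILAR = 0.75
ETA_ELECTRONEGATIVITY_GAP = 0.3
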