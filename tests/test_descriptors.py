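import math

import numpy as np
import pandas as pd
import pytest

from qsrrkit.descriptors import (DescriptorMatrix, build_matrix,
                                 correlation_reduce, eta_beta_s,
                                 filter_constant_missing, mats1p, mdec22,
                                 topological_distances, MODEL_DESCRIPTORS)
from qsrrkit.molecules import parse_smiles


# ---------------------------------------------------------------------------
# independent brute-force reference implementations (oracles)
#
# Deliberately written from the published descriptor definitions with a
# different code path from the package: networkx shortest paths, separately
# entered element tables, explicit double loops.

import networkx as nx

_ORACLE_EN = {"C": 2.55, "N": 3.04, "O": 3.44, "H": 2.20, "S": 2.58,
              "P": 2.19, "F": 3.98, "Cl": 3.16, "Br": 2.96, "I": 2.66}
_ORACLE_POL = {"C": 1.76, "N": 1.10, "O": 0.802, "H": 0.667, "S": 2.90,
               "P": 3.63, "F": 0.557, "Cl": 2.18, "Br": 3.05, "I": 5.35}


def _graph(mol):
    g = nx.Graph()
    for idx, (el, _c, _a) in enumerate(mol.atoms):
        g.add_node(idx, element=el)
    for i, j, _ in mol.bonds:
        g.add_edge(i, j)
    return g


def oracle_eta_beta_s(mol):
    total = 0.0
    for i, j, _ in mol.bonds:
        d = abs(_ORACLE_EN[mol.atoms[i][0]] - _ORACLE_EN[mol.atoms[j][0]])
        total += 0.5 if d <= 0.3 else 0.75
    return total


def oracle_mdec22(mol):
    g = _graph(mol)
    secondary = [v for v, data in g.nodes(data=True)
                 if data["element"] == "C" and g.degree(v) == 2]
    pairs = [(a, b) for k, a in enumerate(secondary)
             for b in secondary[k + 1:]]
    if not pairs:
        return 0.0
    prod = 1.0
    for a, b in pairs:
        prod *= nx.shortest_path_length(g, a, b)
    dbar = prod ** (1.0 / (2 * len(pairs)))
    return len(pairs) / dbar**2


def oracle_mats1p(mol):
    g = _graph(mol)
    w = np.array([_ORACLE_POL[g.nodes[v]["element"]] / _ORACLE_POL["C"]
                  for v in sorted(g.nodes)])
    if g.number_of_edges() == 0:
        return 0.0
    wbar = w.mean()
    denom = np.sum((w - wbar) ** 2) / len(w)
    if denom == 0:
        return 0.0
    num = 0.0
    for i, j in g.edges:
        num += (w[i] - wbar) * (w[j] - wbar)
    num /= g.number_of_edges()
    return num / denom


# ---------------------------------------------------------------------------


class TestTopologicalDistances:
    def test_ethanol_end_to_end(self):
        d = topological_distances(parse_smiles("CCO"))
        assert d[0, 2] == 2 and d[2, 0] == 2

    def test_cyclohexane_max_distance(self):
        d = topological_distances(parse_smiles("C1CCCCC1"))
        assert d.max() == 3

    def test_isobutane_terminal_distance(self):
        mol = parse_smiles("CC(C)C")
        d = topological_distances(mol)
        terminals = [i for i, row in enumerate(d) if (row == 1).sum() == 1]
        assert all(d[a, b] == 2 for a in terminals for b in terminals
                   if a != b)

    def test_symmetric_zero_diagonal(self, probe_molecules):
        for mol in probe_molecules[:10]:
            d = topological_distances(mol)
            assert (d == d.T).all() and (np.diag(d) == 0).all()


class TestEtaBetaS:
    def test_methane_no_heavy_bond(self):
        assert eta_beta_s(parse_smiles("C")) == 0.0

    def test_ethane_single_similar_bond(self):
        # one C-C sigma bond between atoms of equal electronegativity
        assert eta_beta_s(parse_smiles("CC")) == pytest.approx(0.5)

    def test_ethanol(self):
        # C-C (similar) + C-O (dissimilar): 0.5 + 0.75
        mol = parse_smiles("CCO")
        assert eta_beta_s(mol) == pytest.approx(1.25)
        assert eta_beta_s(mol) == pytest.approx(oracle_eta_beta_s(mol))

    def test_unknown_element_named_in_error(self):
        mol = parse_smiles("C[SiH2]C")
        # Si is tabulated; use a genuinely missing element
        mol_se = parse_smiles("C[Se]C")
        with pytest.raises(KeyError, match="Se"):
            eta_beta_s(mol_se)
        assert eta_beta_s(mol) > 0

    def test_monotone_along_n_alkane_series(self):
        values = [eta_beta_s(parse_smiles("C" * n)) for n in range(3, 11)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestMdec22:
    def test_propane_single_secondary_carbon(self):
        assert mdec22(parse_smiles("CCC")) == 0.0

    def test_butane_one_pair_distance_one(self):
        # both geometric-mean conventions give dbar = 1 here
        assert mdec22(parse_smiles("CCCC")) == pytest.approx(1.0)

    def test_hexane_hand_enumeration(self):
        # secondary carbons C2,C3,C4,C5; pair distances {1,1,1,2,2,3}
        prod = 1 * 1 * 1 * 2 * 2 * 3
        expected = 6 / (prod ** (1 / 12)) ** 2
        assert mdec22(parse_smiles("CCCCCC")) == pytest.approx(expected)

    def test_nonnegative_on_probe_set(self, probe_molecules):
        assert all(mdec22(m) >= 0 for m in probe_molecules)


class TestMats1p:
    def test_homonuclear_zero_variance(self):
        assert mats1p(parse_smiles("CCCC")) == 0.0

    def test_single_atom_no_pairs(self):
        assert mats1p(parse_smiles("C")) == 0.0

    def test_ethanol_value(self):
        # hand derivation gives exactly -1/4 for C-C-O
        assert mats1p(parse_smiles("CCO")) == pytest.approx(-0.25)

    def test_missing_weight_raises(self):
        with pytest.raises(KeyError, match="Se"):
            mats1p(parse_smiles("C[Se]C"))

    def test_bounded_on_probe_set(self, probe_molecules):
        values = [mats1p(m) for m in probe_molecules]
        assert all(-1.0 <= v <= 1.0 for v in values)


class TestOracleEquivalence:
    """Native descriptors vs brute-force reference on the 50-molecule probe."""

    def test_all_three_descriptors_match(self, probe_molecules):
        for mol in probe_molecules:
            assert eta_beta_s(mol) == pytest.approx(
                oracle_eta_beta_s(mol), abs=1e-6), mol.smiles_source
            assert mdec22(mol) == pytest.approx(
                oracle_mdec22(mol), abs=1e-6), mol.smiles_source
            assert mats1p(mol) == pytest.approx(
                oracle_mats1p(mol), abs=1e-6), mol.smiles_source

    def test_smiles_writing_order_invariance(self):
        pairs = [("CCCO", "OCCC"), ("CC(C)CO", "OCC(C)C"),
                 ("CCOC(C)=O", "CC(=O)OCC"), ("NCCO", "OCCN")]
        for a, b in pairs:
            ma, mb = parse_smiles(a), parse_smiles(b)
            assert ma.canonical_key == mb.canonical_key
            assert eta_beta_s(ma) == pytest.approx(eta_beta_s(mb))
            assert mdec22(ma) == pytest.approx(mdec22(mb))
            assert mats1p(ma) == pytest.approx(mats1p(mb))


class TestBuildMatrix:
    def test_shape_three_by_three(self):
        mols = [parse_smiles(s) for s in ["CCO", "CCC", "CCCC"]]
        mat = build_matrix(mols, MODEL_DESCRIPTORS)
        assert mat.shape == (3, 3)

    def test_empty_molecule_list(self):
        mat = build_matrix([], MODEL_DESCRIPTORS)
        assert mat.shape == (0, 3)

    def test_unknown_descriptor_rejected(self):
        with pytest.raises(KeyError):
            build_matrix([parse_smiles("CCO")], ["NotADescriptor"])

    def test_failed_computation_recorded_as_missing(self):
        # selenium is outside both element tables -> NaN, never zero
        mols = [parse_smiles("C[Se]C"), parse_smiles("CCO")]
        mat = build_matrix(mols, MODEL_DESCRIPTORS)
        row = mat.values.iloc[0]
        assert np.isnan(row["Eta_betaS"]) and np.isnan(row["MATS1p"])
        assert np.isfinite(row["MDEC-22"])
        assert not mat.values.iloc[1].isna().any()


class TestFilterConstantMissing:
    def test_constant_column_removed(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 1.0]})
        kept, n_const, n_miss = filter_constant_missing(DescriptorMatrix(df))
        assert kept.descriptor_names == ["a"]
        assert (n_const, n_miss) == (1, 0)

    def test_missing_column_removed(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, np.nan]})
        kept, n_const, n_miss = filter_constant_missing(DescriptorMatrix(df))
        assert kept.descriptor_names == ["a"]
        assert (n_const, n_miss) == (0, 1)

    def test_pool_scale_mirror(self, rng):
        # 4182 columns: 2071 constant, 91 with missing values -> 2020 kept
        n = 30
        cols = {}
        for j in range(2071):
            cols[f"const{j}"] = np.full(n, float(j))
        for j in range(91):
            col = rng.normal(size=n)
            col[rng.integers(n)] = np.nan
            cols[f"miss{j}"] = col
        for j in range(2020):
            cols[f"ok{j}"] = rng.normal(size=n)
        mat = DescriptorMatrix(pd.DataFrame(cols))
        kept, n_const, n_miss = filter_constant_missing(mat)
        assert mat.shape[1] == 4182
        assert (n_const, n_miss) == (2071, 91)
        assert kept.shape[1] == 2020


class TestCorrelationReduce:
    def test_identical_columns_one_removed(self, rng):
        x = rng.normal(size=20)
        mat = DescriptorMatrix(pd.DataFrame({"a": x, "b": x.copy()}))
        assert correlation_reduce(mat, 0.95).descriptor_names == ["a"]

    def test_orthogonal_columns_unchanged(self):
        df = pd.DataFrame({"a": [1.0, -1, 1, -1], "b": [1.0, 1, -1, -1]})
        assert correlation_reduce(DescriptorMatrix(df),
                                  0.95).descriptor_names == ["a", "b"]

    def test_scaled_copy_detected(self, rng):
        cols = {f"c{j}": rng.normal(size=25) for j in range(1, 5)}
        cols["c5"] = 2.0 * cols["c1"]
        mat = DescriptorMatrix(pd.DataFrame(cols))
        reduced = correlation_reduce(mat, 0.95)
        # brute-force check: all remaining pairs below threshold
        assert reduced.shape[1] == 4
        vals = reduced.values.to_numpy()
        corr = np.corrcoef(vals, rowvar=False)
        off = corr[~np.eye(4, dtype=bool)]
        assert (np.abs(off) < 0.95).all()

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            correlation_reduce(DescriptorMatrix(df), 0.9)


class TestMatrixIO:
    def test_csv_round_trip_with_blocks(self, tmp_path):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [3.0, 4.0]},
                          index=["m1", "m2"])
        mat = DescriptorMatrix(df, {"a": "topological", "b": "autocorr"})
        path = tmp_path / "m.csv"
        mat.to_csv(path)
        back = DescriptorMatrix.from_csv(path)
        assert back.descriptor_names == ["a", "b"]
        assert back.block_labels == mat.block_labels
        assert np.isnan(back.values.loc["m2", "a"])
        assert back.values.loc["m2", "b"] == 4.0

    def test_duplicate_names_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], columns=["a", "a"])
        with pytest.raises(ValueError):
            DescriptorMatrix(df)
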