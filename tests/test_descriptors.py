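"""Descriptor correctness against independent brute-force oracles, plus the
invariances every topological descriptor must satisfy."""

import numpy as np
import pandas as pd
import pytest

import volqsrr as v
from volqsrr.molgraph import PropertyTable, atom_weights, default_properties

from conftest import autocorrelation_oracle

FAMILIES = {"ATSC": v.atsc, "AATSC": v.aatsc, "MATS": v.mats, "GATS": v.gats}


def _scaled_property_table(scale: float = 1.0, shift: float = 0.0) -> PropertyTable:
    """Property table with every m-scheme weight mapped to a*m + b."""
    base = default_properties()
    rows = {}
    for el in ("C", "N", "O", "S"):
        rows[el] = {
            "Z": base.value(el, "Z"),
            "principal_quantum_number": base.principal_quantum_number(el),
            "valence_electrons": base.valence_electrons(el),
            "mass": scale * base.value(el, "m") + shift,
            "vdw_volume": base.value(el, "v"),
            "sanderson_en": base.value(el, "e"),
            "polarizability": base.value(el, "p"),
        }
    return PropertyTable(rows)


class TestAutocorrelations:
    @pytest.mark.parametrize("family,func", FAMILIES.items())
    @pytest.mark.parametrize("scheme", ["m", "e", "s", "Z"])
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_small_graphs_match_bruteforce_oracle(self, family, func, scheme, k):
        smiles = ["CCO", "CCC", "CC(C)O", "C=CC", "OCC=O", "CC(C)(C)O",
                  "C1CC1", "C1COC1S"]
        smiles += v.make_molecules(10, seed=11, min_atoms=3, max_atoms=5)
        for smi in smiles:
            g = v.from_smiles(smi)
            if g.n_atoms > 5 or (family == "GATS" and g.n_atoms < 2):
                continue
            w = atom_weights(g, scheme)
            expected = autocorrelation_oracle(g, k, w, family)
            assert func(g, k, scheme) == pytest.approx(expected), (smi, k)

    def test_ethanol_lag1_hand_value(self):
        # chain C-C-O: ordered pairs at d=1 are (C1,C2)x2 and (C2,O)x2
        g = v.from_smiles("CCO")
        props = default_properties()
        wc, wo = props.value("C", "m"), props.value("O", "m")
        wbar = (2 * wc + wo) / 3
        expected = 2 * ((wc - wbar) ** 2 + (wc - wbar) * (wo - wbar))
        assert v.atsc(g, 1, "m") == pytest.approx(expected)
        assert v.aatsc(g, 1, "m") == pytest.approx(expected / 4)

    def test_all_carbon_graph_is_zero(self):
        g = v.from_smiles("CCCCC")
        for fam, func in FAMILIES.items():
            assert func(g, 1, "m") == 0.0

    def test_lag_beyond_diameter_is_zero(self):
        g = v.from_smiles("CCO")
        for fam, func in FAMILIES.items():
            assert func(g, 7, "e") == 0.0

    def test_centered_families_shift_invariant(self):
        g = v.from_smiles("CC(S)CO")
        shifted = _scaled_property_table(shift=13.7)
        for func in (v.atsc, v.aatsc, v.mats, v.gats):
            assert func(g, 2, "m", shifted) == \
                pytest.approx(func(g, 2, "m"), abs=1e-10)

    def test_normalized_families_affine_invariant(self):
        g = v.from_smiles("CC(S)CO")
        affine = _scaled_property_table(scale=3.2, shift=-5.0)
        for func in (v.mats, v.gats):
            assert func(g, 1, "m", affine) == pytest.approx(func(g, 1, "m"))
        # plain centered autocorrelation scales quadratically instead
        assert v.atsc(g, 1, "m", _scaled_property_table(scale=2.0)) == \
            pytest.approx(4.0 * v.atsc(g, 1, "m"))

    def test_gats_nonnegative(self):
        for smi in v.make_molecules(10, seed=13, min_atoms=4, max_atoms=12):
            g = v.from_smiles(smi)
            for k in (1, 2, 4):
                assert v.gats(g, k, "e") >= 0.0

    def test_zero_variance_convention(self):
        g = v.from_smiles("CC")
        assert v.mats(g, 1, "m") == 0.0
        assert v.gats(g, 1, "m") == 0.0


class TestVAdjMat:
    @pytest.mark.parametrize("smiles,expected", [
        ("CC", 1.0),                      # one bond
        ("CCCC", 1.0 + np.log2(3.0)),     # three bonds
        ("C", 0.0),                       # bondless convention
    ])
    def test_values(self, smiles, expected):
        assert v.vadjmat(v.from_smiles(smiles)) == pytest.approx(expected)


class TestSpectral:
    def test_sm1_is_trace(self):
        assert v.sm1(np.eye(3)) == 3.0
        with pytest.raises(ValueError, match="square"):
            v.sm1(np.ones((2, 3)))

    def test_sm1_all_carbon_barysz_is_zero(self):
        g = v.from_smiles("CCC1CC1")
        assert v.sm1(v.barysz_matrix(g, "v")) == pytest.approx(0.0)

    def test_sm1_single_oxygen_v_weighting(self):
        g = v.from_smiles("CCO")
        props = default_properties()
        expected = 1.0 - props.value("C", "v") / props.value("O", "v")
        assert v.sm1(v.barysz_matrix(g, "v")) == pytest.approx(expected)

    def test_vr1_two_atom_hand_value(self):
        # leading eigenvector of [[0,1],[1,0]] is (1,1)/sqrt(2)
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert v.vr1(m, [(0, 1, 1.0)]) == pytest.approx(np.sqrt(2.0))

    def test_vr1_path_graph_matches_eigensolver_oracle(self):
        # P3 adjacency: leading eigenvector solved independently here
        m = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        vals, vecs = np.linalg.eig(m)
        a = np.abs(vecs[:, np.argmax(vals)])
        expected = sum(1.0 / np.sqrt(a[i] * a[j]) for i, j in [(0, 1), (1, 2)])
        assert v.vr1(m, [(0, 1, 1.0), (1, 2, 1.0)]) == pytest.approx(expected)

    def test_vr1_degenerate_eigenvector_reported(self):
        # leading eigenvector (1, 0): zero component on a bonded atom
        m = np.diag([2.0, 1.0])
        with pytest.raises(ValueError, match="degenerate"):
            v.vr1(m, [(0, 1, 1.0)])


class TestCatalogue:
    def test_mandatory_names_registered(self):
        names = v.catalogue()
        assert set(v.MANDATORY_DESCRIPTORS) <= set(names)
        assert 140 <= len(names) <= 170

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            v.compute_descriptor(v.from_smiles("CC"), "BANANA3x")

    def test_every_descriptor_permutation_invariant(self, rng):
        g = v.from_smiles("CC(C)C1CCC(=O)C1CS")
        perm = rng.permutation(g.n_atoms)
        gp = g.permuted(perm)
        for name in ("AATSC4e", "AATSC2p", "MATS5v", "GATS6v",
                     "VR1_Dzs", "SM1_Dzv", "VAdjMat", "GATS3s", "MATS2m"):
            assert v.compute_descriptor(gp, name) == \
                pytest.approx(v.compute_descriptor(g, name)), name


class TestDescriptorTable:
    def test_fixture_has_identified_rows_and_mandatory_columns(self, table,
                                                               mandatory_features):
        df = mandatory_features
        assert list(df.columns) == list(v.MANDATORY_DESCRIPTORS)
        n_with_structure = sum(1 for r in table if r.identified and r.smiles)
        assert len(df) == n_with_structure == 90
        assert np.isfinite(df.to_numpy()).all()

    def test_empty_input_gives_empty_table(self):
        df = v.descriptor_table([], names=v.MANDATORY_DESCRIPTORS)
        assert df.empty and list(df.columns) == list(v.MANDATORY_DESCRIPTORS)

    def test_duplicate_rows_rejected(self, table):
        rec = table[28]
        with pytest.raises(ValueError, match="duplicate"):
            v.descriptor_table([rec, rec], names=["VAdjMat"])

    def test_missing_structure_skipped_with_warning(self, caplog):
        rec = v.CompoundRecord(1, "Unknown alkene", "O",
                               ri_2019=900.0, pct_2019=0.1)
        import logging
        with caplog.at_level(logging.WARNING, logger="volqsrr.descriptors"):
            df = v.descriptor_table([rec], names=["VAdjMat"])
        assert df.empty
        assert "no structure" in caplog.text
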