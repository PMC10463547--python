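"""Composition counting, pocket extraction, ligand descriptors, concatenation."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem

from pocketboost import featurize as ft
from pocketboost import io as pio
from pocketboost.errors import FeatureError, SchemaError


def _res(name, seq, chain="A", xyz=(0.0, 0.0, 0.0)):
    return pio.Residue(chain, seq, "", name, (("C", *xyz),))


class TestCompositionFromResidues:
    def test_counts_match_brute_force_tally(self):
        rs = pio.ResidueSet([_res("ALA", 1), _res("GLY", 2), _res("ALA", 3)])
        comp = ft.aa_composition_from_residues(rs)
        oracle = Counter(r.res_name for r in rs)
        for name, value in zip(comp.names, comp.values):
            assert value == oracle.get(name.removeprefix("aa_"), 0)
        assert comp.values.sum() == 3

    def test_empty_set_gives_zero_vector(self):
        comp = ft.aa_composition_from_residues(pio.ResidueSet([]))
        assert comp.values.sum() == 0
        assert comp.n_excluded_nonstandard == 0

    def test_nonstandard_residues_excluded_and_tallied(self):
        rs = pio.ResidueSet([_res("ALA", 1), _res("MSE", 2), _res("HOH", 3)])
        comp = ft.aa_composition_from_residues(rs)
        assert comp.values.sum() == 1
        assert comp.values[ft.STANDARD_AA3.index("ALA")] == 1
        assert comp.n_excluded_nonstandard == 2

    @given(st.lists(st.sampled_from(ft.STANDARD_AA3 + ("HOH", "MSE", "ZN")), max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_conservation_and_permutation_invariance(self, names):
        residues = [_res(n, i) for i, n in enumerate(names)]
        comp = ft.aa_composition_from_residues(pio.ResidueSet(residues))
        assert comp.values.sum() + comp.n_excluded_nonstandard == len(names)
        rev = ft.aa_composition_from_residues(pio.ResidueSet(residues[::-1]))
        assert np.array_equal(comp.values, rev.values)


class TestCompositionFromSequence:
    @pytest.mark.parametrize(
        "seq, expected_counts, expected_excluded",
        [
            ("AAG", {"A": 2, "G": 1}, 0),
            ("", {}, 0),
            ("AXA", {"A": 2}, 1),
            ("acdw", {"A": 1, "C": 1, "D": 1, "W": 1}, 0),  # case-insensitive
        ],
    )
    def test_counts(self, seq, expected_counts, expected_excluded):
        comp = ft.aa_composition_from_sequence(seq)
        for one, idx in zip(ft.STANDARD_AA1_ORDERED, range(20)):
            assert comp.values[idx] == expected_counts.get(one, 0)
        assert comp.n_excluded_nonstandard == expected_excluded
        assert comp.source_kind == "full_chain"


class TestExtractPocket:
    def _protein(self, positions):
        return pio.ResidueSet(
            [_res("ALA", i, xyz=p) for i, p in enumerate(positions, start=1)]
        )

    def test_distance_cutoff_matches_brute_force(self):
        protein = self._protein([(5.0, 0.0, 0.0), (15.0, 0.0, 0.0)])
        pocket = ft.extract_pocket(protein, [(0.0, 0.0, 0.0)], cutoff=10.0)
        assert len(pocket) == 1
        assert pocket.residues[0].res_seq == 1

    def test_cutoff_is_inclusive(self):
        protein = self._protein([(10.0, 0.0, 0.0)])
        assert len(ft.extract_pocket(protein, [(0.0, 0.0, 0.0)], cutoff=10.0)) == 1

    def test_tiny_cutoff_with_no_contacts_gives_empty_pocket(self):
        protein = self._protein([(5.0, 0.0, 0.0)])
        assert len(ft.extract_pocket(protein, [(0.0, 0.0, 0.0)], cutoff=1e-6)) == 0

    def test_huge_cutoff_returns_whole_protein(self):
        protein = self._protein([(5.0, 0.0, 0.0), (50.0, 0.0, 0.0)])
        pocket = ft.extract_pocket(protein, [(0.0, 0.0, 0.0)], cutoff=1e6)
        assert len(pocket) == len(protein)

    def test_monotone_in_cutoff(self, rng):
        positions = rng.uniform(-20, 20, size=(30, 3))
        protein = self._protein([tuple(p) for p in positions])
        lig = [tuple(x) for x in rng.uniform(-5, 5, size=(4, 3))]
        keys = []
        for cutoff in (2.0, 5.0, 10.0, 20.0):
            keys.append({r.key for r in ft.extract_pocket(protein, lig, cutoff)})
        for small, large in zip(keys, keys[1:]):
            assert small <= large

    def test_hydrogens_ignored_for_distance(self):
        res = pio.Residue("A", 1, "", "ALA", (("H", 1.0, 0.0, 0.0), ("C", 30.0, 0.0, 0.0)))
        protein = pio.ResidueSet([res])
        assert len(ft.extract_pocket(protein, [(0.0, 0.0, 0.0)], cutoff=10.0)) == 0

    def test_empty_ligand_coordinates_rejected(self):
        protein = self._protein([(1.0, 0.0, 0.0)])
        with pytest.raises(ValueError):
            ft.extract_pocket(protein, [], cutoff=10.0)


class TestLigandDescriptors:
    def test_methane_forced_by_definition(self):
        desc = ft.ligand_descriptors(Chem.MolFromSmiles("C"))
        vals = dict(zip(desc.names, desc.values))
        assert vals["HeavyAtomCount"] == 1
        assert vals["NumRotatableBonds"] == 0
        assert vals["RingCount"] == 0

    def test_ethanol_hbond_counts_match_independent_implementation(self):
        from rdkit.Chem import rdMolDescriptors

        mol = Chem.MolFromSmiles("CCO")
        desc = ft.ligand_descriptors(mol)
        vals = dict(zip(desc.names, desc.values))
        assert vals["NumHDonors"] == rdMolDescriptors.CalcNumHBD(mol) == 1
        assert vals["NumHAcceptors"] == rdMolDescriptors.CalcNumHBA(mol) == 1

    def test_smiles_and_sdf_routes_agree(self):
        from pocketboost.standardize import standardize_ligand

        smi_lig = pio.parse_ligand_text("c1ccccc1C(=O)O", "SMILES", identifier="ba")
        mol3d = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1C(=O)O"))
        AllChem.Compute2DCoords(mol3d)
        sdf_lig = pio.parse_ligand_text(Chem.MolToMolBlock(mol3d), "SDF", identifier="ba")
        a = ft.ligand_descriptors(standardize_ligand(smi_lig).ligand)
        b = ft.ligand_descriptors(standardize_ligand(sdf_lig).ligand)
        assert a.names == b.names
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_default_set_has_18_descriptors(self):
        assert len(ft.DEFAULT_DESCRIPTOR_SET) == 18

    def test_unknown_descriptor_rejected(self):
        with pytest.raises(SchemaError):
            ft.ligand_descriptors(Chem.MolFromSmiles("C"), descriptor_set=("NotAThing",))

    def test_unparsed_ligand_rejected(self):
        lig = pio.LigandStructure("x", None, "SMILES")
        with pytest.raises(FeatureError):
            ft.ligand_descriptors(lig)


class TestCombine:
    def test_concatenation_identity_and_length(self):
        comp = ft.aa_composition_from_sequence("ACDW")
        desc = ft.ligand_descriptors(Chem.MolFromSmiles("CCO"))
        fv = ft.combine(comp, desc)
        assert len(fv) == 38
        np.testing.assert_array_equal(fv.values[:20], comp.values)
        np.testing.assert_array_equal(fv.values[20:], desc.values)
        assert fv.feature_names[:20] == comp.names
        assert fv.feature_names[20:] == desc.names

    def test_schema_hash_is_stable(self):
        names = ft.COMPOSITION_NAMES + ft.DEFAULT_DESCRIPTOR_SET
        # frozen: the default 38-feature ordering must never drift silently
        assert ft.schema_hash(names) == ft.schema_hash(list(names))
        assert ft.schema_hash(names) != ft.schema_hash(names[::-1])


class TestMeanComposition:
    def test_identity_and_arithmetic(self):
        a = ft.aa_composition_from_sequence("AA")
        b = ft.aa_composition_from_sequence("AAAA")
        assert np.array_equal(ft.mean_composition([a]).values, a.values)
        mean = ft.mean_composition([a, b])
        assert mean.values[ft.STANDARD_AA1_ORDERED.index("A")] == 3

    def test_matches_brute_force_column_means(self, rng):
        vs = [
            ft.CompositionVector(rng.integers(0, 9, 20).astype(float), "pocket_file")
            for _ in range(3)
        ]
        mean = ft.mean_composition(vs)
        oracle = np.stack([v.values for v in vs]).mean(axis=0)
        np.testing.assert_allclose(mean.values, oracle, atol=1e-12)

    def test_empty_list_and_mixed_kinds_rejected(self):
        with pytest.raises(ValueError):
            ft.mean_composition([])
        a = ft.CompositionVector(np.zeros(20), "pocket_file")
        b = ft.CompositionVector(np.zeros(20), "full_chain")
        with pytest.raises(ValueError):
            ft.mean_composition([a, b])


def test_pocket_covering_whole_protein_matches_whole_protein_composition(rng):
    """Every residue within the cutoff: pocket composition == protein composition."""
    from pocketboost.synthetic import gen_pocket

    probs = rng.dirichlet(np.full(20, 2.0))
    text, truth = gen_pocket(12, probs, seed=4, spacing=1.0)
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        path = pathlib.Path(d) / "p.pdb"
        path.write_text(text)
        protein = pio.read_pocket_pdb(path)
    center = np.mean([a[1:] for r in protein for a in r.atoms], axis=0)
    pocket = ft.extract_pocket(protein, [tuple(center)], cutoff=1e5)
    comp = ft.aa_composition_from_residues(pocket)
    np.testing.assert_array_equal(comp.values, truth.values)
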