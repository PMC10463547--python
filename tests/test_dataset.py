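"""Affinity transforms, curation filters and dataset assembly."""

import math

import numpy as np
import pandas as pd
import pytest

import pocketboost as pb
from pocketboost import dataset as ds
from pocketboost.errors import SchemaError


class TestNegLogAffinity:
    @pytest.mark.parametrize(
        "value, unit, expected",
        [
            (1.0, "uM", 6.0),
            (1.0, "nM", 9.0),
            (50.0, "nM", -math.log10(5e-8)),  # 7.30103
            (1.0, "M", 0.0),
            (2.5, "mM", -math.log10(2.5e-3)),
            (1.0, "pM", 12.0),
        ],
    )
    def test_unit_conversion(self, value, unit, expected):
        assert ds.neg_log_affinity(value, unit) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("value, unit", [(0.0, "nM"), (-1.0, "uM"), (1.0, "kg")])
    def test_invalid_inputs_rejected(self, value, unit):
        with pytest.raises(ValueError):
            ds.neg_log_affinity(value, unit)


def _activity_frame(rows):
    return pd.DataFrame(
        rows, columns=["target_id", "ligand_id", "smiles", "measure_type", "value", "unit"]
    )


class TestPairFilters:
    def test_keep_last_dedup_in_source_order(self):
        df = _activity_frame([
            ("T1", "L1", "CCO", "Ki", 100.0, "nM"),
            ("T1", "L1", "CCO", "Ki", 50.0, "nM"),
            ("T1", "L1", "CCO", "Ki", 10.0, "nM"),
        ])
        out, log = ds.apply_pair_filters(df)
        assert len(out) == 1
        assert out.iloc[0]["value"] == 10.0  # last entry in file order
        assert log["drop_duplicate_pairs"] == 2

    def test_measure_type_filter_keeps_only_ki_kd(self):
        df = _activity_frame(
            [("T1", f"L{i}", "CCO", "IC50", 1.0, "uM") for i in range(2)]
            + [("T1", f"M{i}", "CCN", "Ki", 1.0, "uM") for i in range(3)]
        )
        out, log = ds.apply_pair_filters(df)
        assert len(out) == 3
        assert log["drop_measure_type"] == 2

    def test_molecular_weight_ceiling(self):
        big = "C" * 60  # ~842 Da alkane
        df = _activity_frame([
            ("T1", "L1", "CCO", "Ki", 1.0, "uM"),
            ("T1", "L2", big, "Ki", 1.0, "uM"),
            ("T1", "L3", "not_a_smiles", "Kd", 1.0, "uM"),
        ])
        out, log = ds.apply_pair_filters(df)
        assert list(out["ligand_id"]) == ["L1"]
        assert log["drop_mw_or_unparsable"] == 2

    def test_protein_threshold_drops_whole_protein(self):
        rows = [("T1", f"L{i}", "CCO" if i % 2 else "CCN", "Ki", 1.0, "uM") for i in range(5)]
        rows += [("T2", "X1", "CCC", "Kd", 1.0, "uM")]
        df = _activity_frame(rows)
        out, log = ds.apply_pair_filters(df, max_ligands_per_protein=3)
        assert set(out["target_id"]) == {"T2"}
        assert log["drop_protein_threshold"] == 5
        out_none, log_none = ds.apply_pair_filters(df, max_ligands_per_protein=None)
        assert log_none["drop_protein_threshold"] == 0
        assert set(out_none["target_id"]) == {"T1", "T2"}

    def test_conservation_of_rows(self):
        df = _activity_frame([
            ("T1", "L1", "CCO", "Ki", 100.0, "nM"),
            ("T1", "L1", "CCO", "Kd", 50.0, "nM"),
            ("T1", "L2", "IC50junk", "IC50", 1.0, "uM"),
            ("T2", "L3", "C" * 60, "Ki", 1.0, "uM"),
            ("T2", "L4", "CCN", "Kd", 1.0, "uM"),
        ])
        out, log = ds.apply_pair_filters(df)
        drops = (log["drop_measure_type"] + log["drop_mw_or_unparsable"]
                 + log["drop_duplicate_pairs"] + log["drop_protein_threshold"])
        assert log["n_input"] - drops == log["n_output"] == len(out)

    def test_idempotence(self):
        df = _activity_frame([
            ("T1", "L1", "CCO", "Ki", 100.0, "nM"),
            ("T1", "L1", "CCO", "Ki", 50.0, "nM"),
            ("T2", "L2", "CCN", "Kd", 1.0, "uM"),
        ])
        once, _ = ds.apply_pair_filters(df)
        twice, log2 = ds.apply_pair_filters(once)
        pd.testing.assert_frame_equal(once, twice)
        assert all(log2[k] == 0 for k in log2 if k.startswith("drop_"))

    def test_threshold_monotonicity(self, desk_sim):
        table = desk_sim.to_activity_table()
        # add duplicates so curation has work to do
        table = pd.concat([table, table.head(40)], ignore_index=True)
        subsets = {}
        for thr in (5, 10, None):
            out, _ = ds.apply_pair_filters(table, max_ligands_per_protein=thr)
            subsets[thr] = set(zip(out["target_id"], out["ligand_id"]))
        assert subsets[5] <= subsets[10] <= subsets[None]


class TestBuildPairDataset:
    def test_rows_featurized_with_protein_composition(self, small_sim):
        table = small_sim.to_activity_table()
        built = ds.build_pair_dataset(table, small_sim.compositions)
        assert len(built) == len(table)
        # composition block of a row equals its protein's composition vector
        i = built.ids.index(f"{table.iloc[0]['target_id']}:{table.iloc[0]['ligand_id']}")
        np.testing.assert_array_equal(
            built.X[i, :20], small_sim.compositions[table.iloc[0]["target_id"]].values
        )

    def test_missing_composition_dropped_and_logged(self, small_sim):
        table = small_sim.to_activity_table().head(15)  # spans two proteins
        comps = dict(small_sim.compositions)
        victim = table.iloc[0]["target_id"]
        comps.pop(victim)
        built = ds.build_pair_dataset(table, comps)
        expected_drop = int((table["target_id"] == victim).sum())
        assert 0 < expected_drop < 15
        assert built.build_log["drop_missing_composition"] == expected_drop
        assert len(built) == 15 - expected_drop

    def test_affinity_round_trips_through_table(self, small_sim):
        table = small_sim.to_activity_table()
        built = ds.build_pair_dataset(table, small_sim.compositions)
        truth = {f"{r.complex_or_target_id}:{r.ligand_id}": r.neg_log_affinity
                 for r in small_sim.records}
        for pid, y in zip(built.ids, built.y):
            assert y == pytest.approx(truth[pid], abs=1e-9)


class TestBuildCasfDataset:
    @pytest.fixture()
    def casf_fixture(self, tmp_path, small_sim):
        """10 'complexes': pocket + one-ligand SDF-less SMILES files + index."""
        from pocketboost import io as pio

        pockets = tmp_path / "pockets"
        ligands = tmp_path / "ligands"
        pockets.mkdir(), ligands.mkdir()
        ids = []
        records = []
        for i, rec in enumerate(small_sim.records[:10]):
            cid = f"c{i:03d}"
            ids.append(cid)
            (pockets / f"{cid}_pocket.pdb").write_text(
                small_sim.pockets[rec.complex_or_target_id]
            )
            (ligands / f"{cid}.smi").write_text(
                f"{small_sim.ligand_smiles[rec.ligand_id]} {cid}\n"
            )
            records.append(pio.AffinityRecord(cid, cid, rec.measure_type,
                                              rec.neg_log_affinity))
        index = tmp_path / "index.dat"
        pio.write_index(records, index)
        return index, ids, pockets, ligands

    def test_split_sizes_and_disjointness(self, casf_fixture):
        index, ids, pockets, ligands = casf_fixture
        core = ids[:3]
        built = ds.build_casf_dataset(index, core, pockets, ligands)
        labels = built.split_labels
        assert (labels == "test").sum() == 3
        assert (labels == "train").sum() == 7
        train_ids = {i for i, l in zip(built.ids, labels) if l == "train"}
        test_ids = {i for i, l in zip(built.ids, labels) if l == "test"}
        assert train_ids.isdisjoint(test_ids)

    def test_unstandardizable_ligand_dropped_and_counted(self, casf_fixture, tmp_path):
        from test_standardize import BAD_VALENCE_SDF
        from pocketboost.standardize import STAGE_NATIVE, StandardizationConfig

        index, ids, pockets, ligands = casf_fixture
        (ligands / f"{ids[5]}.smi").unlink()
        (ligands / f"{ids[5]}.sdf").write_text(BAD_VALENCE_SDF)
        cfg = StandardizationConfig(stage_order=(STAGE_NATIVE,))
        built = ds.build_casf_dataset(index, ids[:3], pockets, ligands,
                                      standardize_config=cfg)
        assert len(built) == 9
        assert built.build_log["drop_standardization"] == 1


class TestDatasetContainer:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(SchemaError):
            ds.Dataset(ids=["a", "a"], X=np.zeros((2, 1)), y=np.zeros(2),
                       feature_names=("f",))

    def test_frame_round_trip(self, small_dataset):
        back = ds.Dataset.from_frame(small_dataset.to_frame())
        np.testing.assert_allclose(back.X, small_dataset.X)
        np.testing.assert_allclose(back.y, small_dataset.y)
        assert back.feature_names == small_dataset.feature_names
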