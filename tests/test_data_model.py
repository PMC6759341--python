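import numpy as np
import pytest

from myconest.data_model import (
    CountTable,
    DataError,
    PairedDesign,
    combine_paired,
    presence_absence,
    read_count_table,
    read_metadata,
    standardize_depth,
    write_count_table,
    write_metadata,
)
from myconest.diversity import otu_richness
from myconest.synthetic import SimulationParams, simulate_dataset

from conftest import make_metadata, random_table


class TestCountTableIO:
    def test_tsv_identity_roundtrip(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\tS1\tS2\nA\t3\t0\nB\t1\t2\n")
        t = read_count_table(p)
        assert t.otu_ids == ["A", "B"]
        assert t.sample_ids == ["S1", "S2"]
        assert np.array_equal(t.counts, [[3, 0], [1, 2]])

    def test_negative_cell_names_offender(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\tS1\tS2\nA\t3\t0\nB\t-1\t2\n")
        with pytest.raises(DataError, match=r"'B'.*'S1'"):
            read_count_table(p)

    def test_non_integer_cell_names_offender(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\tS1\nA\t3.5\n")
        with pytest.raises(DataError, match=r"non-integer.*'A'.*'S1'"):
            read_count_table(p)

    def test_duplicate_otu_id_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\tS1\nA\t3\nA\t1\n")
        with pytest.raises(DataError, match="duplicate"):
            read_count_table(p)

    @pytest.mark.parametrize("seed", range(20))
    def test_tsv_roundtrip_random_tables(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_otus=int(rng.integers(1, 12)), n_samples=int(rng.integers(1, 8)))
        p = tmp_path / "t.tsv"
        write_count_table(t, p)
        assert read_count_table(p) == t

    @pytest.mark.parametrize("seed", range(5))
    def test_biom_json_roundtrip(self, tmp_path, seed):
        t = random_table(np.random.default_rng(seed))
        p = tmp_path / "t.biom.json"
        write_count_table(t, p, format="biom_json")
        assert read_count_table(p, format="biom_json") == t

    def test_unknown_format(self, tmp_path):
        with pytest.raises(DataError, match="format"):
            read_count_table(tmp_path / "x", format="hdf5")


class TestCountTableInvariants:
    def test_shape_mismatch(self):
        with pytest.raises(DataError, match="shape"):
            CountTable(["A"], ["S1", "S2"], np.zeros((1, 1), dtype=int))

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError, match="negative"):
            CountTable(["A"], ["S1"], np.array([[-2]]))

    def test_float_integral_counts_accepted(self):
        t = CountTable(["A"], ["S1"], np.array([[2.0]]))
        assert t.counts.dtype == np.int64


class TestMetadata:
    def _write(self, tmp_path, rows, header=None):
        header = header or "sample_id\tplant_id\ttreatment\thabitat\televation\tcollection_year\tph"
        p = tmp_path / "m.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_basic_row(self, tmp_path):
        p = self._write(tmp_path, ["S1\tP1\tintact\tgrassland\t640\t2015\t5.5"])
        (m,) = read_metadata(p)
        assert m.treatment == "intact"
        assert m.habitat == "grassland"
        assert m.elevation == 640.0
        assert m.ph == 5.5

    def test_bad_treatment_enum(self, tmp_path):
        p = self._write(tmp_path, ["S1\tP1\tsieved\tgrassland\t640\t2015\t5.5"])
        with pytest.raises(DataError, match="treatment"):
            read_metadata(p)

    def test_bad_habitat_enum(self, tmp_path):
        p = self._write(tmp_path, ["S1\tP1\tintact\tforest\t640\t2015\t5.5"])
        with pytest.raises(DataError, match="habitat"):
            read_metadata(p)

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample_id\ttreatment\nS1\tintact\n")
        with pytest.raises(DataError, match="missing required"):
            read_metadata(p)

    def test_extra_columns_carried_through(self, tmp_path):
        p = self._write(
            tmp_path,
            ["S1\tP1\tintact\tgrassland\t640\t2015\t5.5\t7.7"],
            header="sample_id\tplant_id\ttreatment\thabitat\televation\tcollection_year\tph\tmystery",
        )
        (m,) = read_metadata(p)
        assert m.extras["mystery"] == "7.7"
        assert m.numeric_factors()["mystery"] == 7.7

    def test_generator_roundtrip_60_records(self, tmp_path):
        ds = simulate_dataset(SimulationParams(seed=3))
        p = tmp_path / "m.tsv"
        write_metadata(ds.metadata, p)
        records = read_metadata(p)
        assert len(records) == 60
        assert {m.treatment for m in records} == {"intact", "disturbed"}
        # design reconstructible from the round-tripped file
        design = PairedDesign.from_metadata(records)
        assert design.pairs == ds.design.pairs


class TestPairedDesign:
    def test_sample_in_two_pairs_rejected(self):
        with pytest.raises(DataError, match="more than one pair"):
            PairedDesign({"P1": ("a", "b"), "P2": ("b", "c")})

    def test_from_metadata_missing_treatment(self):
        meta = [make_metadata("S1", "P1", "intact")]
        with pytest.raises(DataError, match="missing treatment"):
            PairedDesign.from_metadata(meta)

    def test_pair_members_must_share_elevation(self):
        meta = [
            make_metadata("S1", "P1", "intact", elevation=640),
            make_metadata("S2", "P1", "disturbed", elevation=700),
        ]
        with pytest.raises(DataError, match="disagree"):
            PairedDesign.from_metadata(meta)


class TestStandardizeDepth:
    def test_single_otu_forced_outcome(self):
        t = CountTable(["A"], ["S1"], np.array([[50_000]]))
        out = standardize_depth(t, depth=10_000, seed=0)
        assert out.counts[0, 0] == 10_000

    @pytest.mark.parametrize("seed", range(5))
    def test_all_columns_sum_to_depth(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_otus=20, n_samples=6, high=2_000)
        out = standardize_depth(t, depth=1_000, seed=seed)
        assert np.all(out.column_sums() == 1_000)
        assert np.all(out.counts <= t.counts)

    def test_deterministic_given_seed(self, rng):
        t = random_table(rng, n_otus=15, n_samples=4, high=3_000)
        a = standardize_depth(t, depth=2_000, seed=7)
        b = standardize_depth(t, depth=2_000, seed=7)
        assert a == b
        c = standardize_depth(t, depth=2_000, seed=8)
        assert not np.array_equal(a.counts, c.counts)

    def test_hypergeometric_expectation(self):
        # depth * 9000 / 12000 = 7500; mean over 1000 seeds within MC error
        t = CountTable(["A", "B"], ["S1"], np.array([[9_000], [3_000]]))
        draws = [
            standardize_depth(t, depth=10_000, seed=s).counts[0, 0]
            for s in range(1_000)
        ]
        # per-draw SD ~ 17.7 -> SE of the mean ~ 0.56; 5 sigma ~ 2.8
        assert abs(np.mean(draws) - 7_500) < 3.0

    def test_shortfall_aborts_by_default(self):
        t = CountTable(["A"], ["S1", "S2"], np.array([[20_000, 500]]))
        with pytest.raises(DataError, match=r"'S2' \(500 < 10000\)"):
            standardize_depth(t, depth=10_000, seed=0)

    def test_shortfall_drop_policy(self):
        t = CountTable(["A"], ["S1", "S2"], np.array([[20_000, 500]]))
        with pytest.warns(UserWarning, match="dropping sample 'S2'"):
            out = standardize_depth(t, depth=10_000, seed=0, on_shortfall="drop")
        assert out.sample_ids == ["S1"]


class TestCombinePaired:
    def test_cellwise_addition(self):
        t = CountTable(
            ["A", "B", "C"], ["P1-I", "P1-D"], np.array([[2, 0], [0, 0], [1, 3]])
        )
        design = PairedDesign({"P1": ("P1-I", "P1-D")})
        out = combine_paired(t, design)
        assert out.sample_ids == ["P1"]
        assert np.array_equal(out.counts[:, 0], [2, 0, 4])

    def test_orphan_sample_rejected(self):
        t = CountTable(["A"], ["P1-I", "P1-D", "X"], np.array([[1, 2, 3]]))
        design = PairedDesign({"P1": ("P1-I", "P1-D")})
        with pytest.raises(DataError, match=r"unpaired.*'X'"):
            combine_paired(t, design)

    def test_missing_pair_member_rejected(self):
        t = CountTable(["A"], ["P1-I"], np.array([[1]]))
        design = PairedDesign({"P1": ("P1-I", "P1-D")})
        with pytest.raises(DataError, match="'P1-D'"):
            combine_paired(t, design)

    def test_synthetic_30_pairs_collapse_to_30_columns(self, default_dataset):
        out = combine_paired(default_dataset.table, default_dataset.design)
        assert len(out.sample_ids) == 30
        assert out.otu_ids == default_dataset.table.otu_ids

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_richness_properties(self, seed):
        rng = np.random.default_rng(seed)
        n_pairs = int(rng.integers(2, 5))
        sample_ids = [f"P{i}-{t}" for i in range(n_pairs) for t in "ID"]
        t = CountTable(
            [f"O{i}" for i in range(8)],
            sample_ids,
            rng.integers(0, 10, size=(8, 2 * n_pairs)),
        )
        design = PairedDesign({f"P{i}": (f"P{i}-I", f"P{i}-D") for i in range(n_pairs)})
        out = combine_paired(t, design)
        assert out.counts.sum() == t.counts.sum()
        for i in range(n_pairs):
            rich = otu_richness(out.column(f"P{i}"))
            assert rich >= otu_richness(t.column(f"P{i}-I"))
            assert rich >= otu_richness(t.column(f"P{i}-D"))


class TestPresenceAbsence:
    def test_binarization(self):
        t = CountTable(["A", "B", "C"], ["S1"], np.array([[0], [1], [37]]))
        out = presence_absence(t)
        assert np.array_equal(out.counts[:, 0], [0, 1, 1])

    def test_idempotent(self, rng):
        t = random_table(rng)
        once = presence_absence(t)
        assert presence_absence(once) == once

    def test_column_sums_equal_richness(self, rng):
        t = random_table(rng, n_otus=10, n_samples=5)
        pa = presence_absence(t)
        for s in t.sample_ids:
            assert pa.column(s).sum() == otu_richness(t.column(s))

    def test_union_property_after_combining(self, rng):
        sample_ids = ["P0-I", "P0-D"]
        t = CountTable([f"O{i}" for i in range(6)], sample_ids, rng.integers(0, 3, (6, 2)))
        design = PairedDesign({"P0": ("P0-I", "P0-D")})
        comb_pa = presence_absence(combine_paired(t, design))
        member_pa = presence_absence(t)
        assert comb_pa.counts[:, 0].sum() >= member_pa.counts[:, 0].sum()
        assert comb_pa.counts[:, 0].sum() >= member_pa.counts[:, 1].sum()
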