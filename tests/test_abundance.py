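"""Abundance-table I/O, normalization and per-taxon feature rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from micronet import abundance as ab
from conftest import make_table


class TestReadWrite:
    def test_roundtrip_small_tsv(self, tmp_path):
        table = make_table([[1, 2], [3, 4], [5, 6]])
        ab.write_abundance_table(table, tmp_path / "t.tsv")
        meta = {"C1": ("C", 1), "C2": ("C", 2)}
        back = ab.read_abundance_table(tmp_path / "t.tsv", meta)
        assert back.values.shape == (3, 2)
        assert np.allclose(back.values.to_numpy(), table.values.to_numpy())

    def test_negative_value_names_the_cell(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("taxon\tC1\nA\t5\nB\t-2\n")
        with pytest.raises(ab.AbundanceTableError, match="'B'.*'C1'"):
            ab.read_abundance_table(tmp_path / "bad.tsv", {"C1": ("C", 1)})

    def test_missing_metadata_column_rejected(self, tmp_path):
        (tmp_path / "t.tsv").write_text("taxon\tC1\tC2\nA\t1\t2\n")
        with pytest.raises(ab.AbundanceTableError, match="C2"):
            ab.read_abundance_table(tmp_path / "t.tsv", {"C1": ("C", 1)})

    def test_duplicate_taxon_rejected(self):
        vals = pd.DataFrame([[1.0], [2.0]], index=["A", "A"], columns=["C1"])
        meta = pd.DataFrame({"condition": ["C"], "date_index": [1]}, index=["C1"])
        with pytest.raises(ab.AbundanceTableError, match="duplicate taxon"):
            ab.AbundanceTable(vals, meta, "counts")

    def test_study_shaped_table_accepted(self, tmp_path):
        # the real dataset's shape: 113 families x 14 samples
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 2000, size=(113, 14)).astype(float)
        taxa = [f"F{i:03d}" for i in range(113)]
        cols = [f"S{i}" for i in range(14)]
        pd.DataFrame(vals, index=taxa, columns=cols).to_csv(
            tmp_path / "big.tsv", sep="\t", index_label="taxon"
        )
        meta = {
            c: ("C" if i < 7 else "B", (i % 7) + 1) for i, c in enumerate(cols)
        }
        table = ab.read_abundance_table(tmp_path / "big.tsv", meta)
        assert table.n_taxa == 113 and table.n_samples == 14


class TestNormalizeCounts:
    def test_samples_rescaled_to_minimum_depth(self):
        table = make_table([[500, 1000, 2000], [500, 1000, 2000]])
        out, discarded = ab.normalize_counts(table)
        # depths 1000/2000/4000 -> scale factors 1, 1/2, 1/4
        assert np.allclose(out.values.to_numpy(), [[500, 500, 500]] * 2)
        assert discarded == []

    def test_taxon_below_one_everywhere_discarded(self):
        table = make_table([[1000, 2000], [0.7, 1.4], [2, 1]])
        out, discarded = ab.normalize_counts(table)
        # after rescaling to depth ~1002.7 the middle taxon is < 1 in both
        assert discarded == ["T1"]
        assert list(out.values.index) == ["T0", "T2"]

    def test_taxon_passing_in_one_sample_retained(self):
        table = make_table([[100, 100], [0.5, 1.2]])
        out, discarded = ab.normalize_counts(table)
        assert "T1" in out.taxa and discarded == []

    def test_zero_depth_sample_rejected(self):
        table = make_table([[1, 0], [2, 0]])
        with pytest.raises(ab.AbundanceTableError, match="zero depth"):
            ab.normalize_counts(table)

    def test_scaling_invariance_of_relative_abundance(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(5, 500, size=(6, 4)).astype(float)
        table = make_table(vals)
        direct = ab.to_relative(table)
        via_norm = ab.to_relative(ab.normalize_counts(table)[0])
        assert np.allclose(direct.values.to_numpy(), via_norm.values.to_numpy())


class TestToRelative:
    def test_simple_column(self):
        out = ab.to_relative(make_table([[1], [1], [2]]))
        assert np.allclose(out.values.to_numpy().ravel(), [25, 25, 50])

    def test_idempotent(self):
        rel = ab.to_relative(make_table([[3, 1], [7, 9]]))
        again = ab.to_relative(rel)
        assert np.allclose(rel.values.to_numpy(), again.values.to_numpy(), atol=1e-9)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ab.AbundanceTableError, match="all-zero"):
            ab.to_relative(make_table([[1, 0], [1, 0]]))

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(
            float, (5, 3),
            elements=st.floats(0.01, 1e4, allow_nan=False),
        )
    )
    def test_columns_sum_to_100(self, vals):
        out = ab.to_relative(make_table(vals))
        assert np.allclose(out.values.sum(axis=0), 100.0, atol=1e-6)


class TestMeanNonzero:
    @pytest.mark.parametrize(
        "profile,expected",
        [((2, 0, 4), 3.0), ((5, 5, 5), 5.0), ((0, 0, 0), 0.0)],
    )
    def test_presence_mean(self, profile, expected):
        assert ab.mean_nonzero(profile) == expected


class TestClassifyLevel:
    @pytest.mark.parametrize(
        "mean,profile,expected",
        [
            (1.5, (1, 2, 1.5), ("H", True, False)),
            (0.05, (0.1, 0, 0.05), ("R", False, True)),
            (0.1, (0.1, 0.1), ("L", True, False)),
            (1.0, (1, 1), ("L", True, False)),
            (0.05, (0.05, 0.05), ("R", True, False)),
        ],
    )
    def test_rules(self, mean, profile, expected):
        assert ab.classify_level(mean, profile) == expected

    def test_every_taxon_gets_exactly_one_level(self):
        rng = np.random.default_rng(7)
        for mean in rng.uniform(0, 3, 200):
            level, _, _ = ab.classify_level(mean, (mean,))
            assert level in {"H", "L", "R"}


class TestDiversity:
    def test_uniform_four_taxa(self):
        sh, inv, _ = ab.diversity_indices([25, 25, 25, 25])
        assert sh == pytest.approx(np.log(4))
        assert inv == pytest.approx(4.0)

    def test_single_taxon(self):
        sh, inv, _ = ab.diversity_indices([100])
        assert sh == 0.0 and inv == pytest.approx(1.0)

    def test_chao1_closed_form(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 16/4 = 14
        counts = [1, 1, 1, 1, 2, 2, 3, 5, 9, 11]
        _, _, chao = ab.diversity_indices(counts, counts)
        assert chao == pytest.approx(14.0)

    def test_chao1_no_doubleton_fallback(self):
        counts = [1, 1, 1, 4, 5]
        _, _, chao = ab.diversity_indices(counts, counts)
        assert chao == pytest.approx(5 + 3 * 2 / 2)

    def test_against_scikit_bio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = np.array([5, 1, 12, 2, 1, 30, 2, 7])
        sh, inv, chao = ab.diversity_indices(counts, counts)
        assert sh == pytest.approx(skbio_alpha.shannon(counts, base=np.e))
        assert inv == pytest.approx(skbio_alpha.enspie(counts))
        assert chao == pytest.approx(skbio_alpha.chao1(counts, bias_corrected=False))


class TestPairedDiffTest:
    def test_clear_increase_is_diff_up(self):
        c = np.array([1, 2, 3, 4, 5, 6, 7], dtype=float)
        b = c + 2.0 + np.array([0.01, -0.02, 0.03, -0.01, 0.02, -0.03, 0.01])
        status, p = ab.paired_diff_test(c, b)
        assert status == "Diff_UP" and p < 0.05

    def test_identical_vectors(self):
        status, p = ab.paired_diff_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0 and status == "NDiff_DN"

    def test_matches_closed_form_t(self):
        c = np.arange(1.0, 8.0)
        b = c + np.array([1, 1, 1, 1, 1, 1, 1.5])
        d = b - c
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(7))
        from scipy import stats

        p_expected = 2 * stats.t.sf(abs(t_stat), 6)
        status, p = ab.paired_diff_test(c, b)
        assert p == pytest.approx(p_expected, rel=1e-12)
        assert status == ("Diff_UP" if p < 0.05 else "NDiff_UP")

    def test_direction_antisymmetry(self):
        rng = np.random.default_rng(11)
        c = rng.uniform(0, 5, 7)
        b = c + rng.normal(0.5, 0.2, 7)
        s1, p1 = ab.paired_diff_test(c, b)
        s2, p2 = ab.paired_diff_test(b, c)
        assert p1 == pytest.approx(p2)
        flip = {"Diff_UP": "Diff_DN", "Diff_DN": "Diff_UP",
                "NDiff_UP": "NDiff_DN", "NDiff_DN": "NDiff_UP"}
        assert s2 == flip[s1]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ab.paired_diff_test([1, 2], [1, 2, 3])


class TestPresencePartition:
    def test_disjoint_toy_sets(self):
        c = make_table([[1, 1], [0, 0]], "C")
        b = make_table([[0, 0], [2, 2]], "B")
        shared, c_only, b_only = ab.presence_partition(c, b)
        assert shared == set() and c_only == {"T0"} and b_only == {"T1"}

    def test_sizes_partition_the_present_taxa(self):
        rng = np.random.default_rng(5)
        vals_c = rng.integers(0, 2, size=(20, 4)).astype(float)
        vals_b = rng.integers(0, 2, size=(20, 4)).astype(float)
        c, b = make_table(vals_c, "C"), make_table(vals_b, "B")
        shared, c_only, b_only = ab.presence_partition(c, b)
        present = {
            t for t in c.taxa
            if (c.profile(t) > 0).any() or (b.profile(t) > 0).any()
        }
        assert shared | c_only | b_only == present
        assert not (shared & c_only or shared & b_only or c_only & b_only)


class TestAnnotate:
    def test_annotation_frame_is_consistent(self, paired_tables):
        c, b = paired_tables
        rel_c, rel_b = ab.to_relative(c), ab.to_relative(b)
        ann = ab.annotate_taxa(rel_c, rel_b)
        assert set(ann.index) == set(c.taxa)
        assert ann["level"].isin(["H", "L", "R"]).all()
        # nR implies rare and not core
        flagged = ann[ann["nR"]]
        assert ((flagged["level"] == "R") & ~flagged["core"]).all()
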