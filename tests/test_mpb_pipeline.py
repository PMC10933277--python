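import numpy as np
import pandas as pd
import pytest

from bloomclone.mpb_pipeline import (
    AmpliconTable,
    LocusSpec,
    build_amplicon_table,
    call_alleles,
    filter_singletons,
    flank_typing,
    longest_repeat_run,
    merge_replicates,
    normalize_and_filter,
    read_counts_tsv,
    repeat_filter,
    run_locus_pipeline,
)

SPEC = LocusSpec(name="PNm1", motif="AC", abundance_threshold_pct=0.65)

F5 = "GGTTCCAAGGTTCA"  # 14 nt
F3 = "TTGGAACCTTGGAA"


def seq(units, f5=F5, f3=F3, motif="AC"):
    return f5 + motif * units + f3


class TestBuildAmpliconTable:
    def test_exact_counts(self):
        table = build_amplicon_table(
            {"s1": {"AAAA": 5, "CCCC": 2}, "s2": {"AAAA": 1, "GGGG": 3}}, SPEC
        )
        assert table.counts.loc["AAAA", "s1"] == 5
        assert table.counts.loc["GGGG", "s1"] == 0
        assert table.counts.shape == (3, 2)

    def test_duplicate_sequence_in_sample_summed(self):
        # dict input cannot repeat keys; use case-variant spellings that fold
        table = build_amplicon_table({"s1": {"acgt": 5, "ACGT": 7}}, SPEC)
        assert table.counts.loc["ACGT", "s1"] == 12

    def test_no_input_errors(self):
        with pytest.raises(ValueError):
            build_amplicon_table({}, SPEC)

    def test_empty_sample_warns_zero_column(self):
        with pytest.warns(UserWarning, match="no sequences"):
            table = build_amplicon_table({"s1": {"AAAA": 1}, "s2": {}}, SPEC)
        assert (table.counts["s2"] == 0).all()

    def test_fasta_size_annotations(self, tmp_path):
        fa = tmp_path / "s1.fasta"
        fa.write_text(">a;size=11\nACGTACGT\n>b;size=4\nTTTTTTTT\n>c\nACGTACGT\n")
        table = build_amplicon_table({"s1": fa}, SPEC)
        assert table.counts.loc["ACGTACGT", "s1"] == 12
        assert table.counts.loc["TTTTTTTT", "s1"] == 4

    def test_tsv_reader(self, tmp_path):
        tsv = tmp_path / "locus.tsv"
        tsv.write_text("sequence\tsample\tcount\nAAAA\ts1\t5\nAAAA\ts1\t2\nCCCC\ts2\t3\n")
        table = read_counts_tsv(tsv, SPEC)
        assert table.counts.loc["AAAA", "s1"] == 7
        assert table.counts.loc["CCCC", "s2"] == 3


class TestFilterSingletons:
    def test_total_one_removed(self):
        table = build_amplicon_table({"s1": {"AAAA": 1, "CCCC": 5}}, SPEC)
        assert "AAAA" not in filter_singletons(table).counts.index

    def test_split_across_samples_retained(self):
        table = build_amplicon_table({"s1": {"AAAA": 1}, "s2": {"AAAA": 1}}, SPEC)
        assert "AAAA" in filter_singletons(table).counts.index

    def test_all_singletons_warns_empty(self):
        table = build_amplicon_table({"s1": {"AAAA": 1, "CCCC": 1}}, SPEC)
        with pytest.warns(UserWarning, match="singletons"):
            out = filter_singletons(table)
        assert len(out) == 0


class TestLongestRepeatRun:
    def test_basic(self):
        assert longest_repeat_run("TT" + "AC" * 3 + "GG", "AC") == (3, 2)

    def test_two_units_only(self):
        assert longest_repeat_run("TTACACGG", "AC")[0] == 2

    def test_interrupted_takes_longest(self):
        s = "AC" * 2 + "G" + "AC" * 5
        assert longest_repeat_run(s, "AC")[0] == 5

    def test_absent_motif(self):
        assert longest_repeat_run("GGGG", "AC") == (0, -1)

    def test_off_frame_run_found(self):
        assert longest_repeat_run("TAAAA", "AA")[0] == 2

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = "".join(rng.choice(list("ACGT"), size=30))
            motif = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            # oracle: max k over all substrings equal to motif * k
            best = 0
            for i in range(len(s)):
                k = 0
                while s[i : i + (k + 1) * len(motif)] == motif * (k + 1):
                    k += 1
                best = max(best, k)
            assert longest_repeat_run(s, motif)[0] == best


class TestRepeatFilter:
    def test_threshold_at_three_units(self):
        table = build_amplicon_table(
            {"s1": {seq(3): 5, seq(2): 5, "GGGGGG": 5}}, SPEC
        )
        out, info = repeat_filter(table, SPEC)
        assert list(out.counts.index) == [seq(3)]
        assert info.loc[seq(3), "repeat_units"] == 3

    def test_run_span_recorded(self):
        table = build_amplicon_table({"s1": {seq(4): 5}}, SPEC)
        _, info = repeat_filter(table, SPEC)
        row = info.loc[seq(4)]
        assert row["run_start"] == len(F5)
        assert row["run_end"] == len(F5) + 8


class TestCallAlleles:
    def _table(self, counts):
        table = build_amplicon_table({"s1": counts}, SPEC)
        return repeat_filter(table, SPEC)

    def test_homoplasy_naming_by_abundance(self):
        a = seq(5)
        b = seq(5, f5="GGTTCCAAGGTTGA")  # same length, different sequence
        table, info = self._table({a: 900, b: 100})
        calls, counts = call_alleles(table, SPEC, info)
        by_name = {c.allele_name: c for c in calls}
        length = len(a)
        assert by_name[f"{length}.1"].sequence == a
        assert by_name[f"{length}.2"].sequence == b

    def test_single_sequence_index_one(self):
        table, info = self._table({seq(4): 10})
        calls, _ = call_alleles(table, SPEC, info)
        assert calls[0].allele_name == f"{len(seq(4))}.1"

    def test_tie_break_deterministic_under_shuffle(self):
        variants = [seq(5), seq(5, f5="AATTCCAAGGTTCA"), seq(5, f5="CCTTCCAAGGTTCA")]
        rng = np.random.default_rng(1)
        names = []
        for _ in range(5):
            order = list(variants)
            rng.shuffle(order)
            table, info = self._table({s: 50 for s in order})
            calls, _ = call_alleles(table, SPEC, info)
            names.append([(c.allele_name, c.sequence) for c in sorted(calls, key=lambda c: c.allele_name)])
        assert all(n == names[0] for n in names)
        # lexicographically smallest sequence gets index 1 on ties
        assert names[0][0][1] == sorted(variants)[0]


class TestNormalizeAndFilter:
    def _allele_counts(self):
        return pd.DataFrame(
            {"s1": [800, 195, 5], "s2": [2400, 570, 30]},
            index=pd.Index(["100.1", "100.2", "102.1"], name="allele"),
        )

    def test_median_scaling(self):
        out = normalize_and_filter(self._allele_counts(), SPEC, min_depth=100)
        # totals 1000 and 3000 -> median 2000; scale factors 2.0 and 2/3
        assert out.normalized_counts["s1"].sum() == pytest.approx(2000)
        assert out.normalized_counts["s2"].sum() == pytest.approx(2000)
        assert out.normalized_counts.loc["100.1", "s1"] == pytest.approx(1600)

    def test_column_sums_100_before_threshold(self):
        spec = LocusSpec(name="PNm1", motif="AC", abundance_threshold_pct=0.0)
        out = normalize_and_filter(self._allele_counts(), spec, min_depth=100)
        assert out.percentages.sum().tolist() == pytest.approx([100.0, 100.0], abs=1e-6)

    def test_threshold_zeroes_per_sample(self):
        out = normalize_and_filter(self._allele_counts(), SPEC, min_depth=100)
        # allele 102.1 sits at 0.5% in s1 (< 0.65%) but 1.0% in s2
        assert out.percentages.loc["102.1", "s1"] == 0.0
        assert out.percentages.loc["102.1", "s2"] == pytest.approx(1.0)

    def test_global_threshold_removes_rows(self):
        counts = self._allele_counts()
        counts.loc["102.1"] = [5, 15]  # below threshold in every sample
        out = normalize_and_filter(counts, SPEC, min_depth=100, global_threshold=True)
        assert "102.1" not in out.percentages.index

    def test_low_depth_sample_excluded(self):
        counts = self._allele_counts()
        counts["shallow"] = [50, 10, 2]
        out = normalize_and_filter(counts, SPEC, min_depth=1000)
        assert out.excluded_samples == ["shallow"]
        assert "shallow" not in out.percentages.columns

    def test_all_samples_shallow_errors(self):
        with pytest.raises(ValueError, match="minimum depth"):
            normalize_and_filter(self._allele_counts(), SPEC, min_depth=10_000)

    def test_scaling_preserves_relative_frequencies(self):
        counts = self._allele_counts()
        spec = LocusSpec(name="PNm1", motif="AC", abundance_threshold_pct=0.0)
        out = normalize_and_filter(counts, spec, min_depth=100)
        for sample in counts.columns:
            raw = counts[sample] / counts[sample].sum()
            assert out.percentages[sample].to_numpy() / 100 == pytest.approx(
                raw.to_numpy(), abs=1e-12
            )


class TestMergeReplicates:
    def _freq(self):
        counts = pd.DataFrame(
            {"r1": [600, 400], "r2": [800, 200], "x1": [500, 500]},
            index=pd.Index(["100.1", "102.1"], name="allele"),
        )
        spec = LocusSpec(name="PNm1", motif="AC")
        return normalize_and_filter(counts, spec, min_depth=100)

    def test_average_of_replicates(self):
        merged = merge_replicates(self._freq(), {"r1": "d1", "r2": "d1", "x1": "d2"})
        assert merged.percentages.loc["100.1", "d1"] == pytest.approx(70.0)
        assert merged.percentages.loc["100.1", "d2"] == pytest.approx(50.0)

    def test_mean_includes_zeros(self):
        counts = pd.DataFrame(
            {"r1": [920, 80], "r2": [1000, 0]},
            index=pd.Index(["100.1", "102.1"], name="allele"),
        )
        spec = LocusSpec(name="PNm1", motif="AC")
        freq = normalize_and_filter(counts, spec, min_depth=100)
        merged = merge_replicates(freq, {"r1": "d1", "r2": "d1"})
        assert merged.percentages.loc["102.1", "d1"] == pytest.approx(4.0)

    def test_unmapped_sample_errors(self):
        with pytest.raises(ValueError, match="x1"):
            merge_replicates(self._freq(), {"r1": "d1", "r2": "d1"})


class TestFlankTyping:
    F5A = "GGTTCCAAGGTTCA"
    F5B = "GGTTCCAAGGTAGA"
    F3A = "TTGGAACCTTGGAA"
    F3B = "TTGGAACCTTCCAA"

    def _calls(self, spec_counts):
        table = build_amplicon_table({"s1": spec_counts}, SPEC)
        filtered, info = repeat_filter(table, SPEC)
        calls, _ = call_alleles(filtered, SPEC, info)
        return flank_typing(calls, SPEC)

    def test_uniform_flanks_no_recombinants(self):
        calls = self._calls({seq(u): 100 for u in (3, 4, 5)})
        assert {c.flank5_type for c in calls} == {"5A"}
        assert {c.flank3_type for c in calls} == {"3A"}
        assert not any(c.recombinant for c in calls)

    def test_planted_recombinant_flagged(self):
        counts = {
            seq(3, f5=self.F5A, f3=self.F3A): 800,
            seq(4, f5=self.F5B, f3=self.F3B): 150,
            seq(5, f5=self.F5A, f3=self.F3B): 50,  # recombinant combination
        }
        calls = self._calls(counts)
        by_units = {c.repeat_units: c for c in calls}
        assert by_units[3].recombinant is False
        assert by_units[4].recombinant is False
        assert by_units[5].recombinant is True
        assert by_units[5].flank5_type == "5A"
        assert by_units[5].flank3_type == "3B"

    def test_short_flank_undefined_no_recombinants(self):
        # 3' flank shorter than the 10 nt minimum -> 3' typing undefined
        counts = {
            seq(3, f3="TTGG"): 800,
            seq(4, f5=self.F5B, f3="TTGG"): 150,
            seq(5, f3="TTGG"): 50,
        }
        with pytest.warns(UserWarning, match="3' flanks too short"):
            calls = self._calls(counts)
        assert all(c.flank3_type is None for c in calls)
        assert not any(c.recombinant for c in calls)


class TestPipelineReport:
    def test_stage_order_and_percentages(self):
        counts = {
            seq(5): 5000,
            seq(4): 3000,
            seq(2): 100,  # fails repeat filter
        }
        table = build_amplicon_table(
            {"s1": {**counts, "G" * 40: 1}, "s2": counts}, SPEC  # dataset-wide singleton
        )
        result = run_locus_pipeline(table, SPEC, min_depth=100)
        report = result["report"].to_frame()
        assert report["stage"].tolist() == [
            "input",
            "singleton_filter",
            "repeat_filter",
            "depth_and_abundance_filter",
        ]
        assert (report["reads"].diff().dropna() <= 0).all()
        assert report["pct_removed"].iloc[1] > 0
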