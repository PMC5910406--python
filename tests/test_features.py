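"""Categorical locus features: the CI-binning rule, every per-locus
statistic, mutant-dependency calls and annotation overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srnaloc import features as ft
from srnaloc.features import (
    CategoricalBinSpec,
    IntervalEstimate,
    annotate_loci,
    bin_by_confidence_interval,
    dcl_dependency,
    differential_dependency,
    five_prime_preference,
    h3_category,
    histone_mark_category,
    interval_overlap,
    methylation_category,
    phasing_category,
    phasing_pvalue,
    poisson_rate_interval,
    promoters_from_genes,
    ratio_21_24,
    repetitiveness,
    strand_ratio,
    tissue_specificity,
    width_category,
    wilson_interval,
)
from conftest import make_reads


def brute_force_bin(lower: float, upper: float, spec: CategoricalBinSpec) -> str:
    """Independent enumeration of the three-way rule: partitions are the
    intervals (-inf,t0], (t0,t1], ...; a threshold t is crossed when
    lower <= t < upper."""
    import bisect

    def part(v):
        return bisect.bisect_left(list(spec.thresholds), v)

    crossed = [t for t in spec.thresholds if lower <= t < upper]
    if not crossed:
        return spec.labels[part(lower)]
    if len(crossed) == 1:
        d = list(spec.labels).index(spec.default_label)
        lo, hi = part(lower), part(upper)
        return spec.labels[lo] if abs(lo - d) < abs(hi - d) else spec.labels[hi]
    return spec.unknown_label


class TestBinByConfidenceInterval:
    spec2 = CategoricalBinSpec([0.5], ["low", "high"], "low")
    spec3 = CategoricalBinSpec([0.33, 0.66], ["low", "mid", "high"], "low")

    def test_inside_one_partition(self):
        est = IntervalEstimate(0.15, 0.10, 0.20)
        assert bin_by_confidence_interval(est, self.spec2) == "low"

    def test_single_crossing_resolves_to_default_side(self):
        est = IntervalEstimate(0.5, 0.40, 0.60)
        assert bin_by_confidence_interval(est, self.spec2) == "low"

    def test_double_crossing_is_unknown(self):
        est = IntervalEstimate(0.5, 0.10, 0.90)
        assert bin_by_confidence_interval(est, self.spec3) == "unknown"

    def test_degenerate_interval_is_a_point(self):
        est = IntervalEstimate(0.33, 0.33, 0.33)
        assert bin_by_confidence_interval(est, self.spec3) == "low"

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        labels = ["a", "b", "c", "d"]
        for _ in range(2000):
            k = int(rng.integers(1, 4))
            thresholds = sorted(rng.choice(np.round(rng.random(10), 3), k, replace=False))
            if len(set(thresholds)) != k:
                continue
            spec = CategoricalBinSpec(thresholds, labels[: k + 1],
                                      labels[int(rng.integers(0, k + 1))])
            lo, hi = sorted(rng.random(2))
            est = IntervalEstimate(point=(lo + hi) / 2, lower=lo, upper=hi)
            assert bin_by_confidence_interval(est, spec) == brute_force_bin(lo, hi, spec)


class TestWidthCategory:
    @pytest.mark.parametrize(
        "width,expected",
        [(50, "(0,50]"), (51, "(50,2000]"), (132, "(50,2000]"),
         (2000, "(50,2000]"), (2001, "(2000,Inf]")],
    )
    def test_bin_boundaries(self, width, expected):
        assert width_category({"start": 1, "end": width}) == expected


class TestRatio2124:
    spec = CategoricalBinSpec([0.2, 0.8], ["low", "moderate", "high"], "low")

    def test_pure_21mers_are_high(self):
        lengths = np.full(100, 21)
        counts = np.ones(100)
        assert ratio_21_24(lengths, counts, self.spec) == "high"

    def test_no_eligible_reads_unknown(self):
        assert ratio_21_24(np.array([30]), np.array([5]), self.spec) == "unknown"

    def test_small_sample_resolved_by_ci_rule(self):
        # 2 reads of 21 nt vs 2 of 24 nt: label must equal the CI rule's
        # verdict computed independently from the Wilson interval
        ci = wilson_interval(2.0, 4.0)
        expected = brute_force_bin(ci.lower, ci.upper, self.spec)
        got = ratio_21_24(np.array([21, 21, 24, 24]), np.ones(4), self.spec)
        assert got == expected

    def test_scaling_counts_never_moves_label_past_point_bin(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n21 = int(rng.integers(0, 20))
            n24 = int(rng.integers(0, 20))
            if n21 + n24 == 0:
                continue
            lengths = np.array([21] * n21 + [24] * n24)
            base = ratio_21_24(lengths, np.ones(n21 + n24), self.spec)
            scaled = ratio_21_24(lengths, np.full(n21 + n24, 10.0), self.spec)
            point_bin = self.spec.labels[self.spec.partition(n21 / (n21 + n24))]
            order = {lbl: i for i, lbl in enumerate(self.spec.labels)}
            if base in order and scaled in order:
                assert abs(order[scaled] - order[point_bin]) <= abs(order[base] - order[point_bin])
            else:
                assert base == "unknown"  # only the unscaled may be unknown


class TestStrandRatio:
    spec = ft.DEFAULT_BIN_SPECS["strand_ratio"]

    def test_all_plus_is_strong(self):
        strands = np.array(["+"] * 100)
        assert strand_ratio(strands, np.ones(100), self.spec) == "strong"

    def test_balanced_deep_is_no_bias(self):
        strands = np.array(["+"] * 500 + ["-"] * 500)
        assert strand_ratio(strands, np.ones(1000), self.spec) == "no"

    def test_three_plus_reads_wide_interval(self):
        ci = wilson_interval(3.0, 3.0)
        expected = brute_force_bin(ci.lower, ci.upper, self.spec)
        assert strand_ratio(np.array(["+"] * 3), np.ones(3), self.spec) == expected
        assert expected in ("medium", "unknown")

    def test_zero_reads_unknown(self):
        assert strand_ratio(np.array([]), np.array([]), self.spec) == "unknown"


class TestRepetitiveness:
    def test_all_unique_reads_give_zero(self):
        est, _ = repetitiveness(np.array([5.0, 3.0]), np.array([1.0, 1.0]))
        assert est.point == pytest.approx(0.0, abs=1e-12)

    def test_single_sequence_two_hits(self):
        est, _ = repetitiveness(np.array([10.0]), np.array([2.0]))
        assert est.point == pytest.approx(0.5, abs=1e-12)

    def test_mixed_hand_example(self):
        est, _ = repetitiveness(np.array([4.0, 6.0]), np.array([1.0, 3.0]))
        assert est.point == pytest.approx(0.4, abs=1e-12)

    def test_no_reads_unknown(self):
        est, lab = repetitiveness(np.array([]), np.array([]))
        assert est is None and lab == "unknown"


class TestTissue:
    @pytest.mark.parametrize(
        "n,expected",
        [(10, "common"), (12, "common"), (9, "intermediate"), (5, "intermediate"),
         (2, "intermediate"), (1, "specific"), (0, "specific")],
    )
    def test_quoted_thresholds(self, n, expected):
        assert tissue_specificity(n) == expected


class TestPhasing:
    def test_perfect_register_significant(self):
        pos = np.array([1, 22, 43, 64])  # relative 0, 21, 42, 63
        p = phasing_pvalue({"start": 1, "end": 84}, pos, pos + 20,
                           np.array(["+"] * 4))
        assert p < 0.05

    def test_uniform_null_rarely_significant(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(300):
            n = int(rng.integers(5, 30))
            pos = rng.integers(1, 200, size=n)
            p = phasing_pvalue({"start": 1, "end": 220}, pos, pos + 20,
                               np.array(["+"] * n))
            hits += p < 0.05
        assert hits / 300 <= 0.07

    def test_short_locus_never_significant(self):
        pos = np.array([1, 22])
        assert phasing_pvalue({"start": 1, "end": 50}, pos, pos + 20,
                              np.array(["+"] * 2)) == 1.0

    def test_category_thresholds(self):
        assert phasing_category([0.01] * 6) == "high"
        assert phasing_category([0.01, 0.5, 0.5]) == "moderate"
        assert phasing_category([0.5, 0.9]) == "none"


class TestFivePrime:
    bg = {"A": 0.51, "C": 0.09, "G": 0.17, "T": 0.22}

    def test_strong_c_enrichment_called(self):
        bc = pd.DataFrame([[0, 100, 0, 0]], columns=list("ACGT"))
        calls = five_prime_preference(bc, self.bg)
        assert calls.iloc[0].tolist() == [False, True, False, False]

    def test_background_composition_not_called(self):
        bc = pd.DataFrame([[51, 9, 17, 22]], columns=list("ACGT"))
        assert not five_prime_preference(bc, self.bg).iloc[0].any()

    def test_three_reads_of_majority_base_not_significant(self):
        # raw p = 0.51^3 = 0.133; survives no BH correction
        bc = pd.DataFrame([[3, 0, 0, 0]], columns=list("ACGT"))
        assert not five_prime_preference(bc, self.bg).iloc[0].any()

    def test_zero_reads_empty(self):
        bc = pd.DataFrame([[0, 0, 0, 0]], columns=list("ACGT"))
        assert not five_prime_preference(bc, self.bg).iloc[0].any()


class TestMethylationCategory:
    spec = CategoricalBinSpec([0.3, 0.7], ["low", "moderate", "high"], "low")

    def test_degenerate_all_ones_high(self):
        rng = np.random.default_rng(0)
        assert methylation_category(np.ones(10), self.spec, rng) == "high"

    def test_no_cytosines_unknown(self):
        rng = np.random.default_rng(0)
        assert methylation_category(np.array([]), self.spec, rng) == "unknown"

    def test_beta_eight_two_sample_binned_high(self):
        # 50 cytosines ~ Beta(8,2): mean 0.8, bootstrap CI comfortably
        # above 0.7 for the vast majority of draws
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.beta(8, 2, size=50)
            hits += methylation_category(vals, self.spec, rng) == "high"
        assert hits >= 18

    def test_bootstrap_ci_matches_direct_percentiles(self):
        vals = np.random.default_rng(3).beta(2, 2, size=30)
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        lab1 = methylation_category(vals, self.spec, rng1, n_boot=500)
        idx = rng2.integers(0, 30, size=(500, 30))
        lo, hi = np.percentile(vals[idx].mean(axis=1), [2.5, 97.5])
        expected = brute_force_bin(lo, hi, self.spec)
        assert lab1 == expected


class TestH3:
    spec = CategoricalBinSpec([0.02, 0.1, 0.3], ["none", "low", "moderate", "high"], "none")

    def test_zero_reads_is_none(self):
        assert h3_category(0, 1000.0, self.spec) == "none"

    def test_exact_poisson_interval_values(self):
        est = poisson_rate_interval(100, 100.0)
        assert est.point == pytest.approx(1.0)
        # Garwood (chi-square) bounds: chi2.ppf(.025, 200)/2 and
        # chi2.ppf(.975, 202)/2, scaled by width 100
        assert est.lower == pytest.approx(0.81364, abs=1e-4)
        assert est.upper == pytest.approx(1.21627, abs=1e-4)
        assert h3_category(100, 100.0, self.spec) == "high"

    def test_rate_invariant_to_joint_scaling(self):
        assert h3_category(200, 200.0, self.spec) == h3_category(100, 100.0, self.spec)


class TestHistoneMark:
    spec = CategoricalBinSpec([0.25, 0.75], ["low", "moderate", "high"], "low")

    def test_mark_only_high(self):
        assert histone_mark_category(50, 0, self.spec) == "high"

    def test_h3_only_low(self):
        assert histone_mark_category(0, 50, self.spec) == "low"

    def test_one_read_each_unknown(self):
        assert histone_mark_category(1, 1, self.spec) == "unknown"

    def test_no_reads_unknown(self):
        assert histone_mark_category(0, 0, self.spec) == "unknown"


def _dependency_dataset(seed, n_dep=100, n_ind=100, wt_mean=100.0, reps=5):
    rng = np.random.default_rng(seed)
    libs = pd.DataFrame({
        "library_id": [f"wt{i}" for i in range(reps)] + [f"mut{i}" for i in range(reps)],
        "replicate_group": ["wt"] * reps + ["mut"] * reps,
        "genotype": ["WT"] * reps + ["nrpd1"] * reps,
        "is_wild_type": [True] * reps + [False] * reps,
    })
    rows, loci, pos, size = [], [], 1, 5.0
    for i in range(n_dep + n_ind):
        loci.append({"locus_id": f"L{i:04d}", "chrom": "chr1", "start": pos, "end": pos + 199})
        for lib in libs["library_id"]:
            mean = 0.0 if (i < n_dep and lib.startswith("mut")) else wt_mean
            if mean > 0:
                tot = int(rng.negative_binomial(size, size / (size + mean)))
                if tot > 0:
                    rows.append(("ACGTACGTACGTACGTACGTA", "chr1", pos, pos + 20, "+",
                                 tot, 1, lib))
        pos += 300
    reads = make_reads(rows)
    return pd.DataFrame(loci), reads, libs


class TestDependency:
    def test_planted_loss_called_dependent(self):
        loci, reads, libs = _dependency_dataset(1)
        lab = differential_dependency(loci, reads, libs, "nrpd1",
                                      {l: 1000.0 for l in libs["library_id"]})
        assert (lab[:100] == "dependent").mean() >= 0.95
        assert (lab[100:] != "dependent").mean() >= 0.95

    def test_single_read_locus_unknown(self):
        libs = pd.DataFrame({
            "library_id": ["wt0", "mut0"], "replicate_group": ["wt", "mut"],
            "genotype": ["WT", "nrpd1"], "is_wild_type": [True, False],
        })
        loci = pd.DataFrame({"locus_id": ["L0"], "chrom": ["chr1"],
                             "start": [1], "end": [200]})
        reads = make_reads([("ACGTACGTACGTACGTACGTA", "chr1", 1, 21, "+", 1, 1, "wt0")])
        lab = differential_dependency(loci, reads, libs, "nrpd1",
                                      {"wt0": 1000.0, "mut0": 1000.0})
        assert lab.iloc[0] == "unknown"

    def test_missing_mutant_group_all_unknown(self):
        loci, reads, libs = _dependency_dataset(1, n_dep=5, n_ind=5)
        lab = differential_dependency(loci, reads, libs, "absent",
                                      {l: 1000.0 for l in libs["library_id"]})
        assert (lab == "unknown").all()

    def test_dcl_mode_expression_fdr(self):
        lik = pd.Series([1.0, 1.0, 0.8, 0.0, 0.0], index=list("abcde"))
        lab = dcl_dependency(lik, fdr=0.05)
        assert list(lab) == ["independent", "independent", "dependent",
                             "dependent", "dependent"]


class TestAnnotationOverlap:
    def test_single_base_overlap_counts(self):
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [300],
                              "strand": ["+"]})
        assert interval_overlap(loci, genes).iloc[0]

    def test_adjacent_does_not_count(self):
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [201], "end": [300],
                              "strand": ["+"]})
        assert not interval_overlap(loci, genes).iloc[0]

    def test_promoter_construction_strand_aware(self):
        genes = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [1000, 5000],
                              "end": [2000, 6000], "strand": ["+", "-"]})
        prom = promoters_from_genes(genes)
        assert prom.iloc[0][["start", "end"]].tolist() == [500, 999]
        assert prom.iloc[1][["start", "end"]].tolist() == [6001, 6500]
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [600], "end": [650]})
        assert interval_overlap(loci, prom).iloc[0]


def test_feature_table_is_complete(study_run):
    import srnaloc.ioutils as io

    ft_table = io.read_feature_table(study_run["run_dir"] / "features.tsv")
    assert not ft_table.isna().any().any()
    # every locus has every feature; unknown is a value, not a hole
    assert ft_table.shape[0] > 0
    for col in ("width", "tissue", "ratio_21_24", "strand_ratio",
                "repetitiveness", "phasing", "CpG", "CHG", "CHH", "H3"):
        assert col in ft_table.columns


def test_planted_21mer_signature_recovered(study_run):
    """Loci simulated with ~95% 21-22 nt reads must be labelled 21/24
    'high' in at least 90% of cases at the study depth."""
    import srnaloc.ioutils as io
    from conftest import match_loci_to_truth

    run_dir = study_run["run_dir"]
    ft_table = io.read_feature_table(run_dir / "features.tsv")
    loci = io.read_loci_bed(run_dir / "loci.bed")
    truth = study_run["truth"]
    gene21 = truth[truth["class_name"] == "gene21"]
    labels = []
    for _, t in gene21.iterrows():
        sub = loci[(loci["chrom"] == t["chrom"]) & (loci["start"] <= t["end"])
                   & (loci["end"] >= t["start"])]
        if len(sub):
            labels.append(ft_table.loc[sub.iloc[0]["locus_id"], "ratio_21_24"])
    labels = pd.Series(labels)
    assert len(labels) >= 0.9 * len(gene21)
    assert (labels == "high").mean() >= 0.9
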