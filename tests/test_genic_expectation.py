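"""Functional classification, expectations, burden test and constraint."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import exact_poisson_binomial_pmf
from patmut import genic_expectation as gx
from patmut.dna import complement, revcomp
from patmut.genic_expectation import (
    CATEGORIES,
    LOF_CATEGORIES,
    SnvRateLookup,
    burden_pvalue,
    calibrate_ngen,
    classify_snv,
    constraint_scores,
    coverage_correct,
    expected_counts,
    generation_scale,
    observed_counts,
    sample_poisson_binomial,
)
from patmut.sequence_io import MutationRecord, ReferenceGenome, TranscriptModel
from patmut.simulate import simulate_transcriptome


def _toy_gene(strand="+"):
    """A 2-exon toy transcript with known codons.

    CDS: ATG GCT TGG TAC TAA (Met Ala Trp Tyr Stop); exon1 = first 7 coding
    bases, exon2 = the rest, separated by a GT..AG intron.
    """
    cds = "ATGGCTTGGTACTAA"
    intron = "GTAAAACCCTTTAG"
    pre = cds[:7] + intron + cds[7:]
    pad5, pad3 = "AACCGGTTAA", "TTGGCCAATT"
    if strand == "+":
        seq = pad5 + pre + pad3
        iv = [(len(pad5), len(pad5) + 7),
              (len(pad5) + 7 + len(intron), len(pad5) + len(pre))]
    else:
        seq = pad5 + revcomp(pre) + pad3
        glen = len(pre)
        iv = sorted([(len(pad5) + glen - 7, len(pad5) + glen),
                     (len(pad5), len(pad5) + glen - 7 - len(intron))])
    genome = ReferenceGenome({"chr1": seq})
    t = TranscriptModel("TOY", "chr1", strand, iv).validate(genome)
    assert t.canonical
    return genome, t


def _uniform_snv_rates(rate=1e-3, k=3):
    arrays = {}
    from patmut.dna import position_digits

    central = position_digits(k, k // 2)
    for lab in ("A>C", "A>G", "A>T"):
        arrays[lab] = np.where(central == 0, rate, np.nan)
    for lab in ("C>A", "C>G", "C>T"):
        arrays[lab] = np.where(central == 1, rate, np.nan)
    return SnvRateLookup(k, arrays, 1.0, rate, 0)


class TestClassification:
    def test_known_codon_changes(self):
        genome, t = _toy_gene("+")
        s = t.cds_intervals[0][0]
        # GCT -> GCC (Ala->Ala): third base of codon 2 is coding index 5
        pos = s + 5
        assert classify_snv(t, genome, pos, "T", "C") == "synonymous"
        # TGG -> TGA (Trp -> stop): coding index 8 is in exon 2
        e2 = t.cds_intervals[1][0]
        pos = e2 + 1  # coding index 8
        assert classify_snv(t, genome, pos, "G", "A") == "nonsense"
        # any change in the start codon
        assert classify_snv(t, genome, s, "A", "G") == "start_disruption"
        # stop codon TAA -> TAC
        stop3 = e2 + (len(t.coding_positions()) - 7) - 1
        assert classify_snv(t, genome, stop3, "A", "C") == "stop_disruption"
        # stop -> stop is synonymous: TAA -> TAG
        assert classify_snv(t, genome, stop3, "A", "G") == "synonymous"

    def test_splice_sites_take_precedence(self):
        genome, t = _toy_gene("+")
        for pos in t.splice_site_positions():
            ref = genome.fetch("chr1", pos, pos + 1)
            alt = "A" if ref != "A" else "C"
            assert classify_snv(t, genome, pos, ref, alt) == "splice_disruption"
        assert len(t.splice_site_positions()) == 4

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_every_substitution_matches_translation_oracle(self, strand):
        """Brute-force oracle: apply each substitution to the full CDS,
        translate, and derive the category from the protein change."""
        genome, t = _toy_gene(strand)
        cds = t.coding_sequence(genome)
        coding_pos = t.coding_positions()
        stops = {"TAA", "TAG", "TGA"}

        def aa(codon):
            return gx.CODON_AA[codon]

        for i, p in enumerate(coding_pos):
            ref = genome.fetch("chr1", int(p), int(p) + 1)
            for alt in "ACGT":
                if alt == ref:
                    continue
                alt_c = complement(alt) if strand == "-" else alt
                mutated = cds[:i] + alt_c + cds[i + 1:]
                ci = i // 3
                if ci == 0:
                    expect = "start_disruption"
                elif ci == len(cds) // 3 - 1 and cds[-3:] in stops:
                    expect = ("synonymous" if mutated[-3:] in stops
                              else "stop_disruption")
                else:
                    ra, ma = aa(cds[3 * ci:3 * ci + 3]), aa(mutated[3 * ci:3 * ci + 3])
                    expect = ("nonsense" if ma == "*"
                              else "synonymous" if ma == ra else "missense")
                assert classify_snv(t, genome, int(p), ref, alt) == expect, \
                    f"pos {p} {ref}>{alt}"

    def test_position_outside_transcript_rejected(self):
        genome, t = _toy_gene("+")
        with pytest.raises(ValueError):
            classify_snv(t, genome, 0, genome.fetch("chr1", 0, 1), "T")


class TestExpectedCounts:
    def test_uniform_rates_make_expectations_proportional_to_site_counts(self):
        genome, t = _toy_gene("+")
        rates = _uniform_snv_rates(1e-3)
        cfg = gx.ScalingConfig(n_gen=1000.0)
        exp, table = expected_counts(t, genome, rates, None, cfg)
        sub = table.df
        frac_syn = (sub["category"] == "synonymous").mean()
        total = sum(exp.values())
        assert exp["synonymous"] / total == pytest.approx(frac_syn, rel=1e-12)

    def test_zero_generations_zero_expectations(self):
        genome, t = _toy_gene("+")
        rates = _uniform_snv_rates(1e-3)
        exp, _ = expected_counts(t, genome, rates, None, gx.ScalingConfig(n_gen=0.0))
        assert all(v == 0.0 for v in exp.values())

    def test_expectations_equal_independent_site_tally(self):
        """Hand tally: walk every coding/splice position, classify, look up
        the rate and sum generation-scaled probabilities per category."""
        genome, t = _toy_gene("-")
        rng = np.random.default_rng(3)
        from patmut.dna import position_digits

        central = position_digits(3, 1)
        arrays = {}
        for lab in ("A>C", "A>G", "A>T"):
            arrays[lab] = np.where(central == 0, rng.uniform(1e-4, 1e-3, 64), np.nan)
        for lab in ("C>A", "C>G", "C>T"):
            arrays[lab] = np.where(central == 1, rng.uniform(1e-4, 1e-3, 64), np.nan)
        rates = SnvRateLookup(3, arrays, 1.0, 0.0, 0)
        n_gen = 500.0
        exp, _ = expected_counts(t, genome, rates, None,
                                 gx.ScalingConfig(n_gen=n_gen))

        tally = {c: 0.0 for c in CATEGORIES}
        positions = sorted(set(int(p) for p in t.coding_positions())
                           | set(t.splice_site_positions()))
        for p in positions:
            window = genome.fetch("chr1", p - 1, p + 2)
            ref = window[1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                r = rates.site_alt_rate(window, alt)
                cat = classify_snv(t, genome, p, ref, alt)
                tally[cat] += 1 - (1 - r) ** (2 * n_gen)
        for cat in CATEGORIES:
            assert exp[cat] == pytest.approx(tally[cat], rel=1e-10), cat

    def test_category_additivity(self):
        genome, t = _toy_gene("+")
        rates = _uniform_snv_rates(2e-3)
        exp, table = expected_counts(t, genome, rates, None,
                                     gx.ScalingConfig(n_gen=100.0))
        snv_cats = [c for c in CATEGORIES if c not in
                    ("inframe_indel", "frameshift_indel")]
        total = generation_scale(table.df["r"].to_numpy(), 100.0).sum()
        assert sum(exp[c] for c in snv_cats) == pytest.approx(total, rel=1e-12)


class TestBurden:
    def test_observed_zero_has_pvalue_one(self):
        df = pd.DataFrame({"pos": [1], "kind": ["snv"], "ref": ["A"],
                           "alt": ["T"], "length": [0],
                           "category": ["missense"], "r": [1e-4]})
        st = gx.TranscriptSiteTable("T", df)
        res = burden_pvalue(st, "missense", 0, n_gen=100, n_samples=1000, seed=0)
        assert res.p_value == 1.0

    def test_equal_probabilities_reduce_to_binomial(self):
        n, p = 200, 0.05
        rng = np.random.default_rng(0)
        samples = sample_poisson_binomial(np.full(n, p), 100_000, rng)
        se_mean = math.sqrt(n * p * (1 - p) / 100_000)
        assert abs(samples.mean() - n * p) < 3 * se_mean
        var = n * p * (1 - p)
        # variance of the sample variance of a binomial, normal approximation
        se_var = math.sqrt(2 * var ** 2 / 100_000)
        assert abs(samples.var() - var) < 4 * se_var

    def test_tail_matches_exact_convolution(self):
        """20 heterogeneous sites: MC tail probability within 3 MC standard
        errors of the exact convolution oracle."""
        rng = np.random.default_rng(7)
        probs = rng.uniform(0.01, 0.4, 20)
        pmf = exact_poisson_binomial_pmf(probs)
        n_samples = 100_000
        samples = sample_poisson_binomial(probs, n_samples,
                                          np.random.default_rng(1))
        for obs in (2, 4, 6, 8):
            exact_tail = pmf[obs:].sum()
            mc_tail = (samples >= obs).mean()
            se = math.sqrt(exact_tail * (1 - exact_tail) / n_samples)
            assert abs(mc_tail - exact_tail) <= 3 * se + 1e-12

    def test_interval_and_expected(self):
        probs = np.full(50, 0.3)
        df = pd.DataFrame({"pos": range(50), "kind": "snv", "ref": "A",
                           "alt": "T", "length": 0, "category": "missense",
                           "r": probs})
        st = gx.TranscriptSiteTable("T", df)
        res = burden_pvalue(st, "missense", 20, n_gen=0.5, n_samples=50_000, seed=2)
        # n_gen = 0.5 makes r_scaled == r exactly
        assert res.expected == pytest.approx(15.0)
        lo, hi = res.interval90
        assert lo < 15 < hi


class TestCalibration:
    def test_closed_form_single_site(self):
        df = pd.DataFrame({"pos": [1], "kind": ["snv"], "ref": ["A"],
                           "alt": ["T"], "length": [0],
                           "category": ["synonymous"], "r": [0.5]})
        st = gx.TranscriptSiteTable("T", df)
        n = calibrate_ngen([st], 0.75)
        assert n == pytest.approx(1.0, rel=1e-9)

    def test_small_rate_linearity(self):
        df = pd.DataFrame({"pos": range(100), "kind": "snv", "ref": "A",
                           "alt": "T", "length": 0, "category": "synonymous",
                           "r": np.full(100, 1e-8)})
        st = gx.TranscriptSiteTable("T", df)
        n1 = calibrate_ngen([st], 1e-3)
        n2 = calibrate_ngen([st], 2e-3)
        assert n2 / n1 == pytest.approx(2.0, rel=1e-3)

    def test_unreachable_target_rejected(self):
        df = pd.DataFrame({"pos": [1], "kind": ["snv"], "ref": ["A"],
                           "alt": ["T"], "length": [0],
                           "category": ["synonymous"], "r": [0.5]})
        st = gx.TranscriptSiteTable("T", df)
        with pytest.raises(ValueError):
            calibrate_ngen([st], 2.0)

    def test_eq_scaling_linear_regime(self):
        r = 1e-9
        n_gen = 10.0
        assert generation_scale(r, n_gen) / (2 * n_gen * r) == \
            pytest.approx(1.0, rel=1e-6)


class TestCoverageCorrection:
    def test_flat_coverage_gives_unit_factors(self):
        oe = pd.Series(np.ones(30))
        an = pd.Series(np.full(30, 80_000.0))
        f = coverage_correct(oe, an)
        assert np.allclose(f, 1.0)

    def test_low_an_transcripts_excluded(self):
        oe = pd.Series(np.ones(30))
        an = pd.Series(np.r_[np.full(29, 80_000.0), 40_000.0])
        f = coverage_correct(oe, an)
        assert len(f) == 29 and 29 not in f.index

    def test_linear_bias_flattened(self):
        rng = np.random.default_rng(0)
        an = pd.Series(np.linspace(55_000, 150_000, 500))
        oe = an / an.max() + rng.normal(0, 0.01, 500)
        f = coverage_correct(oe, an, frac=0.1)
        corrected = (oe / f).to_numpy()
        x = (an / an.max()).to_numpy()
        slope = np.polyfit(x, corrected, 1)[0]
        assert abs(slope) < 0.05

    def test_too_few_transcripts_rejected(self):
        with pytest.raises(ValueError):
            coverage_correct(pd.Series(np.ones(5)),
                             pd.Series(np.full(5, 80_000.0)))


class TestConstraint:
    def test_arithmetic(self):
        cs = constraint_scores(10, 20, 15)
        assert cs.oe_ratio == pytest.approx(10.5 / 20.5)
        assert cs.loeuf == pytest.approx(10.5 / 15.5)

    def test_pseudo_count_limit(self):
        cs = constraint_scores(0, 0, 0)
        assert cs.oe_ratio == 1.0 and cs.loeuf == 1.0

    def test_equal_obs_exp_is_unity(self):
        assert constraint_scores(7, 7, 5).oe_ratio == 1.0


class TestObservedCounts:
    def test_snv_and_indel_tallies(self):
        genome, t = _toy_gene("+")
        s = t.cds_intervals[0][0]
        e2 = t.cds_intervals[1][0]
        muts = [
            MutationRecord("chr1", s + 5, "T", "C"),            # synonymous
            MutationRecord("chr1", e2 + 1, "G", "A"),           # nonsense
            MutationRecord("chr1", s + 2,
                           genome.fetch("chr1", s + 2, s + 3),
                           genome.fetch("chr1", s + 2, s + 3) + "AT"),  # fs ins
            MutationRecord("chr1", e2, genome.fetch("chr1", e2, e2 + 4),
                           genome.fetch("chr1", e2, e2 + 1)),   # 3bp del inframe
            MutationRecord("chr1", 0, "A", "T"),                # outside
        ]
        counts = observed_counts(t, genome, muts)
        assert counts["synonymous"] == 1
        assert counts["nonsense"] == 1
        assert counts["frameshift_indel"] == 1
        assert counts["inframe_indel"] == 1
        assert sum(counts.values()) == 4

    def test_splice_snv_counted(self):
        genome, t = _toy_gene("+")
        pos = t.splice_site_positions()[0]
        ref = genome.fetch("chr1", pos, pos + 1)
        muts = [MutationRecord("chr1", pos, ref, "A" if ref != "A" else "C")]
        assert observed_counts(t, genome, muts)["splice_disruption"] == 1


class TestTranscriptomeIntegration:
    def test_site_table_on_simulated_transcripts(self):
        genome, mask, trans, _ = simulate_transcriptome(3, seed=2)
        rates = _uniform_snv_rates(1e-3)
        for t in trans:
            table = gx.build_site_table(t, genome, rates)
            df = table.df
            # every coding position contributes exactly 3 SNV entries
            n_coding = len(t.coding_positions())
            n_splice = len(t.splice_site_positions())
            assert (df["kind"] == "snv").sum() == 3 * (n_coding + n_splice)
            assert set(df["category"]) <= set(CATEGORIES)
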