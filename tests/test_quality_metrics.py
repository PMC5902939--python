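"""Metric battery: per-metric oracles, histogram conservation, profiles."""

import random

import numpy as np
import pytest

import varrescue as vr
from varrescue.quality_metrics import (
    DEFAULT_BAF_EDGES,
    chromosome_counts,
    make_histogram,
)


def _record(calls, pos=100, ref="A", alt="G"):
    return vr.VariantRecord(key=vr.VariantKey("1", pos, ref, alt), calls=calls)


def _callset(records, roster):
    cs = vr.CallSet(label="t", roster=tuple(roster))
    for r in records:
        cs.add(r)
    return cs


HET = (0, 1)
HOM = (1, 1)
REF = (0, 0)
MISS = (None, None)


class TestBap:
    def test_balanced_het_and_hom_alt(self):
        rec = _record({
            "S1": vr.GenotypeCall(alleles=HET, ad=(5, 5)),
            "S2": vr.GenotypeCall(alleles=HOM, ad=(0, 10)),
        })
        cs = _callset([rec], ["S1", "S2"])
        vals, skipped = vr.bap_values(cs)
        assert sorted(vals) == [0.5, 1.0] and skipped == 0

    def test_non_carriers_and_missing_ad_handled(self):
        rec = _record({
            "S1": vr.GenotypeCall(alleles=HET, ad=(6, 2)),
            "S2": vr.GenotypeCall(alleles=REF, ad=(9, 0)),   # not a carrier
            "S3": vr.GenotypeCall(alleles=HET),              # AD missing
            "S4": vr.GenotypeCall(alleles=HET, ad=(0, 0)),   # zero depth
        })
        cs = _callset([rec], ["S1", "S2", "S3", "S4"])
        vals, skipped = vr.bap_values(cs)
        assert vals == [0.25] and skipped == 2

    def test_pooled_values_match_manual_enumeration(self):
        rng = random.Random(4)
        expected = []
        records = []
        roster = [f"S{i}" for i in range(5)]
        for pos in range(10, 40, 10):
            calls = {}
            for s in roster:
                alleles = rng.choice([HET, HOM, REF, MISS])
                dp = rng.randint(1, 50)
                alt = rng.randint(0, dp)
                calls[s] = vr.GenotypeCall(alleles=alleles, ad=(dp - alt, alt))
                if alleles in (HET, HOM) and dp > 0:
                    expected.append(alt / dp)
            records.append(_record(calls, pos=pos))
        cs = _callset(records, roster)
        vals, _ = vr.bap_values(cs)
        assert sorted(vals) == sorted(expected)


class TestBaf:
    def test_one_het_among_100_called(self):
        roster = [f"S{i}" for i in range(100)]
        calls = {s: vr.GenotypeCall(alleles=REF) for s in roster}
        calls["S0"] = vr.GenotypeCall(alleles=HET)
        assert vr.baf(_record(calls), roster) == 0.005

    def test_all_hom_alt_is_one(self):
        roster = ["S1", "S2"]
        calls = {s: vr.GenotypeCall(alleles=HOM) for s in roster}
        assert vr.baf(_record(calls), roster) == 1.0

    def test_missing_excluded_from_denominator(self):
        roster = [f"S{i}" for i in range(100)]
        calls = {s: vr.GenotypeCall(alleles=REF if i < 50 else MISS)
                 for i, s in enumerate(roster)}
        calls["S0"] = vr.GenotypeCall(alleles=HET)
        assert vr.baf(_record(calls), roster) == 0.01

    def test_zero_called_undefined(self):
        roster = ["S1"]
        with pytest.raises(ValueError, match="undefined"):
            vr.baf(_record({"S1": vr.GenotypeCall(alleles=MISS)}), roster)

    def test_invariant_to_sample_order(self):
        roster = [f"S{i}" for i in range(10)]
        calls = {s: vr.GenotypeCall(alleles=HET if i % 3 == 0 else REF)
                 for i, s in enumerate(roster)}
        rec = _record(calls)
        assert vr.baf(rec, roster) == vr.baf(rec, list(reversed(roster)))


class TestCarrierCount:
    def test_examples(self):
        assert vr.carrier_count(_record({"S1": vr.GenotypeCall(alleles=REF)})) == 0
        rec = _record({"S1": vr.GenotypeCall(alleles=HET),
                       "S2": vr.GenotypeCall(alleles=HOM),
                       "S3": vr.GenotypeCall(alleles=MISS)})
        assert vr.carrier_count(rec) == 2

    def test_binning_reproduces_hand_counts(self):
        # carrier counts 1, 1, 3, 5, 8 -> bins {1: 2, 2-4: 1, >=5: 2}
        counts = [1, 1, 3, 5, 8]
        hist = make_histogram(counts, (1, 2, 5, 10 ** 9))
        assert hist.counts == (2, 1, 2)


class TestGcFlank:
    def test_uniform_references(self):
        ref_g = vr.ReferenceSequence({"1": "G" * 201})
        ref_at = vr.ReferenceSequence({"1": "AT" * 101})
        key = vr.VariantKey("1", 101, "G", "A")
        assert vr.gc_flank(key, ref_g) == 1.0
        assert vr.gc_flank(vr.VariantKey("1", 101, "A", "C"), ref_at) == 0.0

    def test_center_variant_matches_brute_force(self):
        rng = random.Random(9)
        seq = "".join(rng.choice("ACGT") for _ in range(201))
        ref = vr.ReferenceSequence({"1": seq})
        key = vr.VariantKey("1", 101, seq[100], "A" if seq[100] != "A" else "C")
        flank = seq[:100] + seq[101:]
        assert vr.gc_flank(key, ref) == \
            sum(1 for b in flank if b in "GC") / 200

    def test_truncated_at_chromosome_ends_and_n_excluded(self):
        ref = vr.ReferenceSequence({"1": "NGCGC"})
        # pos 2: left flank "N" (excluded), right flank "CGC"
        assert vr.gc_flank(vr.VariantKey("1", 2, "G", "A"), ref) == 1.0

    def test_absent_chromosome_rejected(self):
        ref = vr.ReferenceSequence({"1": "ACGT"})
        with pytest.raises(KeyError):
            vr.gc_flank(vr.VariantKey("9", 2, "C", "T"), ref)

    def test_random_windows_match_brute_force(self):
        rng = random.Random(31)
        for _ in range(200):
            length = rng.randint(3, 300)
            seq = "".join(rng.choice("ACGTN") for _ in range(length))
            pos = rng.randint(1, length)
            window = rng.randint(1, 150)
            ref = vr.ReferenceSequence({"1": seq})
            flank = (seq[max(0, pos - 1 - window):pos - 1]
                     + seq[pos:pos + window])
            denom = sum(1 for b in flank if b != "N")
            key = vr.VariantKey("1", pos, "A", "G")
            if denom == 0:
                with pytest.raises(ValueError):
                    vr.gc_flank(key, ref, window=window)
            else:
                expected = sum(1 for b in flank if b in "GC") / denom
                assert vr.gc_flank(key, ref, window=window) == pytest.approx(expected)


class TestRegionFraction:
    def test_empty_region_sets_all_other(self):
        keys = [vr.VariantKey("1", p, "A", "G") for p in (5, 10)]
        empty = vr.GenomicRegionSet(label="e", intervals=[])
        fr = vr.region_fraction(keys, empty, empty)
        assert fr == {"LCR": 0.0, "SDR": 0.0, "other": 1.0}

    def test_ten_keys_enumeration(self):
        keys = [vr.VariantKey("1", p, "A", "G") for p in range(1, 11)]
        lcr = vr.GenomicRegionSet(label="LCR", intervals=[("1", 0, 1)])    # pos 1
        sdr = vr.GenomicRegionSet(label="SDR", intervals=[("1", 1, 4)])    # pos 2-4
        fr = vr.region_fraction(keys, lcr, sdr)
        assert fr == {"LCR": 0.1, "SDR": 0.3, "other": 0.6}

    def test_lcr_precedence_over_sdr(self):
        keys = [vr.VariantKey("1", 5, "A", "G")]
        both = [("1", 0, 10)]
        fr = vr.region_fraction(keys,
                                vr.GenomicRegionSet(label="LCR", intervals=both),
                                vr.GenomicRegionSet(label="SDR", intervals=both))
        assert fr["LCR"] == 1.0 and fr["SDR"] == 0.0

    def test_empty_group_rejected(self):
        empty = vr.GenomicRegionSet(label="e", intervals=[])
        with pytest.raises(ValueError):
            vr.region_fraction([], empty, empty)

    def test_categories_exhaustive_on_random_groups(self):
        rng = random.Random(14)
        for _ in range(30):
            keys = [vr.VariantKey("1", rng.randint(1, 100), "A", "G")
                    for _ in range(rng.randint(1, 20))]
            lcr = vr.GenomicRegionSet(
                label="LCR", intervals=[("1", rng.randint(0, 50), rng.randint(51, 80))])
            sdr = vr.GenomicRegionSet(
                label="SDR", intervals=[("1", rng.randint(0, 50), rng.randint(51, 80))])
            fr = vr.region_fraction(keys, lcr, sdr)
            assert abs(sum(fr.values()) - 1.0) < 1e-9


class TestTiTv:
    def test_single_transition_undefined_ratio(self):
        ratio, ti, tv = vr.titv([vr.VariantKey("1", 1, "A", "G")])
        assert ratio is None and (ti, tv) == (1, 0)

    def test_qc_threshold_construction(self):
        keys = [vr.VariantKey("1", i, "A", "G") for i in range(1, 29)] \
            + [vr.VariantKey("1", i, "A", "T") for i in range(100, 110)]
        ratio, ti, tv = vr.titv(keys)
        assert (ti, tv) == (28, 10) and ratio == pytest.approx(2.8)

    def test_random_pairs_match_brute_force(self):
        rng = random.Random(8)
        bases = "ACGT"
        keys = []
        for i in range(200):
            ref = rng.choice(bases)
            alt = rng.choice([b for b in bases if b != ref])
            keys.append(vr.VariantKey("1", i + 1, ref, alt))
        _, ti, tv = vr.titv(keys)
        expected_ti = sum(1 for k in keys
                          if {k.ref, k.alt} in ({"A", "G"}, {"C", "T"}))
        assert ti == expected_ti and tv == len(keys) - expected_ti

    def test_generated_odds_recovered_within_binomial_error(self):
        rng = np.random.default_rng(5)
        n, p_ti = 4000, 0.75
        keys = []
        for i in range(n):
            if rng.random() < p_ti:
                ref, alt = ("A", "G") if rng.random() < 0.5 else ("C", "T")
            else:
                ref, alt = ("A", "C") if rng.random() < 0.5 else ("G", "T")
            keys.append(vr.VariantKey("1", i + 1, ref, alt))
        _, ti, tv = vr.titv(keys)
        se = (p_ti * (1 - p_ti) / n) ** 0.5
        assert abs(ti / n - p_ti) < 3 * se


class TestHistogramAndProfile:
    def test_histogram_conserves_count(self):
        rng = np.random.default_rng(2)
        vals = rng.random(500)
        hist = make_histogram(vals, np.linspace(0, 1, 11))
        assert hist.n + hist.n_out_of_range == 500

    def test_chromosome_counts_sorted_naturally(self):
        keys = [vr.VariantKey(c, 1, "A", "G") for c in ("10", "2", "X", "1")]
        assert list(chromosome_counts(keys)) == ["1", "2", "10", "X"]

    def _freq_callset(self, n_samples, carrier_counts):
        roster = tuple(f"S{i}" for i in range(n_samples))
        cs = vr.CallSet(label="f", roster=roster)
        for j, cc in enumerate(carrier_counts):
            calls = {s: vr.GenotypeCall(alleles=HET if i < cc else REF,
                                        gq=50, dp=30, ad=(15, 15))
                     for i, s in enumerate(roster)}
            cs.add(_record(calls, pos=10 * (j + 1)))
        return cs

    def test_profile_conserves_counts_and_invariants(self):
        cs = self._freq_callset(40, [1, 1, 2, 10, 30])
        profile = vr.build_quality_profile(cs, cs.records.keys(), "g")
        assert profile.n_variants == 5
        assert profile.carrier_hist.n == 5
        assert profile.baf_hist.n == 5
        # every BAP/GQ/DP value comes from a carrier genotype
        assert profile.bap_hist.n == sum([1, 1, 2, 10, 30])
        assert abs(sum(profile.region_fractions.values()) - 1.0) < 1e-9

    def test_rare_enriched_group_has_higher_rare_fraction(self):
        rare = self._freq_callset(200, [1] * 8)       # BAF 1/400 each
        common = self._freq_callset(200, [80] * 8)    # BAF 0.2 each
        p_rare = vr.build_quality_profile(rare, rare.records.keys(), "rare")
        p_common = vr.build_quality_profile(common, common.records.keys(), "common")
        assert p_rare.frac_rare_baf > p_common.frac_rare_baf

    def test_rare_bin_inclusive_of_exact_half_percent(self):
        # one het among 100 called -> BAF exactly 0.005, must be in the rare bin
        cs = self._freq_callset(100, [1])
        profile = vr.build_quality_profile(cs, cs.records.keys(), "edge")
        assert profile.frac_rare_baf == 1.0
        assert profile.baf_hist.counts[0] == 1

    def test_single_sample_mode_drops_baf(self):
        cs = self._freq_callset(10, [1, 2])
        profile = vr.build_quality_profile(cs, cs.records.keys(), "s",
                                           compute_baf=False)
        assert profile.baf_hist is None and profile.frac_rare_baf is None
        assert profile.carrier_hist.n == 2
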