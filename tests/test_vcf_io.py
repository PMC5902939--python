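"""I/O layer: parsing, writing, round-trips, and the inclusion filters."""

import random

import pytest

import varrescue as vr
from varrescue.vcf_io import BedFormatError, FastaFormatError, VcfParseError

from conftest import make_callset, random_keys


class TestReadVcf:
    def test_roster_and_record_count(self, toy_vcf):
        cs = vr.read_vcf(toy_vcf, "toy")
        assert cs.roster == ("S1", "S2")
        assert len(cs) == 5

    def test_format_subfields_parsed(self, toy_vcf):
        cs = vr.read_vcf(toy_vcf, "toy")
        call = cs.records[vr.VariantKey("1", 100, "A", "G")].calls["S1"]
        assert call.alleles == (0, 1)
        assert (call.gq, call.dp, call.ad) == (99, 30, (15, 15))

    def test_missing_subfields_become_none(self, toy_vcf):
        cs = vr.read_vcf(toy_vcf, "toy")
        rec = cs.records[vr.VariantKey("1", 200, "C", "T")]
        call = rec.calls["S1"]  # GT-only FORMAT
        assert call.gq is None and call.dp is None and call.ad is None
        assert not rec.calls["S2"].is_called

    def test_half_call_is_not_called(self, toy_vcf):
        cs = vr.read_vcf(toy_vcf, "toy")
        call = cs.records[vr.VariantKey("1", 300, "G", "A")].calls["S2"]
        assert call.alleles[1] is None
        assert not call.is_called

    def test_multiallelic_retained_with_full_alt_field(self, toy_vcf):
        cs = vr.read_vcf(toy_vcf, "toy")
        rec = cs.records[vr.VariantKey("1", 200, "C", "T")]
        assert rec.alt_field == ("T", "G")
        assert not rec.is_biallelic

    def test_gt_only_vcf_has_all_missing_metrics(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "1\t5\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        )
        p = tmp_path / "gt_only.vcf"
        p.write_text(text)
        cs = vr.read_vcf(p, "gtonly")
        for call in cs.records[vr.VariantKey("1", 5, "A", "C")].calls.values():
            assert call.gq is None and call.dp is None and call.ad is None

    def test_duplicate_key_raises(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t5\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n"
            "1\t5\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\n"
        )
        p = tmp_path / "dup.vcf"
        p.write_text(text)
        with pytest.raises(VcfParseError, match="duplicate"):
            vr.read_vcf(p, "dup")

    def test_chr_prefix_stripped(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "chr1\t5\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n"
        )
        p = tmp_path / "chr.vcf"
        p.write_text(text)
        cs = vr.read_vcf(p, "chr")
        assert vr.VariantKey("1", 5, "A", "C") in cs


class TestWriteVcf:
    def test_round_trip_identity_on_retained_fields(self, tmp_path):
        rng = random.Random(7)
        cs = vr.CallSet(label="rt", roster=("S1", "S2", "S3"))
        for key in sorted(random_keys(rng, 30), key=lambda k: k.sort_key()):
            calls = {}
            for s in cs.roster:
                g = rng.choice([(0, 0), (0, 1), (1, 1), (None, None)])
                dp = rng.randint(1, 60) if rng.random() < 0.8 else None
                ad = None
                if dp is not None and rng.random() < 0.8:
                    alt = rng.randint(0, dp)
                    ad = (dp - alt, alt)
                calls[s] = vr.GenotypeCall(
                    alleles=g,
                    gq=rng.randint(0, 99) if rng.random() < 0.8 else None,
                    dp=dp, ad=ad)
            cs.add(vr.VariantRecord(
                key=key,
                filter_label=rng.choice(["PASS", "PASS", "VQSRTrancheSNP99.00to99.90"]),
                calls=calls))
        path = tmp_path / "rt.vcf"
        vr.write_vcf(cs, path)
        back = vr.read_vcf(path, "rt")
        assert back.roster == cs.roster
        assert back.keys() == cs.keys()
        for key, rec in cs.records.items():
            brec = back.records[key]
            assert brec.filter_label == rec.filter_label
            for s in cs.roster:
                assert brec.calls[s] == rec.calls[s]

    def test_empty_callset_writes_header_only(self, tmp_path):
        cs = vr.CallSet(label="empty", roster=("S1",))
        path = tmp_path / "empty.vcf"
        vr.write_vcf(cs, path)
        lines = path.read_text().splitlines()
        assert lines[-1].startswith("#CHROM")
        assert all(l.startswith("#") for l in lines)

    def test_missing_ad_written_as_dot(self, tmp_path):
        cs = vr.CallSet(label="x", roster=("S1",))
        cs.add(vr.VariantRecord(
            key=vr.VariantKey("1", 10, "A", "G"),
            calls={"S1": vr.GenotypeCall(alleles=(0, 1), gq=50, dp=20)}))
        path = tmp_path / "ad.vcf"
        vr.write_vcf(cs, path)
        data_line = [l for l in path.read_text().splitlines()
                     if not l.startswith("#")][0]
        assert data_line.endswith("0/1:50:20:.")

    def test_deterministic_bytes(self, tmp_path):
        cs = make_callset("det", random_keys(random.Random(1), 20))
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        vr.write_vcf(cs, p1)
        vr.write_vcf(cs, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestBed:
    def test_overlapping_lines_merge(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("1\t0\t10\n1\t5\t20\n")
        rs = vr.read_bed(p, "LCR")
        assert rs.intervals == [("1", 0, 20)]

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        rs = vr.read_bed(p, "LCR")
        assert len(rs) == 0 and not rs.contains("1", 5)

    def test_bad_interval_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("1\t0\t10\n1\t30\t30\n")
        with pytest.raises(BedFormatError, match=":2:"):
            vr.read_bed(p, "LCR")

    def test_normalization_preserves_covered_bases(self, tmp_path):
        rng = random.Random(11)
        lines, covered = [], set()
        for _ in range(10):
            chrom = rng.choice(["1", "2"])
            s = rng.randint(0, 80)
            e = s + rng.randint(1, 30)
            lines.append(f"{chrom}\t{s}\t{e}")
            covered |= {(chrom, b) for b in range(s, e)}
        p = tmp_path / "r.bed"
        p.write_text("\n".join(lines) + "\n")
        rs = vr.read_bed(p, "X")
        # brute-force oracle: per-base membership over the full range
        for chrom in ("1", "2"):
            for b in range(0, 120):
                assert rs.contains(chrom, b + 1) == ((chrom, b) in covered)
        assert rs.total_bases() == len(covered)

    def test_one_based_query_boundary_semantics(self):
        rs = vr.GenomicRegionSet(label="x", intervals=[("1", 9, 10)])
        assert rs.contains("1", 10)       # interval (P-1, P) contains P
        assert not vr.GenomicRegionSet(
            label="x", intervals=[("1", 10, 11)]).contains("1", 10)


class TestFasta:
    def test_lookup_by_one_based_position(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">1\nACGT\n")
        ref = vr.read_fasta(p)
        assert ref.base("1", 1) == "A" and ref.base("1", 4) == "T"

    def test_lowercase_uppercased_and_multi_record(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">1\nacgt\n>2 description here\nGGGG\n")
        ref = vr.read_fasta(p)
        assert ref.base("1", 2) == "C"
        assert set(ref.chroms()) == {"1", "2"}

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">1\nACGT\n>1\nTTTT\n")
        with pytest.raises(FastaFormatError, match="duplicate"):
            vr.read_fasta(p)


class TestCallRateAndFilter:
    @staticmethod
    def _record(called_flags, filter_label="PASS", key=None):
        key = key or vr.VariantKey("1", 50, "A", "G")
        calls = {
            f"S{i}": vr.GenotypeCall(alleles=(0, 1) if c else (None, None))
            for i, c in enumerate(called_flags)
        }
        return vr.VariantRecord(key=key, filter_label=filter_label, calls=calls)

    def test_call_rate_all_and_partial(self):
        roster = [f"S{i}" for i in range(10)]
        assert vr.call_rate(self._record([True] * 10), roster) == 1.0
        assert vr.call_rate(self._record([True] * 9 + [False]), roster) == 0.9

    def test_call_rate_matches_manual_count(self):
        rng = random.Random(3)
        for _ in range(50):
            flags = [rng.random() < 0.7 for _ in range(rng.randint(1, 20))]
            roster = [f"S{i}" for i in range(len(flags))]
            assert vr.call_rate(self._record(flags), roster) == \
                sum(flags) / len(flags)

    def _toy_set(self):
        roster = tuple(f"S{i}" for i in range(10))
        cs = vr.CallSet(label="toy", roster=roster)
        mk = lambda pos, ref, alt: vr.VariantKey("1", pos, ref, alt)
        full = {s: vr.GenotypeCall(alleles=(0, 1)) for s in roster}
        # multi-allelic row
        cs.add(vr.VariantRecord(key=mk(10, "A", "G"), calls=dict(full),
                                alt_field=("G", "T")))
        # indel
        cs.add(vr.VariantRecord(key=mk(20, "A", "AT"), calls=dict(full)))
        # non-PASS
        cs.add(vr.VariantRecord(key=mk(30, "C", "T"), filter_label="LowQual",
                                calls=dict(full)))
        # call rate 0.8
        calls80 = {s: vr.GenotypeCall(alleles=(0, 1) if i < 8 else (None, None))
                   for i, s in enumerate(roster)}
        cs.add(vr.VariantRecord(key=mk(40, "G", "A"), calls=calls80))
        # clean record
        cs.add(vr.VariantRecord(key=mk(50, "T", "C"), calls=dict(full)))
        return cs

    def test_filter_cascade_enumeration(self):
        cs = self._toy_set()
        out = vr.filter_pass_biallelic_snv(cs, min_call_rate=0.9)
        assert out.keys() == {vr.VariantKey("1", 50, "T", "C")}
        assert len(cs) == 5  # input unmodified

    def test_call_rate_exactly_at_threshold_retained(self):
        roster = tuple(f"S{i}" for i in range(10))
        cs = vr.CallSet(label="b", roster=roster)
        calls = {s: vr.GenotypeCall(alleles=(0, 1) if i < 9 else (None, None))
                 for i, s in enumerate(roster)}
        cs.add(vr.VariantRecord(key=vr.VariantKey("1", 5, "A", "G"),
                                calls=calls))
        assert len(vr.filter_pass_biallelic_snv(cs, min_call_rate=0.9)) == 1

    def test_none_threshold_skips_call_rate(self):
        cs = self._toy_set()
        out = vr.filter_pass_biallelic_snv(cs, min_call_rate=None)
        assert out.keys() == {vr.VariantKey("1", 40, "G", "A"),
                              vr.VariantKey("1", 50, "T", "C")}

    def test_dot_filter_fails_pass_criterion(self):
        cs = vr.CallSet(label="d", roster=("S1",))
        cs.add(vr.VariantRecord(key=vr.VariantKey("1", 5, "A", "G"),
                                filter_label=".",
                                calls={"S1": vr.GenotypeCall(alleles=(0, 1))}))
        assert len(vr.filter_pass_biallelic_snv(cs)) == 0

    def test_filter_idempotent_and_subset(self):
        cs = self._toy_set()
        once = vr.filter_pass_biallelic_snv(cs, min_call_rate=0.9)
        twice = vr.filter_pass_biallelic_snv(once, min_call_rate=0.9)
        assert once.keys() == twice.keys()
        assert once.keys() <= cs.keys()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="min_call_rate"):
            vr.filter_pass_biallelic_snv(self._toy_set(), min_call_rate=1.5)
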