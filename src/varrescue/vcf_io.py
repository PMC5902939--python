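"""Domain types and standard-format I/O (VCF, BED, FASTA) plus variant-level filters.

Conventions used throughout the package:

* Variant identity is the normalized tuple ``(chrom, pos, ref, alt)`` with a
  1-based position (VCF convention).  Chromosome labels are stored without a
  leading ``chr`` prefix so GRCh37-style ("1") and UCSC-style ("chr1")
  resources interoperate.
* BED intervals are 0-based half-open and converted at the boundary.
* Genotype alleles are coded 0 (reference), 1 (alternate) or ``None``
  (missing).  A genotype is *called* iff both alleles are non-missing;
  half-calls count as missing.
"""

from __future__ import annotations

import bisect
import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam
from Bio import SeqIO

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed or violates call-set invariants."""


class BedFormatError(ValueError):
    """Raised for malformed BED lines (reports the 1-based line number)."""


class FastaFormatError(ValueError):
    """Raised for duplicate headers or empty sequences in a FASTA file."""


def normalize_chrom(chrom: str) -> str:
    """Strip an optional 'chr' prefix so "chr1" and "1" compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Normalized variant identity: chromosome, 1-based position, ref, alt.

    Equality and hashing are over exactly these four fields; this is the key
    used for every cross-pipeline match.  After SNV filtering ref/alt are
    single uppercase bases and differ; the constructor does not enforce the
    SNV constraint so that raw multi-allelic/indel rows can be represented
    before filtering.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _BASES
            and self.alt in _BASES
            and self.ref != self.alt
        )

    def sort_key(self) -> tuple:
        return (_chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """One sample's genotype at one site.

    ``alleles`` is a pair over {0: ref, 1: alt, None: missing}.  ``gq``,
    ``dp`` and ``ad`` are ``None`` when absent from the source — absent is
    distinct from zero.  ``ad`` is a (ref_reads, alt_reads) pair.
    """

    alleles: tuple[Optional[int], Optional[int]] = (None, None)
    gq: Optional[int] = None
    dp: Optional[int] = None
    ad: Optional[tuple[int, int]] = None

    @property
    def is_called(self) -> bool:
        return self.alleles[0] is not None and self.alleles[1] is not None

    @property
    def alt_count(self) -> int:
        """Number of alternate alleles; 0 for a no-call."""
        if not self.is_called:
            return 0
        return sum(1 for a in self.alleles if a == 1)

    @property
    def is_carrier(self) -> bool:
        return self.alt_count >= 1


NO_CALL = GenotypeCall()
HOM_REF = GenotypeCall(alleles=(0, 0))


@dataclass(slots=True)
class VariantRecord:
    """One variant row: key, VQSR filter label, per-sample genotype calls.

    ``calls`` maps sample_id -> GenotypeCall; sample ids must belong to the
    owning call-set's roster.  ``alt_field`` preserves the raw ALT column so
    multi-allelic rows can be recognized by the bi-allelic filter even though
    the key carries only the first alternate.
    """

    key: VariantKey
    filter_label: str = "PASS"
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    alt_field: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.alt_field:
            self.alt_field = (self.key.alt,)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_field) == 1

    def carriers(self) -> list[str]:
        return [s for s, c in self.calls.items() if c.is_carrier]


@dataclass(slots=True)
class CallSet:
    """One pipeline configuration's variant records over a sample roster.

    ``label`` is a free-form pipeline tag (aligner x genotyping mode), e.g.
    ``"bwa.joint"``.  ``records`` is keyed by VariantKey (unique).
    """

    label: str
    roster: tuple[str, ...]
    records: dict[VariantKey, VariantRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("CallSet label must be non-empty")
        if not self.roster:
            raise ValueError("CallSet roster must be non-empty")
        self.roster = tuple(self.roster)
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("duplicate sample ids in roster")

    def add(self, record: VariantRecord) -> None:
        if record.key in self.records:
            raise VcfParseError(f"duplicate variant key {record.key}")
        self.records[record.key] = record

    def keys(self) -> set[VariantKey]:
        return set(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.records

    def sorted_records(self) -> list[VariantRecord]:
        return sorted(self.records.values(), key=lambda r: r.key.sort_key())


@dataclass(slots=True)
class GenomicRegionSet:
    """A labeled set of genomic intervals (BED semantics: 0-based half-open).

    Intervals are normalized on construction: sorted and overlap/adjacency
    merged per chromosome, so membership queries can bisect.
    """

    label: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    _starts: dict[str, list[int]] = field(default_factory=dict, repr=False)
    _ends: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        merged: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"interval start {start} >= end {end} on {chrom}")
            by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end))
        for chrom in sorted(by_chrom, key=_chrom_sort_key):
            ivs = sorted(by_chrom[chrom])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:  # overlap or bookend: merge
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        self.intervals = merged
        self._starts = {}
        self._ends = {}
        for chrom, s, e in merged:
            self._starts.setdefault(chrom, []).append(s)
            self._ends.setdefault(chrom, []).append(e)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position (converted to 0-based internally)."""
        chrom = normalize_chrom(chrom)
        starts = self._starts.get(chrom)
        if not starts:
            return False
        p0 = pos - 1
        i = bisect.bisect_right(starts, p0) - 1
        return i >= 0 and p0 < self._ends[chrom][i]

    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


class ReferenceSequence:
    """In-memory reference: per-chromosome base strings over {A,C,G,T,N}.

    Lookup is by (chrom, 1-based pos).  Chromosome labels are normalized
    (no 'chr' prefix) at construction.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for chrom, seq in sequences.items():
            chrom = normalize_chrom(chrom)
            if chrom in self._seqs:
                raise FastaFormatError(f"duplicate chromosome label {chrom!r}")
            if not seq:
                raise FastaFormatError(f"empty sequence for {chrom!r}")
            self._seqs[chrom] = seq.upper()

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[normalize_chrom(chrom)])

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self._seqs[normalize_chrom(chrom)][pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Bases for 1-based inclusive [start, end], truncated at chromosome ends."""
        seq = self._seqs[normalize_chrom(chrom)]
        return seq[max(0, start - 1):min(len(seq), end)]

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._seqs

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, label: str) -> CallSet:
    """Read a VCF (plain or gzip text) into a CallSet.

    The roster equals the header sample order.  Multi-allelic rows are
    retained unmodified (the key carries the first ALT; the raw ALT tuple is
    preserved for the bi-allelic filter).  Missing FORMAT subfields become
    ``None``.  Duplicate (chrom, pos, ref, alt) rows raise
    :class:`VcfParseError`.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = tuple(vf.header.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} names no samples in its header")
    cs = CallSet(label=label, roster=samples)
    for rec in vf:
        alts = tuple(rec.alts) if rec.alts else ()
        key = VariantKey(
            chrom=normalize_chrom(rec.chrom),
            pos=rec.pos,
            ref=rec.ref.upper(),
            alt=(alts[0].upper() if alts else "."),
        )
        filters = list(rec.filter.keys())
        if len(filters) == 1:
            filter_label = filters[0]
        elif filters:
            filter_label = ";".join(filters)
        else:
            filter_label = "."
        calls: dict[str, GenotypeCall] = {}
        for sid in samples:
            sc = rec.samples[sid]
            gt = sc.get("GT", (None, None))
            if gt is None:
                gt = (None, None)
            # haploid rows padded to diploid missing second allele
            if len(gt) == 1:
                gt = (gt[0], None)
            a = tuple(None if g is None else min(int(g), 1) for g in gt[:2])
            gq = sc.get("GQ")
            dp = sc.get("DP")
            ad_raw = sc.get("AD")
            ad: Optional[tuple[int, int]] = None
            if ad_raw is not None and len(ad_raw) >= 2 and ad_raw[0] is not None and ad_raw[1] is not None:
                ad = (int(ad_raw[0]), int(ad_raw[1]))
            calls[sid] = GenotypeCall(
                alleles=a,  # type: ignore[arg-type]
                gq=None if gq is None else int(gq),
                dp=None if dp is None else int(dp),
                ad=ad,
            )
        cs.add(VariantRecord(key=key, filter_label=filter_label,
                             calls=calls, alt_field=tuple(x.upper() for x in alts)))
    vf.close()
    return cs


_VCF_HEADER_META = """##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
"""


def _fmt_call(call: GenotypeCall) -> str:
    a0 = "." if call.alleles[0] is None else str(call.alleles[0])
    a1 = "." if call.alleles[1] is None else str(call.alleles[1])
    gq = "." if call.gq is None else str(call.gq)
    dp = "." if call.dp is None else str(call.dp)
    ad = "." if call.ad is None else f"{call.ad[0]},{call.ad[1]}"
    return f"{a0}/{a1}:{gq}:{dp}:{ad}"


def write_vcf(callset: CallSet, path: str | Path) -> None:
    """Write a CallSet as deterministic VCF 4.2 text.

    Records are sorted by (chrom, pos, ref, alt); FORMAT is ``GT:GQ:DP:AD``
    with ``.`` for missing subfields.  Non-PASS filter labels are declared in
    the header so the file round-trips through strict parsers.
    """
    path = Path(path)
    filter_labels = sorted(
        {r.filter_label for r in callset.records.values()}
        - {"PASS", "."}
    )
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(_VCF_HEADER_META)
        for fl in filter_labels:
            for part in fl.split(";"):
                fh.write(f'##FILTER=<ID={part},Description="Failed filter">\n')
        chroms = sorted({r.key.chrom for r in callset.records.values()},
                        key=_chrom_sort_key)
        for chrom in chroms:
            max_pos = max(r.key.pos for r in callset.records.values()
                          if r.key.chrom == chrom)
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(callset.roster) + "\n")
        for rec in callset.sorted_records():
            alt_col = ",".join(rec.alt_field) if rec.alt_field else rec.key.alt
            cols = [
                rec.key.chrom, str(rec.key.pos), ".", rec.key.ref, alt_col,
                ".", rec.filter_label, ".", "GT:GQ:DP:AD",
            ]
            cols += [_fmt_call(rec.calls.get(s, NO_CALL)) for s in callset.roster]
            fh.write("\t".join(cols) + "\n")


def read_bed(path: str | Path, label: str) -> GenomicRegionSet:
    """Read a 3+ column BED (0-based half-open) into a normalized region set."""
    intervals: list[tuple[str, int, int]] = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedFormatError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((parts[0], start, end))
    return GenomicRegionSet(label=label, intervals=intervals)


def write_bed(regions: GenomicRegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in regions.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_fasta(path: str | Path) -> ReferenceSequence:
    """Read a FASTA into memory; the header token before whitespace is the label."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FastaFormatError(f"duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"empty sequence for {rec.id!r}")
        seqs[rec.id] = seq
    if not seqs:
        raise FastaFormatError(f"no records in {path}")
    return ReferenceSequence(seqs)


def write_fasta(reference: ReferenceSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Variant-level inclusion filters
# ---------------------------------------------------------------------------

def call_rate(record: VariantRecord, roster: Sequence[str]) -> float:
    """Fraction of roster samples with a called (both-alleles) genotype."""
    if not roster:
        raise ValueError("roster must be non-empty")
    called = sum(
        1 for s in roster
        if (c := record.calls.get(s)) is not None and c.is_called
    )
    return called / len(roster)


def filter_pass_biallelic_snv(
    callset: CallSet,
    min_call_rate: Optional[float] = None,
) -> CallSet:
    """Apply the variant inclusion cascade: PASS, bi-allelic SNV, call rate.

    Retains records whose FILTER is exactly "PASS", whose ALT column named a
    single alternate allele, whose ref/alt are single distinct A/C/G/T bases,
    and — when ``min_call_rate`` is given — whose call rate over the roster is
    at least that threshold (inclusive).  ``min_call_rate=None`` skips the
    call-rate criterion, matching single-sample genotyping mode where call
    rate is not computable.  Multi-allelic rows are dropped, not split.  The
    input is unmodified.
    """
    if min_call_rate is not None and not (0.0 <= min_call_rate <= 1.0):
        raise ValueError(f"min_call_rate must be in [0, 1], got {min_call_rate}")
    out = CallSet(label=callset.label, roster=callset.roster)
    for key, rec in callset.records.items():
        if rec.filter_label != "PASS":
            continue
        if not rec.is_biallelic or not key.is_snv():
            continue
        if min_call_rate is not None and call_rate(rec, callset.roster) < min_call_rate:
            continue
        out.records[key] = rec
    return out
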