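"""The variant quality-assessment battery applied to any variant group.

Eight metrics characterize a group of variants (e.g. the pipeline-unique and
shared groups from a comparison): B-allele proportion (BAP, per-carrier read
support), B-allele frequency (BAF, cohort alternate-allele frequency),
carrier counts, genotype quality (GQ), read depth (DP), flanking GC content,
chromosome distribution, and overlap with low-complexity (LCR) and
segmental-duplication (SDR) regions.  A :class:`QualityProfile` bundles all
of them for one group, together with functional-tier and known/novel
fractions from the annotation layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from varrescue.vcf_io import (
    CallSet,
    GenomicRegionSet,
    ReferenceSequence,
    VariantKey,
    VariantRecord,
    _chrom_sort_key,
)

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

# BAF reporting uses an explicit first bin at <= 0.5% — the threshold used to
# report the rare-variant excess among pipeline-unique calls.
RARE_BAF_THRESHOLD = 0.005

DEFAULT_BAP_EDGES = tuple(np.linspace(0.0, 1.0, 21))
DEFAULT_GQ_EDGES = tuple(range(0, 105, 5))
DEFAULT_DP_EDGES = tuple(np.unique(np.round(np.geomspace(1, 1024, 21)).astype(int)))
# first bin is the inclusive "<= 0.5%" rare bin: its upper edge sits one ulp
# above the threshold so a BAF of exactly 0.005 lands inside it
DEFAULT_BAF_EDGES = (0.0, float(np.nextafter(RARE_BAF_THRESHOLD, 1.0)),
                     0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)
DEFAULT_CARRIER_EDGES = (1, 2, 5, 10, 50, 10 ** 9)


@dataclass(frozen=True, slots=True)
class Histogram:
    """Counts over ascending bin edges; conserves its input count.

    Binning follows numpy.histogram semantics: bins are half-open except the
    last, which is closed, and values outside [edges[0], edges[-1]] are
    dropped (tracked in ``n_out_of_range``).
    """

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    n_out_of_range: int = 0

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    def fraction_below(self, threshold: float) -> float:
        """Fraction of binned values in bins entirely at or below ``threshold``."""
        if self.n == 0:
            raise ValueError("empty histogram")
        total = 0
        for (lo, hi), c in zip(zip(self.bin_edges, self.bin_edges[1:]), self.counts):
            if hi <= threshold:
                total += c
        return total / self.n

    def to_dict(self) -> dict:
        return {
            "bin_edges": [float(e) for e in self.bin_edges],
            "counts": list(self.counts),
            "n_out_of_range": self.n_out_of_range,
        }


def make_histogram(values: Iterable[float], bin_edges: Sequence[float]) -> Histogram:
    vals = np.asarray(list(values), dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    in_range = int(counts.sum())
    return Histogram(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        n_out_of_range=len(vals) - in_range,
    )


# ---------------------------------------------------------------------------
# Per-metric operations
# ---------------------------------------------------------------------------

def bap_values(
    callset: CallSet,
    keys: Optional[Iterable[VariantKey]] = None,
) -> tuple[list[float], int]:
    """B-allele proportions pooled over carrier genotypes in a variant group.

    One value per (variant, sample) pair where the genotype carries at least
    one alternate allele and AD is present with ref+alt reads > 0; the value
    is alt_reads / (ref_reads + alt_reads).  Pairs lacking usable AD are
    skipped; the skip count is returned alongside.
    """
    if keys is None:
        keys = callset.records.keys()
    values: list[float] = []
    skipped = 0
    for key in keys:
        rec = callset.records[key]
        for call in rec.calls.values():
            if not call.is_carrier:
                continue
            if call.ad is None or (call.ad[0] + call.ad[1]) <= 0:
                skipped += 1
                continue
            values.append(call.ad[1] / (call.ad[0] + call.ad[1]))
    return values, skipped


def baf(record: VariantRecord, roster: Sequence[str]) -> float:
    """Alternate-allele frequency over called genotypes at one site.

    Missing genotypes are excluded from both numerator and denominator:
    BAF = (alt allele count among called) / (2 x number called).
    """
    alt = 0
    called = 0
    for s in roster:
        call = record.calls.get(s)
        if call is None or not call.is_called:
            continue
        called += 1
        alt += call.alt_count
    if called == 0:
        raise ValueError(f"no called genotypes at {record.key}; BAF undefined")
    return alt / (2 * called)


def carrier_count(record: VariantRecord) -> int:
    """Number of samples whose called genotype has >= 1 alternate allele.

    A carrier count of 1 defines a singleton.
    """
    return sum(1 for c in record.calls.values() if c.is_carrier)


def gc_flank(
    key: VariantKey,
    reference: ReferenceSequence,
    window: int = 100,
) -> float:
    """GC fraction of the bases flanking a variant position.

    Takes up to ``window`` bases on each side of the position (the variant
    base itself excluded), truncated at chromosome ends; N bases are excluded
    from numerator and denominator.
    """
    if key.chrom not in reference:
        raise KeyError(f"chromosome {key.chrom!r} absent from reference")
    if window < 1:
        raise ValueError("window must be positive")
    left = reference.slice(key.chrom, key.pos - window, key.pos - 1)
    right = reference.slice(key.chrom, key.pos + 1, key.pos + window)
    flank = left + right
    denom = sum(1 for b in flank if b != "N")
    if denom == 0:
        raise ValueError(f"no non-N flanking bases at {key}")
    gc = sum(1 for b in flank if b in "GC")
    return gc / denom


def region_fraction(
    keys: Iterable[VariantKey],
    lcr: GenomicRegionSet,
    sdr: GenomicRegionSet,
) -> dict[str, float]:
    """Fractions of a variant group in LCR / SDR / other regions.

    Each key lands in exactly one category: LCR if inside any LCR interval
    (LCR takes precedence when a position is in both), else SDR, else other.
    """
    counts = region_counts(keys, lcr, sdr)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty variant group")
    return {k: v / total for k, v in counts.items()}


def region_counts(
    keys: Iterable[VariantKey],
    lcr: GenomicRegionSet,
    sdr: GenomicRegionSet,
) -> dict[str, int]:
    counts = {"LCR": 0, "SDR": 0, "other": 0}
    for key in keys:
        if lcr.contains(key.chrom, key.pos):
            counts["LCR"] += 1
        elif sdr.contains(key.chrom, key.pos):
            counts["SDR"] += 1
        else:
            counts["other"] += 1
    return counts


def titv(keys: Iterable[VariantKey]) -> tuple[Optional[float], int, int]:
    """Transition/transversion ratio of a variant group.

    Transitions are A<->G and C<->T; every other ref/alt pair is a
    transversion.  Returns (ratio, ti_count, tv_count); the ratio is ``None``
    (undefined) when there are no transversions.
    """
    ti = tv = 0
    for key in keys:
        if (key.ref, key.alt) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if ti + tv == 0:
        raise ValueError("empty variant group")
    return (ti / tv if tv > 0 else None), ti, tv


def chromosome_counts(keys: Iterable[VariantKey]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for key in keys:
        counts[key.chrom] = counts.get(key.chrom, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: _chrom_sort_key(kv[0])))


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class QualityProfile:
    """The full metric battery for one variant group.

    ``baf_hist`` is populated in joint-genotyping mode (its first bin is the
    explicit <= 0.5% rare bin); in single-sample mode BAF is not computable —
    no-calls and reference calls are indistinguishable — so ``carrier_hist``
    stands in.  ``tier_fractions`` / ``known_fraction`` come from the
    annotation layer and are ``None`` when no annotations were supplied.
    """

    group_label: str
    n_variants: int
    bap_hist: Histogram
    bap_skipped: int
    gq_hist: Histogram
    dp_hist: Histogram
    carrier_hist: Histogram
    chrom_counts: dict[str, int]
    region_fractions: dict[str, float]
    titv_ratio: Optional[float]
    ti_count: int
    tv_count: int
    gc_mean: Optional[float] = None
    gc_hist: Optional[Histogram] = None
    baf_hist: Optional[Histogram] = None
    #: fraction of variants with BAF <= 0.5% (inclusive), computed from raw
    #: values rather than histogram bins — the rare-variant excess statistic
    frac_rare_baf: Optional[float] = None
    tier_fractions: Optional[dict[str, float]] = None
    n_unannotated: int = 0
    known_fraction: Optional[float] = None
    novel_fraction: Optional[float] = None
    novel_high_cadd_fraction: Optional[float] = None

    @property
    def frac_singleton(self) -> Optional[float]:
        if self.carrier_hist.n == 0:
            return None
        return self.carrier_hist.counts[0] / self.carrier_hist.n

    def to_dict(self) -> dict:
        return {
            "group_label": self.group_label,
            "n_variants": self.n_variants,
            "bap_hist": self.bap_hist.to_dict(),
            "bap_skipped": self.bap_skipped,
            "gq_hist": self.gq_hist.to_dict(),
            "dp_hist": self.dp_hist.to_dict(),
            "carrier_hist": self.carrier_hist.to_dict(),
            "frac_singleton": self.frac_singleton,
            "chrom_counts": self.chrom_counts,
            "region_fractions": self.region_fractions,
            "titv_ratio": self.titv_ratio,
            "ti_count": self.ti_count,
            "tv_count": self.tv_count,
            "gc_mean": self.gc_mean,
            "gc_hist": self.gc_hist.to_dict() if self.gc_hist else None,
            "baf_hist": self.baf_hist.to_dict() if self.baf_hist else None,
            "frac_rare_baf": self.frac_rare_baf,
            "tier_fractions": self.tier_fractions,
            "n_unannotated": self.n_unannotated,
            "known_fraction": self.known_fraction,
            "novel_fraction": self.novel_fraction,
            "novel_high_cadd_fraction": self.novel_high_cadd_fraction,
        }


def build_quality_profile(
    callset: CallSet,
    keys: Iterable[VariantKey],
    group_label: str,
    reference: Optional[ReferenceSequence] = None,
    lcr: Optional[GenomicRegionSet] = None,
    sdr: Optional[GenomicRegionSet] = None,
    annotations=None,
    known_index=None,
    compute_baf: bool = True,
    gc_window: int = 100,
    bap_edges: Sequence[float] = DEFAULT_BAP_EDGES,
    gq_edges: Sequence[float] = DEFAULT_GQ_EDGES,
    dp_edges: Sequence[float] = DEFAULT_DP_EDGES,
    baf_edges: Sequence[float] = DEFAULT_BAF_EDGES,
    carrier_edges: Sequence[float] = DEFAULT_CARRIER_EDGES,
) -> QualityProfile:
    """Assemble the full quality profile for a variant group.

    ``callset`` may be a single pipeline's call-set or a union merge; ``keys``
    selects the group (must all be present in the call-set).
    ``compute_baf=False`` selects single-sample mode: the BAF histogram is
    omitted and carrier counts carry the frequency information.  Region
    fractions, GC and annotation-derived fractions are only computed when the
    corresponding resources are given.
    """
    keys = list(keys)
    if not keys:
        raise ValueError("empty variant group")
    missing = [k for k in keys if k not in callset.records]
    if missing:
        raise KeyError(f"{len(missing)} group keys absent from call-set, e.g. {missing[0]}")

    baps, bap_skipped = bap_values(callset, keys)
    gqs = [c.gq for k in keys for c in callset.records[k].calls.values()
           if c.is_carrier and c.gq is not None]
    dps = [c.dp for k in keys for c in callset.records[k].calls.values()
           if c.is_carrier and c.dp is not None]
    carriers = [carrier_count(callset.records[k]) for k in keys]

    ratio, ti, tv = titv(keys)

    baf_hist = None
    frac_rare = None
    if compute_baf:
        bafs = []
        for k in keys:
            rec = callset.records[k]
            try:
                bafs.append(baf(rec, callset.roster))
            except ValueError:
                pass  # zero called genotypes: excluded from the spectrum
        baf_hist = make_histogram(bafs, baf_edges)
        if bafs:
            frac_rare = float(np.mean(np.asarray(bafs) <= RARE_BAF_THRESHOLD))

    gc_mean = gc_hist = None
    if reference is not None:
        gcs = [gc_flank(k, reference, window=gc_window) for k in keys]
        gc_mean = float(np.mean(gcs))
        gc_hist = make_histogram(gcs, np.linspace(0, 1, 21))

    if lcr is not None and sdr is not None:
        region_fracs = region_fraction(keys, lcr, sdr)
    else:
        region_fracs = {"LCR": 0.0, "SDR": 0.0, "other": 1.0}

    tier_fracs = None
    n_unannot = 0
    known_frac = novel_frac = novel_cadd_frac = None
    if annotations is not None:
        from varrescue.annotation_tiers import tier_composition
        tier_fracs, n_unannot = tier_composition(keys, annotations)
    if known_index is not None:
        from varrescue.annotation_tiers import known_novel_split
        known_frac, novel_frac, novel_cadd_frac = known_novel_split(
            keys, known_index, annotations
        )

    return QualityProfile(
        group_label=group_label,
        n_variants=len(keys),
        bap_hist=make_histogram(baps, bap_edges),
        bap_skipped=bap_skipped,
        gq_hist=make_histogram(gqs, gq_edges),
        dp_hist=make_histogram(dps, dp_edges),
        carrier_hist=make_histogram(carriers, carrier_edges),
        chrom_counts=chromosome_counts(keys),
        region_fractions=region_fracs,
        titv_ratio=ratio,
        ti_count=ti,
        tv_count=tv,
        gc_mean=gc_mean,
        gc_hist=gc_hist,
        baf_hist=baf_hist,
        frac_rare_baf=frac_rare,
        tier_fractions=tier_fracs,
        n_unannotated=n_unannot,
        known_fraction=known_frac,
        novel_fraction=novel_frac,
        novel_high_cadd_fraction=novel_cadd_frac,
    )


def write_metric_table(
    callset: CallSet,
    keys: Iterable[VariantKey],
    path,
    reference: Optional[ReferenceSequence] = None,
    lcr: Optional[GenomicRegionSet] = None,
    sdr: Optional[GenomicRegionSet] = None,
    compute_baf: bool = True,
) -> None:
    """Per-variant metric TSV: key, BAF, carrier count, GC, region class."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tbaf\tcarrier_count\tgc_flank\tregion\n")
        for key in sorted(keys, key=lambda k: k.sort_key()):
            rec = callset.records[key]
            try:
                b = f"{baf(rec, callset.roster):.6g}" if compute_baf else "."
            except ValueError:
                b = "."
            cc = carrier_count(rec)
            gc = f"{gc_flank(key, reference):.4f}" if reference is not None else "."
            if lcr is not None and lcr.contains(key.chrom, key.pos):
                region = "LCR"
            elif sdr is not None and sdr.contains(key.chrom, key.pos):
                region = "SDR"
            else:
                region = "other"
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                     f"{b}\t{cc}\t{gc}\t{region}\n")
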