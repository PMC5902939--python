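"""Functional tier classification, known/novel partition, and the curated
EOAD variant audit.

Variants are ranked into three research-priority tiers from their annotated
consequence terms (ANNOVAR-style strings): Tier 1 disrupts a start or stop
codon or causes a splicing event; Tier 2 causes a non-synonymous amino-acid
change; Tier 3 is everything else.  A variant is *known* when its exact
(chrom, pos, ref, alt) key appears in any reference database key list
(dbSNP, ESP, ClinVar, 1000G, ExAC, Kaviar, HRC, ...); novel variants with a
CADD PHRED score of at least 20 are flagged as likely-deleterious novelties.

The package ships a curated table of previously published pathogenic and
protective coding variants in the three autosomal-dominant early-onset
Alzheimer's genes (APP, PSEN1, PSEN2), with each variant's external allele
frequency and whether the default single-pipeline analysis detected it; the
audit operation summarizes how many such variants a default pipeline misses.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from varrescue.vcf_io import VariantKey

# Consequence-term -> tier mapping (case/space/underscore-insensitive).
# User-extensible via the `extra_terms` argument of classify_tier.
TIER1_TERMS = frozenset({
    "stopgain", "stoploss", "startloss", "startgain", "splicing",
    "splice_acceptor_variant", "splice_donor_variant",
    "start_lost", "stop_gained", "stop_lost",
})
TIER2_TERMS = frozenset({
    "nonsynonymous snv", "nonsynonymous", "missense_variant", "missense",
    "nonframeshift substitution",
})
KNOWN_TIER3_TERMS = frozenset({
    "synonymous snv", "synonymous", "synonymous_variant",
    "intronic", "intron_variant", "intergenic", "intergenic_variant",
    "utr3", "utr5", "3_prime_utr_variant", "5_prime_utr_variant",
    "upstream", "downstream", "upstream_gene_variant",
    "downstream_gene_variant", "ncrna_exonic", "ncrna_intronic", "unknown",
})


def _canon(term: str) -> str:
    return term.strip().lower().replace("-", "_")


@dataclass(frozen=True, slots=True)
class AnnotationRecord:
    """Functional annotation for one variant: consequence terms + CADD PHRED."""

    key: VariantKey
    consequences: tuple[str, ...]
    cadd_phred: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.consequences:
            raise ValueError("consequences must be non-empty for an annotated key")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")


class KnownVariantIndex:
    """Exact-key membership index over one or more reference variant sources."""

    def __init__(self, sources: Optional[Mapping[str, Iterable[VariantKey]]] = None):
        self._sources: dict[str, set[VariantKey]] = {}
        if sources:
            for label, keys in sources.items():
                self.add_source(label, keys)

    def add_source(self, label: str, keys: Iterable[VariantKey]) -> None:
        self._sources[label] = set(keys)

    @property
    def source_labels(self) -> list[str]:
        return list(self._sources)

    def __contains__(self, key: VariantKey) -> bool:
        return any(key in s for s in self._sources.values())

    def sources_of(self, key: VariantKey) -> list[str]:
        return [lbl for lbl, s in self._sources.items() if key in s]

    def __len__(self) -> int:
        return len(set().union(*self._sources.values())) if self._sources else 0


def classify_tier(
    consequences: Sequence[str],
    strict: bool = False,
    extra_terms: Optional[Mapping[str, int]] = None,
) -> int:
    """Map consequence terms to a functional tier in {1, 2, 3}.

    The highest-priority tier among the terms wins (1 beats 2 beats 3).
    Unknown terms fall through to Tier 3 with a warning, or raise in
    ``strict`` mode.  ``extra_terms`` maps additional term strings to tiers.
    """
    if not consequences:
        raise ValueError("consequences must be non-empty")
    extra = { _canon(k): v for k, v in (extra_terms or {}).items() }
    best = 3
    for term in consequences:
        ct = _canon(term)
        if ct in extra:
            best = min(best, extra[ct])
        elif ct in TIER1_TERMS:
            best = 1
        elif ct in TIER2_TERMS:
            best = min(best, 2)
        elif ct not in KNOWN_TIER3_TERMS:
            if strict:
                raise ValueError(f"unknown consequence term {term!r}")
            warnings.warn(f"unknown consequence term {term!r}; treating as Tier 3",
                          stacklevel=2)
    return best


def tier_composition(
    keys: Iterable[VariantKey],
    annotations: Mapping[VariantKey, AnnotationRecord],
) -> tuple[dict[str, float], int]:
    """Tier fractions for a variant group; unannotated keys tallied separately.

    Returns ``(fractions, n_unannotated)`` where fractions are over the whole
    group and include an ``"unannotated"`` bucket, so they sum to 1.
    """
    keys = list(keys)
    if not keys:
        raise ValueError("empty variant group")
    counts = {"tier1": 0, "tier2": 0, "tier3": 0, "unannotated": 0}
    for key in keys:
        ann = annotations.get(key)
        if ann is None:
            counts["unannotated"] += 1
        else:
            counts[f"tier{classify_tier(ann.consequences)}"] += 1
    total = len(keys)
    return {k: v / total for k, v in counts.items()}, counts["unannotated"]


def known_novel_split(
    keys: Iterable[VariantKey],
    index: KnownVariantIndex,
    annotations: Optional[Mapping[VariantKey, AnnotationRecord]] = None,
    cadd_threshold: float = 20.0,
) -> tuple[float, float, float]:
    """(known, novel, novel-with-high-CADD) fractions of a variant group.

    Known = exact key present in any index source.  Novel-high-CADD = novel
    and annotated with cadd_phred >= threshold (inclusive: "at least 20").
    Novel keys lacking a CADD score never count as high-CADD.
    """
    keys = list(keys)
    if not keys:
        raise ValueError("empty variant group")
    n_known = n_novel_cadd = 0
    for key in keys:
        if key in index:
            n_known += 1
        else:
            ann = annotations.get(key) if annotations else None
            if ann is not None and ann.cadd_phred is not None \
                    and ann.cadd_phred >= cadd_threshold:
                n_novel_cadd += 1
    n = len(keys)
    return n_known / n, (n - n_known) / n, n_novel_cadd / n


# ---------------------------------------------------------------------------
# Curated EOAD variant audit
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class CuratedVariant:
    gene: str
    protein_change: str
    external_af: float
    called_by_default: bool


@dataclass(slots=True)
class CuratedVariantTable:
    """Curated list of published pathogenic/protective coding variants."""

    rows: list[CuratedVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rows:
            k = (r.gene, r.protein_change)
            if k in seen:
                raise ValueError(f"duplicate curated row {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True, slots=True)
class CuratedAudit:
    total: int
    detected_by_default: int
    undetected: int
    per_gene_detected: dict[str, int]
    per_gene_undetected: dict[str, int]
    undetected_pct: int  # whole percent, rounded half-up

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "detected_by_default": self.detected_by_default,
            "undetected": self.undetected,
            "per_gene_detected": dict(self.per_gene_detected),
            "per_gene_undetected": dict(self.per_gene_undetected),
            "undetected_pct": self.undetected_pct,
        }


def audit_curated_table(table: CuratedVariantTable) -> CuratedAudit:
    """Count how many curated variants the default pipeline missed.

    The undetected percentage is rounded half-up to a whole percent.
    """
    if len(table) == 0:
        raise ValueError("curated table is empty")
    det: dict[str, int] = {}
    undet: dict[str, int] = {}
    for r in table.rows:
        det.setdefault(r.gene, 0)
        undet.setdefault(r.gene, 0)
        if r.called_by_default:
            det[r.gene] += 1
        else:
            undet[r.gene] += 1
    n_det = sum(det.values())
    n_undet = sum(undet.values())
    pct = int(math.floor(100.0 * n_undet / len(table) + 0.5))
    return CuratedAudit(
        total=len(table),
        detected_by_default=n_det,
        undetected=n_undet,
        per_gene_detected=det,
        per_gene_undetected=undet,
        undetected_pct=pct,
    )


def read_curated_table(path) -> CuratedVariantTable:
    """Read a curated-variant TSV (gene, protein_change, external_af,
    called_by_default as 1/0)."""
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append(CuratedVariant(
                gene=row["gene"],
                protein_change=row["protein_change"],
                external_af=float(row["external_af"]),
                called_by_default=row["called_by_default"].strip().lower()
                in ("1", "true", "yes"),
            ))
    return CuratedVariantTable(rows=rows)


def load_eoad_table() -> CuratedVariantTable:
    """The packaged curated table of published EOAD variants (APP/PSEN1/PSEN2)."""
    ref = resources.files("varrescue").joinpath("data/eoad_variants.tsv")
    with resources.as_file(ref) as path:
        return read_curated_table(path)


# ---------------------------------------------------------------------------
# Annotation / key-list I/O
# ---------------------------------------------------------------------------

def read_annotation_table(path) -> dict[VariantKey, AnnotationRecord]:
    """Annotation TSV: chrom, pos, ref, alt, consequences (comma-joined), cadd.

    "." or empty marks a missing CADD score.
    """
    out: dict[VariantKey, AnnotationRecord] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = VariantKey(chrom=row["chrom"], pos=int(row["pos"]),
                             ref=row["ref"], alt=row["alt"])
            cadd_raw = row.get("cadd", "").strip()
            cadd = None if cadd_raw in ("", ".") else float(cadd_raw)
            out[key] = AnnotationRecord(
                key=key,
                consequences=tuple(t.strip() for t in row["consequences"].split(",")
                                   if t.strip()),
                cadd_phred=cadd,
            )
    return out


def write_annotation_table(annotations: Mapping[VariantKey, AnnotationRecord],
                           path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tconsequences\tcadd\n")
        for key in sorted(annotations, key=lambda k: k.sort_key()):
            ann = annotations[key]
            cadd = "." if ann.cadd_phred is None else f"{ann.cadd_phred:g}"
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                     f"{','.join(ann.consequences)}\t{cadd}\n")


def read_key_list(path) -> set[VariantKey]:
    """One key per line: chrom<TAB>pos<TAB>ref<TAB>alt (header optional)."""
    keys: set[VariantKey] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            keys.add(VariantKey(chrom=chrom, pos=int(pos), ref=ref, alt=alt))
    return keys


def write_key_list(keys: Iterable[VariantKey], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for key in sorted(keys, key=lambda k: k.sort_key()):
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\n")
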