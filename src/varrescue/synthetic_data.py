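"""Generative models for synthetic cohorts and per-pipeline call-set emulation.

Real multi-pipeline comparisons of this kind run on access-controlled exome
cohorts.  This module generates, from explicit generative models, everything
the analysis consumes — reference FASTA, LCR/SDR BEDs, a truth cohort with a
heavily rare-skewed allele-frequency spectrum, per-pipeline VCFs, annotation
tables, known-variant key lists and a sample-metrics table — so every stage
is testable end-to-end and generative parameters can be recovered downstream.

The two mechanisms that drive pipeline discordance are modeled directly:

* **Aligner differences** are confined to per-region-class detection
  sensitivity (aligners differ mainly inside segmental duplications, where
  read mapping is ambiguous) plus a small global asymmetry.
* **Joint-genotyping rare-allele dropout** is a carrier-count-indexed miss
  probability ``q_k`` (``q_1 > q_2 > ... -> 0``): with thousands of samples
  genotyped together, the few reads supporting a private allele can be deemed
  statistically insignificant, so the rarest variants are preferentially
  lost.  Single-sample genotyping evaluates each carrier independently and
  keeps them.  No read-level simulation is attempted; this is the minimal
  model that reproduces the observed sample-size-dependent divergence.

All randomness flows from one master seed through named substreams
(reference, cohort, per-pipeline, per-subset), so bundles and experiments are
bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from varrescue.vcf_io import (
    CallSet,
    GenomicRegionSet,
    GenotypeCall,
    HOM_REF,
    ReferenceSequence,
    VariantKey,
    VariantRecord,
    write_bed,
    write_fasta,
    write_vcf,
)

REGION_CLASSES = ("LCR", "SDR", "other")

_BASE_AT = np.array(list("AT"))
_BASE_GC = np.array(list("GC"))

# transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


def _stream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Named, deterministic substream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode()), *extra])
    )


@dataclass(frozen=True, slots=True)
class MafSpectrum:
    """Mixture spectrum: a singleton class plus a Beta-distributed rare tail.

    With probability ``p_singleton`` a variant is a singleton (exactly one
    heterozygous carrier in the cohort); otherwise its alternate-allele
    frequency is drawn from Beta(a, b), clipped to (0, 0.5].  The default
    Beta(0.2, 1.2) is U-shaped like a neutral site-frequency spectrum
    (density ~ 1/x near zero with a persistent common component), giving the
    heavily rare-skewed spectrum of large exome cohorts: most segregating
    sites are very rare, yet enough common sites exist that small subsets
    still share most of their discovered variants.
    """

    p_singleton: float = 0.45
    beta_a: float = 0.2
    beta_b: float = 1.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_singleton <= 1.0):
            raise ValueError("p_singleton must be in [0, 1]")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta parameters must be positive")


@dataclass(frozen=True, slots=True)
class CohortModel:
    """Generative parameters for the synthetic truth cohort.

    ``region_model`` gives the target fraction of variant positions falling
    in LCR / SDR / other; ``gc_model`` the mean GC of reference sequence per
    region class; ``ti_fraction`` the probability an alternate allele is a
    transition (0.75 ~ the exome-wide Ti/Tv of 3 expected of good calls).
    """

    n_samples: int = 500
    n_variants: int = 5000
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {str(i): 250_000 for i in range(1, 9)}
    )
    region_model: Mapping[str, float] = field(
        default_factory=lambda: {"LCR": 0.005, "SDR": 0.06, "other": 0.935}
    )
    gc_model: Mapping[str, float] = field(
        default_factory=lambda: {"LCR": 0.30, "SDR": 0.48, "other": 0.45}
    )
    ti_fraction: float = 0.75
    block_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_variants < 0:
            raise ValueError("n_samples must be >= 1 and n_variants >= 0")
        if abs(sum(self.region_model.values()) - 1.0) > 1e-9:
            raise ValueError("region_model fractions must sum to 1")
        for cls in REGION_CLASSES:
            if cls not in self.region_model or cls not in self.gc_model:
                raise ValueError(f"region/gc model must cover {cls!r}")
        if any(l < self.block_size for l in self.chrom_lengths.values()):
            raise ValueError("chromosomes must be at least one block long")

    @property
    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"S{i:0{width}d}" for i in range(1, self.n_samples + 1)]


@dataclass(frozen=True, slots=True)
class NoiseModel:
    """Per-call GQ/DP/AD generative noise for carrier genotypes.

    DP is negative-binomial (mean ``dp_mean``, shape ``dp_shape``) with a
    floor of 1; AD alt reads are Binomial(DP, 0.5) for a heterozygote and
    Binomial(DP, ``hom_alt_read_prob``) for a homozygote; GQ is a capped
    deterministic function of DP (3 per read, max 99) — simple, documented,
    replaceable.
    """

    dp_mean: float = 40.0
    dp_shape: float = 8.0
    het_alt_read_prob: float = 0.5
    hom_alt_read_prob: float = 0.98
    gq_per_read: float = 3.0
    gq_cap: int = 99


@dataclass(frozen=True, slots=True)
class PipelineModel:
    """Detection model for one pipeline configuration (aligner x genotyping).

    ``aligner_sensitivity`` maps region class to the probability a truth
    variant polymorphic in the analyzed subset is detected at all.
    ``joint_rare_dropout`` is the tuple (q_1, q_2, ...): in joint mode a
    detected variant with subset carrier count k is additionally missed with
    probability q_k (zero beyond the tuple).  In single mode each carrier's
    site-call is retained independently with ``single_call_retention`` and
    the variant is emitted iff at least one carrier call survives.
    """

    label: str
    aligner_sensitivity: Mapping[str, float] = field(
        default_factory=lambda: {"LCR": 0.85, "SDR": 0.95, "other": 0.997}
    )
    genotyping_mode: str = "joint"
    joint_rare_dropout: tuple[float, ...] = (0.3, 0.15, 0.07, 0.03)
    single_call_retention: float = 0.995
    per_call_noise: NoiseModel = field(default_factory=NoiseModel)
    pass_mislabel_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.genotyping_mode not in ("joint", "single"):
            raise ValueError("genotyping_mode must be 'joint' or 'single'")
        probs = list(self.aligner_sensitivity.values()) \
            + list(self.joint_rare_dropout) \
            + [self.single_call_retention, self.pass_mislabel_rate]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all model probabilities must lie in [0, 1]")

    def q(self, carrier_count: int) -> float:
        """Joint-genotyping miss probability for a given subset carrier count."""
        if carrier_count < 1:
            return 0.0
        idx = carrier_count - 1
        if idx >= len(self.joint_rare_dropout):
            return 0.0
        return self.joint_rare_dropout[idx]


def default_pipeline_models(
    joint_rare_dropout: tuple[float, ...] = (0.3, 0.15, 0.07, 0.03),
) -> dict[str, PipelineModel]:
    """Four study-like configurations: two aligners x two genotyping modes.

    Aligner A (the default, bwa-like) has lower sensitivity inside segmental
    duplications than aligner B (novo-like), which is slightly weaker
    elsewhere — so each aligner contributes unique calls, with B's advantage
    concentrated in the SDR.
    """
    sens_a = {"LCR": 0.85, "SDR": 0.88, "other": 0.997}
    sens_b = {"LCR": 0.85, "SDR": 0.96, "other": 0.995}
    return {
        "alignerA.joint": PipelineModel(
            label="alignerA.joint", aligner_sensitivity=sens_a,
            genotyping_mode="joint", joint_rare_dropout=joint_rare_dropout),
        "alignerB.joint": PipelineModel(
            label="alignerB.joint", aligner_sensitivity=sens_b,
            genotyping_mode="joint", joint_rare_dropout=joint_rare_dropout),
        "alignerA.single": PipelineModel(
            label="alignerA.single", aligner_sensitivity=sens_a,
            genotyping_mode="single"),
        "alignerB.single": PipelineModel(
            label="alignerB.single", aligner_sensitivity=sens_b,
            genotyping_mode="single"),
    }


@dataclass(slots=True)
class TruthVariant:
    key: VariantKey
    maf: float
    region_class: str
    is_singleton_class: bool


@dataclass(slots=True)
class TruthCohort:
    """Simulation ground truth: variant table + genotype matrix.

    ``genotypes`` is (n_samples, n_variants) int8 with codes 0/1/2 (alternate
    allele dosage); there is no missingness in the truth — missingness is a
    property of the emulated pipelines.
    """

    sample_ids: list[str]
    variants: list[TruthVariant]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("genotype matrix shape mismatch")

    def carrier_counts(self, sample_indices: Optional[np.ndarray] = None) -> np.ndarray:
        g = self.genotypes if sample_indices is None else self.genotypes[sample_indices]
        return (g >= 1).sum(axis=0)

    def sample_index(self, subset: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in subset], dtype=int)
        except KeyError as exc:
            raise ValueError(f"sample {exc.args[0]!r} not in cohort") from exc


# ---------------------------------------------------------------------------
# Reference + regions
# ---------------------------------------------------------------------------

def generate_reference(
    model: CohortModel,
) -> tuple[ReferenceSequence, GenomicRegionSet, GenomicRegionSet]:
    """Random reference with region-dependent GC, plus LCR and SDR BED sets.

    Each chromosome is tiled into ``block_size`` blocks; blocks are assigned
    region classes realizing the model's target fractions (rounded per
    chromosome) at seeded random positions, and bases are drawn i.i.d. with
    the class's GC probability.  Deterministic under the model seed.
    """
    rng = _stream(model.seed, "reference")
    seqs: dict[str, str] = {}
    lcr_iv: list[tuple[str, int, int]] = []
    sdr_iv: list[tuple[str, int, int]] = []
    # allocate region blocks globally so small per-chromosome counts do not
    # round a positive target fraction down to zero blocks
    blocks_per_chrom = {c: l // model.block_size
                        for c, l in model.chrom_lengths.items()}
    total_blocks = sum(blocks_per_chrom.values())
    n_lcr = int(round(total_blocks * model.region_model["LCR"]))
    n_sdr = int(round(total_blocks * model.region_model["SDR"]))
    if model.region_model["LCR"] > 0:
        n_lcr = max(1, n_lcr)
    if model.region_model["SDR"] > 0:
        n_sdr = max(1, n_sdr)
    if n_lcr + n_sdr > total_blocks:
        raise ValueError(f"region fractions infeasible for {total_blocks} "
                         f"total blocks")
    all_blocks = [(c, b) for c, nb in blocks_per_chrom.items()
                  for b in range(nb)]
    special_idx = rng.choice(total_blocks, size=n_lcr + n_sdr, replace=False)
    block_class: dict[tuple[str, int], str] = {}
    for i in special_idx[:n_lcr]:
        block_class[all_blocks[i]] = "LCR"
    for i in special_idx[n_lcr:]:
        block_class[all_blocks[i]] = "SDR"
    for chrom, length in model.chrom_lengths.items():
        n_blocks = blocks_per_chrom[chrom]
        classes = [block_class.get((chrom, b), "other")
                   for b in range(n_blocks)]
        parts: list[str] = []
        for b, cls in enumerate(classes):
            start = b * model.block_size
            end = min(length, (b + 1) * model.block_size) if b < n_blocks - 1 \
                else length  # last block absorbs the remainder
            size = end - start
            p_gc = model.gc_model[cls]
            is_gc = rng.random(size) < p_gc
            half = rng.integers(0, 2, size=size)
            bases = np.where(is_gc, _BASE_GC[half], _BASE_AT[half])
            parts.append("".join(bases))
            if cls == "LCR":
                lcr_iv.append((chrom, start, end))
            elif cls == "SDR":
                sdr_iv.append((chrom, start, end))
        seqs[chrom] = "".join(parts)
    return (
        ReferenceSequence(seqs),
        GenomicRegionSet(label="LCR", intervals=lcr_iv),
        GenomicRegionSet(label="SDR", intervals=sdr_iv),
    )


# ---------------------------------------------------------------------------
# Truth cohort
# ---------------------------------------------------------------------------

def generate_truth_cohort(
    model: CohortModel,
    reference: Optional[ReferenceSequence] = None,
    lcr: Optional[GenomicRegionSet] = None,
    sdr: Optional[GenomicRegionSet] = None,
) -> TruthCohort:
    """Draw the truth variant table and Hardy-Weinberg genotype matrix.

    Variant positions are drawn uniformly within region classes according to
    the region model; each variant's frequency comes from the MAF spectrum;
    genotypes are sampled independently per sample under Hardy-Weinberg at
    the drawn frequency, except singleton-class variants, which are placed as
    a single heterozygous carrier.  The reference (for ref alleles and region
    layout) is regenerated from the model seed when not supplied.
    """
    if reference is None or lcr is None or sdr is None:
        reference, lcr, sdr = generate_reference(model)
    rng = _stream(model.seed, "cohort")

    # candidate segments per class from the realized region layout, so
    # positions can be drawn by offset without materializing every base
    class_segments: dict[str, list[tuple[str, int, int]]] = {c: [] for c in REGION_CLASSES}
    for chrom in reference.chroms():
        length = reference.length(chrom)
        special = sorted(
            [(s, e, "LCR") for c, s, e in lcr.intervals if c == chrom]
            + [(s, e, "SDR") for c, s, e in sdr.intervals if c == chrom]
        )
        cursor = 0
        for s, e, cls in special:
            if s > cursor:
                class_segments["other"].append((chrom, cursor, s))
            class_segments[cls].append((chrom, s, e))
            cursor = e
        if cursor < length:
            class_segments["other"].append((chrom, cursor, length))

    n_by_class = {
        cls: int(round(model.n_variants * model.region_model[cls]))
        for cls in REGION_CLASSES
    }
    n_by_class["other"] += model.n_variants - sum(n_by_class.values())

    def _draw_positions(cls: str, n: int) -> list[tuple[str, int]]:
        segs = class_segments[cls]
        sizes = np.array([e - s for _, s, e in segs], dtype=np.int64)
        total = int(sizes.sum())
        if n > total:
            raise ValueError(f"n_variants exceeds available {cls} positions "
                             f"({n} > {total})")
        cum = np.concatenate([[0], np.cumsum(sizes)])
        offsets = rng.choice(total, size=n, replace=False)
        out = []
        for off in offsets:
            i = int(np.searchsorted(cum, off, side="right")) - 1
            chrom, s, _ = segs[i]
            out.append((chrom, s + int(off - cum[i]) + 1))  # 1-based
        return out

    spectrum = model.maf_spectrum
    variants: list[TruthVariant] = []
    geno_cols: list[np.ndarray] = []
    for cls in REGION_CLASSES:
        n = n_by_class[cls]
        if n == 0:
            continue
        for chrom, pos in _draw_positions(cls, n):
            ref = reference.base(chrom, pos)
            if rng.random() < model.ti_fraction:
                alt = _TRANSITION[ref]
            else:
                alt = _TRANSVERSIONS[ref][rng.integers(0, 2)]
            key = VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)
            is_singleton = rng.random() < spectrum.p_singleton
            col = np.zeros(model.n_samples, dtype=np.int8)
            if is_singleton:
                maf = 1.0 / (2 * model.n_samples)
                col[rng.integers(0, model.n_samples)] = 1
            else:
                maf = float(min(0.5, rng.beta(spectrum.beta_a, spectrum.beta_b)))
                draws = rng.random((model.n_samples, 2)) < maf
                col = draws.sum(axis=1).astype(np.int8)
            variants.append(TruthVariant(key=key, maf=maf, region_class=cls,
                                         is_singleton_class=is_singleton))
            geno_cols.append(col)

    # sort variants (and genotype columns) by genomic coordinate
    order = sorted(range(len(variants)), key=lambda i: variants[i].key.sort_key())
    variants = [variants[i] for i in order]
    genotypes = (np.stack([geno_cols[i] for i in order], axis=1)
                 if variants else np.zeros((model.n_samples, 0), dtype=np.int8))
    return TruthCohort(sample_ids=model.sample_ids, variants=variants,
                       genotypes=genotypes)


# ---------------------------------------------------------------------------
# Pipeline emulation
# ---------------------------------------------------------------------------

def emulate_pipeline(
    truth: TruthCohort,
    pipeline: PipelineModel,
    subset: Sequence[str],
    seed: int,
) -> CallSet:
    """Emulate one pipeline configuration's call-set on a sample subset.

    For each truth variant polymorphic within the subset: it is detected with
    the aligner's region-class sensitivity; in joint mode it is additionally
    missed with probability q_k for subset carrier count k, and every subset
    sample receives a genotype; in single mode each carrier's site-call is
    independently retained and the variant is emitted iff one survives, with
    non-carriers left as no-calls (reference and no-call being
    indistinguishable without joint evidence).  Carrier genotypes receive
    GQ/DP/AD from the noise model; FILTER is PASS except with the pipeline's
    mislabel rate.  Deterministic given (truth, pipeline, subset, seed).
    """
    rng = _stream(seed, "pipeline", zlib.crc32(pipeline.label.encode()))
    sub_idx = truth.sample_index(subset)
    g = truth.genotypes[sub_idx]  # (n_sub, n_var)
    n_sub, n_var = g.shape
    carriers = (g >= 1).sum(axis=0)
    polymorphic = carriers >= 1

    region = np.array([v.region_class for v in truth.variants], dtype=object)
    sens = np.array([pipeline.aligner_sensitivity[r] for r in region])
    detected = polymorphic & (rng.random(n_var) < sens)

    noise = pipeline.per_call_noise
    cs = CallSet(label=pipeline.label, roster=tuple(subset))

    if pipeline.genotyping_mode == "joint":
        qk = np.array([pipeline.q(int(k)) for k in carriers])
        keep = detected & (rng.random(n_var) >= qk)
        emit_idx = np.flatnonzero(keep)
        carrier_rows = [np.flatnonzero(g[:, j] >= 1) for j in emit_idx]
    else:
        emit_idx_all = np.flatnonzero(detected)
        emit_idx_list: list[int] = []
        carrier_rows = []
        for j in emit_idx_all:
            rows = np.flatnonzero(g[:, j] >= 1)
            kept = rows[rng.random(rows.size) < pipeline.single_call_retention]
            if kept.size:
                emit_idx_list.append(j)
                carrier_rows.append(kept)
        emit_idx = np.array(emit_idx_list, dtype=int)

    # vectorized per-carrier noise over all emitted records
    n_carrier_calls = int(sum(r.size for r in carrier_rows))
    dp = np.maximum(
        1, rng.negative_binomial(
            noise.dp_shape,
            noise.dp_shape / (noise.dp_shape + noise.dp_mean),
            size=n_carrier_calls)
    )
    mislabel = rng.random(emit_idx.size) < pipeline.pass_mislabel_rate

    ptr = 0
    for rec_i, j in enumerate(emit_idx):
        var = truth.variants[j]
        rows = carrier_rows[rec_i]
        calls: dict[str, GenotypeCall] = (
            dict.fromkeys(subset, HOM_REF)
            if pipeline.genotyping_mode == "joint" else {}
        )
        for r in rows:
            d = int(dp[ptr])
            dosage = int(g[r, j])
            p_alt = noise.het_alt_read_prob if dosage == 1 else noise.hom_alt_read_prob
            alt_reads = int(rng.binomial(d, p_alt))
            gq = min(noise.gq_cap, int(noise.gq_per_read * d))
            calls[subset[r]] = GenotypeCall(
                alleles=(0, 1) if dosage == 1 else (1, 1),
                gq=gq, dp=d, ad=(d - alt_reads, alt_reads),
            )
            ptr += 1
        cs.add(VariantRecord(
            key=var.key,
            filter_label="VQSRTrancheSNP99.00to99.90" if mislabel[rec_i] else "PASS",
            calls=calls,
        ))
    return cs


def make_provider(truth: TruthCohort, pipeline: PipelineModel):
    """Adapt (truth, pipeline) to the subsample_experiment provider signature."""
    def provider(subset: Sequence[str], seed: int) -> CallSet:
        return emulate_pipeline(truth, pipeline, subset, seed)
    return provider


# ---------------------------------------------------------------------------
# Study bundle
# ---------------------------------------------------------------------------

def _write_truth_table(truth: TruthCohort, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tmaf\tregion_class\tis_singleton_class"
                 "\tcarrier_count\n")
        cc = truth.carrier_counts()
        for i, v in enumerate(truth.variants):
            fh.write(f"{v.key.chrom}\t{v.key.pos}\t{v.key.ref}\t{v.key.alt}\t"
                     f"{v.maf:.8g}\t{v.region_class}\t"
                     f"{int(v.is_singleton_class)}\t{int(cc[i])}\n")


def _synthesize_annotations(truth: TruthCohort, rng: np.random.Generator):
    """Illustrative consequence/CADD annotations for every truth variant.

    Tier composition is drawn exome-like (a few percent tier 1, roughly half
    non-synonymous); CADD PHRED is normal(15, 6) clipped at 0.
    """
    from varrescue.annotation_tiers import AnnotationRecord
    tier_terms = {
        1: ("stopgain", "stoploss", "splicing"),
        2: ("nonsynonymous SNV",),
        3: ("synonymous SNV", "intronic", "UTR3", "UTR5"),
    }
    annotations = {}
    tiers = rng.choice([1, 2, 3], size=len(truth.variants), p=[0.03, 0.47, 0.50])
    cadd = np.clip(rng.normal(15.0, 6.0, size=len(truth.variants)), 0.0, None)
    for i, v in enumerate(truth.variants):
        terms = tier_terms[int(tiers[i])]
        annotations[v.key] = AnnotationRecord(
            key=v.key,
            consequences=(terms[rng.integers(0, len(terms))],),
            cadd_phred=float(round(cadd[i], 2)),
        )
    return annotations


def _synthesize_sample_metrics(sample_ids: Sequence[str],
                               rng: np.random.Generator):
    """Mostly-passing per-sample QC metrics with a sprinkling of failures."""
    from varrescue.sample_qc import SampleMetrics
    out = []
    n = len(sample_ids)
    cov10 = np.clip(rng.normal(0.96, 0.02, n), 0, 1)
    cov40 = np.clip(rng.normal(0.45, 0.08, n), 0, 1)
    cr = np.clip(rng.normal(0.985, 0.01, n), 0, 1)
    titv = rng.normal(3.0, 0.08, n)
    freemix = np.clip(rng.exponential(0.005, n), 0, 1)
    is_male = rng.random(n) < 0.5
    sex_f = np.where(is_male,
                     np.clip(rng.normal(0.95, 0.05, n), -1, 1),
                     np.clip(rng.normal(0.02, 0.08, n), -1, 1))
    apoe_ok = rng.random(n) > 0.01
    for i, sid in enumerate(sample_ids):
        out.append(SampleMetrics(
            sample_id=sid,
            frac_target_ge_10x=float(round(cov10[i], 4)),
            frac_target_ge_40x=float(round(cov40[i], 4)),
            call_rate=float(round(cr[i], 4)),
            titv=float(round(titv[i], 3)),
            freemix=float(round(freemix[i], 5)),
            sex_f=float(round(sex_f[i], 3)),
            reported_sex="male" if is_male[i] else "female",
            apoe_match=bool(apoe_ok[i]),
        ))
    return out


def generate_study_bundle(
    cohort_model: CohortModel,
    pipeline_models: Sequence[PipelineModel],
    out_dir,
    seed: Optional[int] = None,
    known_prob: float = 0.78,
) -> dict:
    """Write a complete, self-consistent input set for the analysis pipeline.

    Emits reference FASTA, LCR/SDR BEDs, one VCF per pipeline model (each
    pipeline applied to the full cohort), an annotation TSV, a known-variant
    key list (each truth variant indexed with probability ``known_prob``),
    a sample-metrics TSV, and the truth tables used by oracle checks.
    Returns a manifest dict of the written paths.  Deterministic under seed.
    """
    if len(pipeline_models) < 2:
        raise ValueError("need at least two pipeline models")
    seed = cohort_model.seed if seed is None else seed
    if seed != cohort_model.seed:
        cohort_model = CohortModel(
            **{**{f: getattr(cohort_model, f) for f in (
                "n_samples", "n_variants", "maf_spectrum", "chrom_lengths",
                "region_model", "gc_model", "ti_fraction", "block_size")},
               "seed": seed},
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    reference, lcr, sdr = generate_reference(cohort_model)
    truth = generate_truth_cohort(cohort_model, reference, lcr, sdr)

    manifest: dict = {"seed": seed, "out_dir": str(out_dir), "vcfs": {}}
    write_fasta(reference, out_dir / "reference.fa")
    manifest["reference"] = str(out_dir / "reference.fa")
    write_bed(lcr, out_dir / "lcr.bed")
    write_bed(sdr, out_dir / "sdr.bed")
    manifest["lcr_bed"] = str(out_dir / "lcr.bed")
    manifest["sdr_bed"] = str(out_dir / "sdr.bed")

    for pm in pipeline_models:
        cs = emulate_pipeline(truth, pm, truth.sample_ids,
                              seed=int(_stream(seed, "vcfseed",
                                               zlib.crc32(pm.label.encode()))
                                       .integers(0, 2 ** 31)))
        vcf_path = out_dir / f"{pm.label}.vcf"
        write_vcf(cs, vcf_path)
        manifest["vcfs"][pm.label] = str(vcf_path)

    from varrescue.annotation_tiers import (
        write_annotation_table, write_key_list,
    )
    ann_rng = _stream(seed, "annotations")
    annotations = _synthesize_annotations(truth, ann_rng)
    write_annotation_table(annotations, out_dir / "annotations.tsv")
    manifest["annotations"] = str(out_dir / "annotations.tsv")

    known = [v.key for v in truth.variants if ann_rng.random() < known_prob]
    write_key_list(known, out_dir / "known_variants.tsv")
    manifest["known_index"] = {"synthetic_db": str(out_dir / "known_variants.tsv")}

    from varrescue.sample_qc import write_metrics_table
    metrics = _synthesize_sample_metrics(truth.sample_ids, _stream(seed, "metrics"))
    write_metrics_table(metrics, out_dir / "sample_metrics.tsv")
    manifest["sample_metrics"] = str(out_dir / "sample_metrics.tsv")

    _write_truth_table(truth, out_dir / "truth_variants.tsv")
    manifest["truth_variants"] = str(out_dir / "truth_variants.tsv")
    return manifest
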