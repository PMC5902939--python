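"""Cross-pipeline set algebra: pairwise comparison, N-way union with
provenance, the repeated-subsampling experiment, and 2x2 rescue categories.

Variant identity across pipelines is the exact :class:`~varrescue.vcf_io.VariantKey`
— no position-window or allele-normalization fuzziness — because all compared
call-sets are bi-allelic SNVs on the same reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from varrescue.vcf_io import CallSet, VariantKey, VariantRecord

# A pipeline emulator / provider: given a sample subset and a seed, produce
# that pipeline configuration's call-set on the subset.
PipelineProvider = Callable[[Sequence[str], int], CallSet]


@dataclass(frozen=True, slots=True)
class ComparisonResult:
    """Unique/shared/union counts and percentages for a pair of call-sets."""

    label_a: str
    label_b: str
    unique_a: int
    unique_b: int
    shared: int

    @property
    def union_size(self) -> int:
        return self.unique_a + self.unique_b + self.shared

    @property
    def pct_unique_a(self) -> float:
        return 100.0 * self.unique_a / self.union_size

    @property
    def pct_unique_b(self) -> float:
        return 100.0 * self.unique_b / self.union_size

    @property
    def pct_shared(self) -> float:
        return 100.0 * self.shared / self.union_size

    def swapped(self) -> "ComparisonResult":
        return ComparisonResult(self.label_b, self.label_a,
                                self.unique_b, self.unique_a, self.shared)

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a, "label_b": self.label_b,
            "unique_a": self.unique_a, "unique_b": self.unique_b,
            "shared": self.shared, "union_size": self.union_size,
            "pct_unique_a": self.pct_unique_a,
            "pct_unique_b": self.pct_unique_b,
            "pct_shared": self.pct_shared,
        }


def compare(a: CallSet, b: CallSet) -> ComparisonResult:
    """Compare two call-sets by variant key only (genotypes ignored).

    Raises ValueError when the union is empty (percentages undefined).
    """
    ka, kb = a.keys(), b.keys()
    shared = len(ka & kb)
    result = ComparisonResult(
        label_a=a.label, label_b=b.label,
        unique_a=len(ka) - shared, unique_b=len(kb) - shared, shared=shared,
    )
    if result.union_size == 0:
        raise ValueError("cannot compare two empty call-sets (empty union)")
    return result


def comparison_groups(a: CallSet, b: CallSet) -> dict[str, set[VariantKey]]:
    """The three key groups underlying a comparison: unique_a / unique_b / shared."""
    ka, kb = a.keys(), b.keys()
    return {"unique_a": ka - kb, "unique_b": kb - ka, "shared": ka & kb}


def union_merge(
    callsets: Sequence[CallSet],
    reconcile_rosters: bool = False,
) -> tuple[CallSet, dict[VariantKey, tuple[str, ...]]]:
    """Merge N call-sets into one record per union key, with provenance.

    Genotypes are carried from the first input containing each key (per-source
    genotypes are not reconciled into a consensus).  The provenance map lists,
    per key, the labels of every input that contained it.  Inputs must share a
    roster unless ``reconcile_rosters=True``, in which case the union roster
    is used.
    """
    if not callsets:
        raise ValueError("union_merge requires at least one call-set")
    rosters = {cs.roster for cs in callsets}
    if len(rosters) > 1 and not reconcile_rosters:
        raise ValueError(
            "call-sets have conflicting rosters; pass reconcile_rosters=True "
            "to merge over the union roster"
        )
    if len(rosters) == 1:
        roster = callsets[0].roster
    else:
        seen: dict[str, None] = {}
        for cs in callsets:
            for s in cs.roster:
                seen.setdefault(s)
        roster = tuple(seen)
    label = "+".join(cs.label for cs in callsets)
    merged = CallSet(label=label, roster=roster)
    provenance: dict[VariantKey, tuple[str, ...]] = {}
    for cs in callsets:
        for key, rec in cs.records.items():
            if key not in merged.records:
                merged.records[key] = rec
                provenance[key] = (cs.label,)
            else:
                provenance[key] = provenance[key] + (cs.label,)
    return merged, provenance


@dataclass(frozen=True, slots=True)
class SubsampleDesign:
    """Sizes, replicate count and master seed for the subsampling experiment.

    Mirrors the study design: at each cohort size below the largest, subsets
    are drawn 5 times and summaries averaged; the largest size is drawn once
    when ``largest_once`` (it exhausts the pool, so replicates would coincide).
    """

    sizes: tuple[int, ...] = (50, 100, 200, 500, 1000)
    replicates: int = 5
    seed: int = 0
    largest_once: bool = True

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(s < 1 for s in self.sizes):
            raise ValueError("sizes must be positive")

    def replicates_for(self, size: int, pool_size: int) -> int:
        if self.largest_once and size >= pool_size:
            return 1
        if self.largest_once and size == max(self.sizes):
            return 1
        return self.replicates


def subset_seed(master_seed: int, size: int, replicate: int) -> int:
    """Deterministic sub-seed for one (size, replicate) cell, < 2**31."""
    ss = np.random.SeedSequence([master_seed, size, replicate])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass(slots=True)
class SubsampleSummary:
    """Per-size replicate comparisons plus mean/SD of the percentage fields."""

    label_a: str
    label_b: str
    sizes: tuple[int, ...]
    # size -> list of ComparisonResult, one per replicate
    replicates: dict[int, list[ComparisonResult]] = field(default_factory=dict)

    def _stat(self, size: int, attr: str) -> tuple[float, float]:
        vals = [getattr(r, attr) for r in self.replicates[size]]
        return float(np.mean(vals)), float(np.std(vals, ddof=0))

    def mean_pct_shared(self, size: int) -> float:
        return self._stat(size, "pct_shared")[0]

    def sd_pct_shared(self, size: int) -> float:
        return self._stat(size, "pct_shared")[1]

    def mean_pct_unique_a(self, size: int) -> float:
        return self._stat(size, "pct_unique_a")[0]

    def mean_pct_unique_b(self, size: int) -> float:
        return self._stat(size, "pct_unique_b")[0]

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "sizes": list(self.sizes),
            "per_size": {
                str(size): {
                    "n_replicates": len(reps),
                    "mean_pct_shared": self.mean_pct_shared(size),
                    "sd_pct_shared": self.sd_pct_shared(size),
                    "mean_pct_unique_a": self.mean_pct_unique_a(size),
                    "mean_pct_unique_b": self.mean_pct_unique_b(size),
                    "replicates": [r.to_dict() for r in reps],
                }
                for size, reps in self.replicates.items()
            },
        }


def subsample_experiment(
    pool: Sequence[str],
    pipelines: Sequence[PipelineProvider],
    design: SubsampleDesign,
    pipeline_labels: Optional[Sequence[str]] = None,
) -> SubsampleSummary:
    """Draw seeded subsets at each design size, run both pipelines, compare.

    For each size, ``design.replicates`` subsets are drawn uniformly without
    replacement (one replicate at the largest size when it equals the pool or
    ``largest_once``); the first two pipeline providers are invoked on each
    subset and their call-sets compared.  Every draw and every provider call
    is seeded from a deterministic (size, replicate) sub-seed of the master
    seed, so the experiment is reproducible and each cell individually
    re-runnable.
    """
    if len(pipelines) < 2:
        raise ValueError("subsample_experiment requires at least two pipelines")
    pool = list(pool)
    for size in design.sizes:
        if size > len(pool):
            raise ValueError(f"subsample size {size} exceeds pool size {len(pool)}")
    labels = list(pipeline_labels) if pipeline_labels else None
    summary: Optional[SubsampleSummary] = None
    for size in design.sizes:
        n_rep = design.replicates_for(size, len(pool))
        for rep in range(n_rep):
            sseed = subset_seed(design.seed, size, rep)
            rng = np.random.default_rng(sseed)
            subset = [pool[i] for i in rng.choice(len(pool), size=size, replace=False)]
            try:
                cs_a = pipelines[0](subset, sseed)
                cs_b = pipelines[1](subset, sseed + 1)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline failed at size={size} replicate={rep}: {exc}"
                ) from exc
            result = compare(cs_a, cs_b)
            if summary is None:
                la = labels[0] if labels else result.label_a
                lb = labels[1] if labels else result.label_b
                summary = SubsampleSummary(label_a=la, label_b=lb,
                                           sizes=tuple(design.sizes))
            summary.replicates.setdefault(size, []).append(result)
    assert summary is not None
    return summary


RESCUE_CATEGORIES = (
    "shared_all",
    "default_only",
    "rescued_by_aligner",
    "rescued_by_genotyping",
    "rescued_by_both",
    "other",
)


@dataclass(slots=True)
class RescueResult:
    """Per-key presence flags across up to four pipeline configurations and
    the rescue category each key falls in.

    Categories partition the union of keys.  A key is *rescued* when it is
    absent from the default joint call-set but present in an alternate
    aligner's joint set (``rescued_by_aligner``), in a single-sample set only
    (``rescued_by_genotyping``), or in both kinds of alternative
    (``rescued_by_both``).  Precedence for the label is aligner -> genotyping
    -> both; full presence flags are kept so users can re-cut.
    """

    set_labels: tuple[str, ...]
    presence: dict[VariantKey, tuple[bool, ...]] = field(default_factory=dict)
    category: dict[VariantKey, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in RESCUE_CATEGORIES}
        for cat in self.category.values():
            out[cat] += 1
        return out

    @property
    def union_size(self) -> int:
        return len(self.presence)

    @property
    def n_rescued(self) -> int:
        c = self.counts
        return (c["rescued_by_aligner"] + c["rescued_by_genotyping"]
                + c["rescued_by_both"])

    @property
    def pct_rescued(self) -> float:
        return 100.0 * self.n_rescued / self.union_size

    def keys_in_category(self, cat: str) -> set[VariantKey]:
        return {k for k, c in self.category.items() if c == cat}

    def to_dict(self) -> dict:
        return {
            "set_labels": list(self.set_labels),
            "union_size": self.union_size,
            "counts": self.counts,
            "n_rescued": self.n_rescued,
            "pct_rescued": self.pct_rescued,
        }


def rescue_sets(
    default: CallSet,
    alt_aligner: Optional[CallSet] = None,
    single_gt: Optional[CallSet] = None,
    alt_single_gt: Optional[CallSet] = None,
) -> RescueResult:
    """Categorize every union key by which pipeline configurations carry it.

    ``default`` is the default aligner's joint-genotyping call-set;
    ``alt_aligner`` the alternate aligner's joint set; ``single_gt`` and
    ``alt_single_gt`` single-sample-genotyping sets.  At least two call-sets
    are required.  Category rules:

    * ``shared_all`` — present in every provided set;
    * ``default_only`` — present in the default set only (not a rescue);
    * ``rescued_by_aligner`` — absent from default, present in the alternate
      aligner's joint set but in no single-sample set;
    * ``rescued_by_genotyping`` — absent from both joint sets, present in a
      single-sample set;
    * ``rescued_by_both`` — absent from default, present in the alternate
      aligner's joint set *and* a single-sample set;
    * ``other`` — any remaining pattern (present in default plus a strict
      subset of the alternatives).
    """
    provided = [("default", default)]
    if alt_aligner is not None:
        provided.append(("alt_aligner", alt_aligner))
    if single_gt is not None:
        provided.append(("single_gt", single_gt))
    if alt_single_gt is not None:
        provided.append(("alt_single_gt", alt_single_gt))
    if len(provided) < 2:
        raise ValueError("rescue_sets requires at least two call-sets")

    roles = [role for role, _ in provided]
    keysets = {role: cs.keys() for role, cs in provided}
    union: set[VariantKey] = set().union(*keysets.values())
    result = RescueResult(set_labels=tuple(cs.label for _, cs in provided))
    single_roles = [r for r in roles if r in ("single_gt", "alt_single_gt")]
    for key in union:
        flags = tuple(key in keysets[r] for r in roles)
        result.presence[key] = flags
        in_default = key in keysets["default"]
        in_alt = "alt_aligner" in keysets and key in keysets["alt_aligner"]
        in_single = any(key in keysets[r] for r in single_roles)
        if all(flags):
            cat = "shared_all"
        elif in_default and not in_alt and not in_single:
            cat = "default_only"
        elif not in_default and in_alt and in_single:
            cat = "rescued_by_both"
        elif not in_default and in_alt:
            cat = "rescued_by_aligner"
        elif not in_default and in_single:
            cat = "rescued_by_genotyping"
        else:
            cat = "other"
        result.category[key] = cat
    return result


def write_rescue_tsv(result: RescueResult, path) -> None:
    """One row per union key: key fields, per-set presence flags, category."""
    roles = result.set_labels
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\t"
                 + "\t".join(f"in_{lbl}" for lbl in roles) + "\tcategory\n")
        for key in sorted(result.presence, key=lambda k: k.sort_key()):
            flags = result.presence[key]
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                     + "\t".join("1" if f else "0" for f in flags)
                     + f"\t{result.category[key]}\n")
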