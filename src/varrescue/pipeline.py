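"""End-to-end orchestration: filter -> compare/rescue -> profile -> report.

:func:`run_pipeline` wires the I/O, filtering, set-algebra and profiling
layers into one deterministic run over a :class:`RunConfig`, writing TSV
reports plus a JSON summary that contains every count and percentage needed
to redraw the headline pairwise-comparison and rescue figures.  Outputs embed
the config hash and master seed for provenance; identical config + seed
yields byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from varrescue.annotation_tiers import (
    KnownVariantIndex,
    read_annotation_table,
    read_key_list,
)
from varrescue.callset_algebra import (
    compare,
    comparison_groups,
    rescue_sets,
    union_merge,
    write_rescue_tsv,
)
from varrescue.quality_metrics import build_quality_profile, write_metric_table
from varrescue.sample_qc import apply_sample_qc, read_metrics_table, write_qc_report
from varrescue.vcf_io import (
    CallSet,
    filter_pass_biallelic_snv,
    read_bed,
    read_fasta,
    read_vcf,
)

logger = logging.getLogger("varrescue")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(slots=True)
class RunConfig:
    """Inputs, filter settings and output location for one pipeline run.

    ``vcfs`` maps pipeline labels to VCF paths.  Labels containing
    ``.single`` select single-sample-genotyping semantics for that call-set:
    no call-rate filter and carrier counts instead of BAF.  For the rescue
    categorization, ``default_label`` names the default joint call-set and
    ``alt_aligner_label`` / ``single_labels`` the alternatives.
    """

    vcfs: dict[str, str]
    out_dir: str
    reference: Optional[str] = None
    lcr_bed: Optional[str] = None
    sdr_bed: Optional[str] = None
    annotations: Optional[str] = None
    known_index: dict[str, str] = field(default_factory=dict)
    sample_metrics: Optional[str] = None
    min_call_rate: Optional[float] = 0.9
    default_label: Optional[str] = None
    alt_aligner_label: Optional[str] = None
    single_labels: tuple[str, ...] = ()
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.vcfs:
            raise ValueError("config names no input VCFs")
        if len(set(self.vcfs)) != len(self.vcfs):
            raise ValueError("pipeline labels must be unique")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["known_index"] = dict(sorted(self.known_index.items()))
        d["single_labels"] = list(self.single_labels)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON."""
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["vcfs"] = dict(data["vcfs"])
        if "known_index" in data:
            data["known_index"] = dict(data["known_index"])
        if "single_labels" in data:
            data["single_labels"] = tuple(data["single_labels"])
        return cls(**data)


def _is_single(config: RunConfig, label: str) -> bool:
    return label in config.single_labels or ".single" in label


def _load_inputs(config: RunConfig):
    for label, path in config.vcfs.items():
        if not Path(path).exists():
            raise PipelineError(f"stage=load: VCF for label {label!r} "
                                f"not found at {path}")
    reference = read_fasta(config.reference) if config.reference else None
    lcr = read_bed(config.lcr_bed, "LCR") if config.lcr_bed else None
    sdr = read_bed(config.sdr_bed, "SDR") if config.sdr_bed else None
    annotations = (read_annotation_table(config.annotations)
                   if config.annotations else None)
    known = None
    if config.known_index:
        known = KnownVariantIndex(
            {lbl: read_key_list(p) for lbl, p in config.known_index.items()}
        )
    return reference, lcr, sdr, annotations, known


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Stages: read + filter each call-set (PASS, bi-allelic SNV, call rate for
    joint sets); pairwise comparison of the first two call-sets; rescue
    categorization when a default label and alternatives are configured;
    quality profile per comparison group; optional sample QC.  Returns the
    JSON-serializable summary (also written to ``out_dir/summary.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    file_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    file_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(file_handler)

    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "filter": {},
        "comparisons": {},
        "rescue": None,
        "profiles": {},
        "sample_qc": None,
    }
    try:
        reference, lcr, sdr, annotations, known = _load_inputs(config)

        filtered: dict[str, CallSet] = {}
        for label, path in config.vcfs.items():
            raw = read_vcf(path, label)
            single = _is_single(config, label)
            mcr = None if single else config.min_call_rate
            cs = filter_pass_biallelic_snv(raw, min_call_rate=mcr)
            filtered[label] = cs
            summary["filter"][label] = {
                "n_input": len(raw),
                "n_retained": len(cs),
                "mode": "single" if single else "joint",
                "min_call_rate": mcr,
            }
            logger.info("filter %s: %d -> %d records (mode=%s)",
                        label, len(raw), len(cs),
                        "single" if single else "joint")

        labels = list(filtered)
        profile_jobs: list[tuple[str, CallSet, set, bool]] = []

        if len(labels) >= 2:
            a, b = filtered[labels[0]], filtered[labels[1]]
            result = compare(a, b)
            summary["comparisons"][f"{labels[0]}__vs__{labels[1]}"] = result.to_dict()
            groups = comparison_groups(a, b)
            merged, _ = union_merge([a, b], reconcile_rosters=True)
            single_mode = _is_single(config, labels[0]) or _is_single(config, labels[1])
            for gname, keys in groups.items():
                if keys:
                    profile_jobs.append(
                        (f"{gname}", merged, keys, not single_mode))

        if config.default_label:
            if config.default_label not in filtered:
                raise PipelineError(
                    f"stage=rescue: default label {config.default_label!r} "
                    f"has no VCF")
            alt = (filtered.get(config.alt_aligner_label)
                   if config.alt_aligner_label else None)
            singles = [filtered[l] for l in config.single_labels if l in filtered]
            rescue = rescue_sets(
                default=filtered[config.default_label],
                alt_aligner=alt,
                single_gt=singles[0] if singles else None,
                alt_single_gt=singles[1] if len(singles) > 1 else None,
            )
            summary["rescue"] = rescue.to_dict()
            write_rescue_tsv(rescue, out_dir / "rescue.tsv")
            logger.info("rescue: %d/%d union keys rescued (%.2f%%)",
                        rescue.n_rescued, rescue.union_size, rescue.pct_rescued)

        for gname, cs, keys, compute_baf in profile_jobs:
            profile = build_quality_profile(
                cs, keys, group_label=gname,
                reference=reference, lcr=lcr, sdr=sdr,
                annotations=annotations, known_index=known,
                compute_baf=compute_baf,
            )
            summary["profiles"][gname] = profile.to_dict()
            write_metric_table(cs, keys, out_dir / f"metrics_{gname}.tsv",
                               reference=reference, lcr=lcr, sdr=sdr,
                               compute_baf=compute_baf)

        if config.sample_metrics:
            metrics = read_metrics_table(config.sample_metrics)
            report = apply_sample_qc(metrics)
            summary["sample_qc"] = report.to_dict()
            write_qc_report(report, out_dir / "sample_qc.tsv")
            logger.info("sample QC: retained %d of %d",
                        len(report.retained), len(report.verdicts))

        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage=run: {exc}") from exc
    finally:
        logger.removeHandler(file_handler)
        file_handler.close()
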