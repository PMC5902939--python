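"""Sample- and population-level QC as a threshold cascade over supplied metrics.

The cascade mirrors standard exome QC practice: per-sample coverage of the
capture target, variant call rate, Ti/Tv ratio, sequence-based contamination
(FREEMIX), an X-chromosome inbreeding-coefficient sex check, APOE genotype
concordance with sample metadata, and cohort-level relatedness / ancestry /
batch flags.  The upstream estimators (verifyBamID, PCA, kinship) are out of
scope — their outputs are consumed as a metrics table.

Default thresholds:

==================  =========================================================
coverage            >= 90% of target at 10x AND >= 30% of target at 40x
call rate           >= 0.95
Ti/Tv               >= 2.8
FREEMIX             fail only when strictly > 0.02
sex check           male fails when F < 0.7; female fails when F > 0.3
APOE concordance    fail when the exome-derived genotype mismatches metadata
==================  =========================================================

Criteria 1-3 use "at least" (inclusive) semantics; contamination and the sex
check are strict inequalities as conventionally stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

CRITERIA = (
    "coverage",
    "call_rate",
    "titv",
    "contamination",
    "sex_check",
    "apoe_concordance",
    "relatedness",
    "ancestry",
    "batch",
)


@dataclass(frozen=True, slots=True)
class SampleMetrics:
    """One sample's QC inputs.  ``None`` marks a metric that was not supplied."""

    sample_id: str
    frac_target_ge_10x: Optional[float] = None
    frac_target_ge_40x: Optional[float] = None
    call_rate: Optional[float] = None
    titv: Optional[float] = None
    freemix: Optional[float] = None
    sex_f: Optional[float] = None
    reported_sex: str = "unknown"  # male / female / unknown
    apoe_match: Optional[bool] = None
    relatedness_flag: bool = False
    ancestry_flag: bool = False
    batch_flag: bool = False

    def __post_init__(self) -> None:
        for name in ("frac_target_ge_10x", "frac_target_ge_40x", "call_rate",
                     "freemix"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.titv is not None and self.titv <= 0:
            raise ValueError(f"titv must be positive, got {self.titv}")
        if self.reported_sex not in ("male", "female", "unknown"):
            raise ValueError(f"reported_sex must be male/female/unknown, "
                             f"got {self.reported_sex!r}")


@dataclass(frozen=True, slots=True)
class QCThresholds:
    """The cascade's tunable thresholds, defaulting to standard exome values."""

    min_frac_target_ge_10x: float = 0.90
    min_frac_target_ge_40x: float = 0.30
    min_call_rate: float = 0.95
    min_titv: float = 2.8
    max_freemix: float = 0.02          # fail requires strictly greater
    male_min_sex_f: float = 0.7        # male fails when F < this
    female_max_sex_f: float = 0.3      # female fails when F > this
    strict_missing: bool = False       # True: missing metric fails the sample


@dataclass(slots=True)
class QCReport:
    """Per-sample, per-criterion verdicts plus the retained sample list.

    ``verdicts[sample][criterion]`` is "pass", "fail" or "indeterminate".
    A sample may fail several criteria; it is retained iff it fails none.
    Indeterminate criteria (missing metric, unknown reported sex) do not by
    themselves remove a sample unless ``strict_missing`` was set, but are
    tallied separately.
    """

    verdicts: dict[str, dict[str, str]] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)

    @property
    def failure_counts(self) -> dict[str, int]:
        """Samples failing each criterion (a sample can appear under several)."""
        out = {c: 0 for c in CRITERIA}
        for per_sample in self.verdicts.values():
            for crit, verdict in per_sample.items():
                if verdict == "fail":
                    out[crit] += 1
        return out

    @property
    def indeterminate_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CRITERIA}
        for per_sample in self.verdicts.values():
            for crit, verdict in per_sample.items():
                if verdict == "indeterminate":
                    out[crit] += 1
        return out

    def failed_criteria(self, sample_id: str) -> list[str]:
        return [c for c, v in self.verdicts[sample_id].items() if v == "fail"]

    def to_dict(self) -> dict:
        return {
            "n_input": len(self.verdicts),
            "n_retained": len(self.retained),
            "n_removed": len(self.removed),
            "failure_counts": self.failure_counts,
            "indeterminate_counts": self.indeterminate_counts,
            "retained": self.retained,
            "removed": self.removed,
        }


def inbreeding_f(
    x_genotypes: Sequence[int],
    allele_freqs: Sequence[float],
) -> float:
    """Method-of-moments inbreeding coefficient over X-chromosome sites.

    ``x_genotypes`` are one sample's genotype codes (0 hom-ref, 1 het,
    2 hom-alt) at m sites; ``allele_freqs`` the per-site alternate-allele
    frequencies p_i in (0, 1).  F = (O_hom - E_hom) / (m - E_hom) with O_hom
    the observed homozygous site count and E_hom = sum_i (1 - 2 p_i (1-p_i)).
    Genetic males are hemizygous on X so appear fully homozygous (F near 1);
    females' F centers near 0 — hence the sex-check thresholds.

    Callers supplying X genotypes should exclude pseudo-autosomal regions;
    no PAR table is built in.
    """
    g = np.asarray(x_genotypes, dtype=int)
    p = np.asarray(allele_freqs, dtype=float)
    if g.ndim != 1 or g.shape != p.shape:
        raise ValueError("genotypes and allele_freqs must be 1-D and equal length")
    m = g.size
    if m < 1:
        raise ValueError("need at least one site")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if np.any((g < 0) | (g > 2)):
        raise ValueError("genotype codes must be 0, 1 or 2")
    o_hom = int(np.sum(g != 1))
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p)))
    denom = m - e_hom
    if denom == 0:
        raise ZeroDivisionError("m - E_hom is zero; F undefined")
    return (o_hom - e_hom) / denom


def _evaluate(metrics: SampleMetrics, t: QCThresholds) -> dict[str, str]:
    v: dict[str, str] = {}

    def check(value, fails) -> str:
        if value is None:
            return "fail" if t.strict_missing else "indeterminate"
        return "fail" if fails(value) else "pass"

    if metrics.frac_target_ge_10x is None or metrics.frac_target_ge_40x is None:
        v["coverage"] = "fail" if t.strict_missing else "indeterminate"
    else:
        ok = (metrics.frac_target_ge_10x >= t.min_frac_target_ge_10x
              and metrics.frac_target_ge_40x >= t.min_frac_target_ge_40x)
        v["coverage"] = "pass" if ok else "fail"
    v["call_rate"] = check(metrics.call_rate, lambda x: x < t.min_call_rate)
    v["titv"] = check(metrics.titv, lambda x: x < t.min_titv)
    # contamination removal requires strictly greater than the cutoff
    v["contamination"] = check(metrics.freemix, lambda x: x > t.max_freemix)

    if metrics.reported_sex == "unknown" or metrics.sex_f is None:
        v["sex_check"] = "indeterminate"
    elif metrics.reported_sex == "male":
        v["sex_check"] = "fail" if metrics.sex_f < t.male_min_sex_f else "pass"
    else:
        v["sex_check"] = "fail" if metrics.sex_f > t.female_max_sex_f else "pass"

    if metrics.apoe_match is None:
        v["apoe_concordance"] = "indeterminate"
    else:
        v["apoe_concordance"] = "pass" if metrics.apoe_match else "fail"

    v["relatedness"] = "fail" if metrics.relatedness_flag else "pass"
    v["ancestry"] = "fail" if metrics.ancestry_flag else "pass"
    v["batch"] = "fail" if metrics.batch_flag else "pass"
    return v


def apply_sample_qc(
    metrics: Iterable[SampleMetrics],
    thresholds: Optional[QCThresholds] = None,
) -> QCReport:
    """Run the full QC cascade and report per-criterion verdicts.

    Every criterion is evaluated for every sample (no short-circuiting), so a
    sample can fail multiple criteria and per-criterion removal counts can sum
    to more than the number of removed samples.  Retained samples are those
    failing zero criteria.
    """
    t = thresholds or QCThresholds()
    report = QCReport()
    seen: set[str] = set()
    for m in metrics:
        if m.sample_id in seen:
            raise ValueError(f"duplicate sample_id {m.sample_id!r}")
        seen.add(m.sample_id)
        verdicts = _evaluate(m, t)
        report.verdicts[m.sample_id] = verdicts
        if any(v == "fail" for v in verdicts.values()):
            report.removed.append(m.sample_id)
        else:
            report.retained.append(m.sample_id)
    return report


# ---------------------------------------------------------------------------
# Metrics table I/O
# ---------------------------------------------------------------------------

_BOOL_COLS = ("apoe_match", "relatedness_flag", "ancestry_flag", "batch_flag")


def read_metrics_table(path) -> list[SampleMetrics]:
    """Read the documented TSV schema into SampleMetrics rows.

    Columns are the SampleMetrics field names; "." or empty marks a missing
    value; boolean columns take 1/0/true/false.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=True)
    if "sample_id" not in df.columns:
        raise ValueError("metrics table must have a sample_id column")
    known = {f.name for f in dc_fields(SampleMetrics)}
    rows: list[SampleMetrics] = []
    for _, row in df.iterrows():
        kwargs: dict = {"sample_id": str(row["sample_id"])}
        for col in df.columns:
            if col == "sample_id" or col not in known:
                continue
            raw = row[col]
            if pd.isna(raw):
                continue
            if col in _BOOL_COLS:
                val = str(raw).strip().lower() in ("1", "true", "yes")
            elif col == "reported_sex":
                val = str(raw).strip().lower()
            else:
                val = float(raw)
            kwargs[col] = val
        rows.append(SampleMetrics(**kwargs))
    return rows


def write_metrics_table(metrics: Sequence[SampleMetrics], path) -> None:
    cols = [f.name for f in dc_fields(SampleMetrics)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for m in metrics:
            vals = []
            for c in cols:
                v = getattr(m, c)
                if v is None:
                    vals.append(".")
                elif isinstance(v, bool):
                    vals.append("1" if v else "0")
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")


def write_qc_report(report: QCReport, tsv_path, json_path=None) -> None:
    """Per-sample verdict TSV and an optional JSON summary."""
    import json
    with open(tsv_path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(CRITERIA) + "\tretained\n")
        for sid, verdicts in report.verdicts.items():
            fh.write(sid + "\t"
                     + "\t".join(verdicts[c] for c in CRITERIA)
                     + f"\t{int(sid in set(report.retained))}\n")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
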