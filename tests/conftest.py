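"""Shared fixtures: hand-written VCF text, small synthetic cohorts."""

from __future__ import annotations

import random

import pytest

import varrescue as vr
from varrescue.synthetic_data import default_pipeline_models

TOY_VCF = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=LowQual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=1,length=100000>
##contig=<ID=2,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\t.\tA\tG\t50\tPASS\t.\tGT:GQ:DP:AD\t0/1:99:30:15,15\t0/0:50:20:20,0
1\t200\t.\tC\tT,G\t30\tPASS\t.\tGT\t1/2\t./.
1\t300\t.\tG\tA\t10\tLowQual\t.\tGT:GQ:DP:AD\t1|1:.:10:0,10\t0/.:20:.:.
2\t150\t.\tT\tC\t40\tPASS\t.\tGT:GQ:DP:AD\t0/1:80:25:12,13\t0/1:70:22:11,11
2\t250\t.\tG\tGA\t40\tPASS\t.\tGT\t0/1\t0/0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    """A 2-sample, 5-record VCF exercising missing fields, multi-allelics,
    half-calls, indels and non-PASS labels."""
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


def make_callset(label: str, keys, roster=("S1",)) -> vr.CallSet:
    """Minimal call-set holding the given keys (no genotype content)."""
    cs = vr.CallSet(label=label, roster=tuple(roster))
    for key in keys:
        cs.add(vr.VariantRecord(key=key))
    return cs


def random_keys(rng: random.Random, n: int) -> set[vr.VariantKey]:
    pairs = [("A", "G"), ("C", "T"), ("G", "C"), ("T", "A")]
    out = set()
    while len(out) < n:
        ref, alt = rng.choice(pairs)
        out.add(vr.VariantKey(chrom=rng.choice(["1", "2", "X"]),
                              pos=rng.randint(1, 500), ref=ref, alt=alt))
    return out


@pytest.fixture(scope="session")
def small_model() -> vr.CohortModel:
    return vr.CohortModel(
        n_samples=60, n_variants=800,
        chrom_lengths={"1": 60_000, "2": 60_000, "3": 40_000},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_truth(small_model) -> vr.TruthCohort:
    return vr.generate_truth_cohort(small_model)


@pytest.fixture(scope="session")
def pipeline_models():
    return default_pipeline_models()


@pytest.fixture(scope="session")
def small_bundle(small_model, pipeline_models, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return vr.generate_study_bundle(
        small_model, list(pipeline_models.values()), out, seed=42)
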