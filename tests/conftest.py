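"""Shared fixtures: session-scoped synthetic datasets and BAM helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from iedetect import (
    RunConfig,
    SampleDepthProfile,
    SimulationSpec,
    annotate_callability,
    annotate_gc,
    gc_correct,
    make_fixtures,
    read_capture_bed,
)
from iedetect.depth_profile import ReadFilterPolicy, build_depth_profile
from iedetect.model import ExonModel, GeneModel

import pyfaidx

SEED = 1234


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """Standard evaluation dataset: 100 genes, 50x, 20 planted runs of 1-6 exons."""
    spec = SimulationSpec(seed=SEED)
    return make_fixtures(spec, tmp_path_factory.mktemp("fx_default"), n_samples=1)


@pytest.fixture(scope="session")
def default_analysis(default_fixture):
    """Callable genes plus the GC-corrected depth profile of the default sample."""
    fx = default_fixture
    capture = read_capture_bed(fx.bed)
    reference = pyfaidx.Fasta(str(fx.fasta))
    annotate_gc(fx.genes, reference)
    callable_genes = annotate_callability(fx.genes, capture)
    profile = build_depth_profile(str(fx.bams[0]), callable_genes, ReadFilterPolicy())
    corrected = gc_correct(profile)
    return {
        "fixture": fx,
        "capture": capture,
        "callable_genes": callable_genes,
        "profile": corrected,
    }


@pytest.fixture(scope="session")
def gcbias_fixture(tmp_path_factory):
    """Dataset with a strong GC-dependent depth response and no deletions.

    GC targets span 0.40-0.75, the mostly-declining side of the unimodal
    response, so raw depth correlates strongly with GC bin.
    """
    spec = SimulationSpec(
        n_genes=120,
        n_planted_deletions=0,
        gc_bias=True,
        gc_range=(0.40, 0.75),
        seed=77,
    )
    return make_fixtures(spec, tmp_path_factory.mktemp("fx_gc"), n_samples=1)


@pytest.fixture(scope="session")
def multi_fixture(tmp_path_factory):
    """Four-sample dataset for parallelism and summary tests."""
    spec = SimulationSpec(n_genes=30, n_planted_deletions=5, seed=4321)
    return make_fixtures(spec, tmp_path_factory.mktemp("fx_multi"), n_samples=4)


def make_gene(n_exons: int, gene_id: str = "G", chrom: str = "chr1",
              exon_len: int = 100, spacing: int = 200) -> GeneModel:
    """Gene model with evenly spaced dummy exons for detection-level tests."""
    exons = []
    pos = 1000
    for i in range(n_exons):
        exons.append(
            ExonModel(gene_id=gene_id, ordinal=i + 1, chromosome=chrom,
                      start=pos, end=pos + exon_len)
        )
        pos += exon_len + spacing
    return GeneModel(gene_id=gene_id, chromosome=chrom, strand="+", exons=exons)


def make_profile(raws, gcs=None, sample_id="s1", gene_id="G") -> SampleDepthProfile:
    """Depth profile over one synthetic gene, straight from raw medians."""
    n = len(raws)
    gcs = gcs if gcs is not None else [0.5] * n
    table = pd.DataFrame(
        {
            "gene_id": [gene_id] * n,
            "ordinal": np.arange(1, n + 1),
            "chromosome": ["chr1"] * n,
            "start": np.arange(n) * 300 + 1000,
            "end": np.arange(n) * 300 + 1100,
            "gc_fraction": gcs,
            "gc_bin": -1,
            "raw_median": np.asarray(raws, dtype=float),
            "corrected": np.nan,
        }
    )
    return SampleDepthProfile(sample_id=sample_id, table=table)


def write_bam(path, reads, chrom="chr1", chrom_len=100_000, read_len=50,
              pg_name="bwa"):
    """Hand-built sorted+indexed BAM.

    ``reads`` is a list of dicts with keys pos, and optionally mapq (60),
    length (read_len), quals (constant 35), flag (0).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": chrom_len}],
        "PG": [{"ID": pg_name, "PN": pg_name}],
    }
    reads = sorted(reads, key=lambda r: r["pos"])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, r in enumerate(reads):
            length = r.get("length", read_len)
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"read{i}"
            a.reference_id = 0
            a.reference_start = r["pos"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigartuples = [(0, length)]
            a.query_sequence = "A" * length
            quals = r.get("quals", [35] * length)
            a.query_qualities = quals
            a.flag = r.get("flag", 0)
            bam.write(a)
    pysam.index(str(path))
    return path


def run_config(fx, outdir, **kwargs) -> RunConfig:
    return RunConfig(
        bams=[str(b) for b in fx.bams],
        bed=str(fx.bed),
        gtf=str(fx.gtf),
        fasta=str(fx.fasta),
        outdir=str(outdir),
        **kwargs,
    )
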