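"""Quality-filtered per-exon depth extraction and GC median correction.

For each exon the per-base filtered depth vector is built over the full exon
interval (zero-coverage bases contribute 0) and summarized by its median
DP_e.  Read filtering depends on the aligner: BWA-style BAMs drop reads with
MAPQ < 20; for other aligners, whose MAPQ scales differ, reads with mean
base quality < 20 are dropped instead.  GC bias is then removed by median
correction: each exon's depth is rescaled by m / m_GC, the ratio of the
global median of exon depths to the median within the exon's GC bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .model import ExonModel, GeneModel

logger = logging.getLogger(__name__)

DEPTH_COLUMNS = [
    "gene_id",
    "ordinal",
    "chromosome",
    "start",
    "end",
    "gc_fraction",
    "gc_bin",
    "raw_median",
    "corrected",
]


@dataclass
class ReadFilterPolicy:
    """Which reads enter the pileup.

    Exactly one mode is active: ``mapq`` keeps reads with MAPQ >= mapq_min
    (BWA-style quality scale), ``basequal`` keeps reads whose mean base
    quality is >= basequal_min.  Both cutoffs are strict removals at < 20 by
    default, so a read exactly at 20 is kept.  Duplicate, secondary,
    supplementary and unmapped records always fail.
    """

    mode: str = "mapq"
    mapq_min: int = 20
    basequal_min: float = 20.0

    def __post_init__(self) -> None:
        if self.mode not in ("mapq", "basequal"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


@dataclass
class SampleDepthProfile:
    """Per-exon raw and GC-corrected median depths for one sample.

    ``table`` has one row per exon of every callable gene (columns in
    DEPTH_COLUMNS).  ``global_median`` (m) and ``bin_medians`` (m_GC) are
    filled by :func:`gc_correct`.
    """

    sample_id: str
    table: pd.DataFrame
    global_median: Optional[float] = None
    bin_medians: dict[int, float] = field(default_factory=dict)

    def gene_depths(self, gene_id: str, column: str = "corrected") -> np.ndarray:
        sub = self.table[self.table["gene_id"] == gene_id].sort_values("ordinal")
        return sub[column].to_numpy(dtype=float)


def mean_base_quality(qualities: Sequence[int]) -> float:
    """Arithmetic mean of a read's phred base qualities; empty input is an error."""
    if len(qualities) == 0:
        raise ValueError("read has no base qualities")
    return float(np.mean(qualities))


def read_passes_filter(read: pysam.AlignedSegment, policy: ReadFilterPolicy) -> bool:
    if read.is_unmapped or read.is_duplicate or read.is_secondary or read.is_supplementary:
        return False
    if policy.mode == "mapq":
        return read.mapping_quality >= policy.mapq_min
    quals = read.query_qualities
    if quals is None or len(quals) == 0:
        return False
    return mean_base_quality(quals) >= policy.basequal_min


def detect_filter_mode(bam: pysam.AlignmentFile) -> str:
    """Pick the filter mode from the BAM @PG records.

    If any program record names a program containing "bwa" the MAPQ filter
    applies; otherwise the mean-base-quality filter is used.  A CLI override
    takes precedence over this auto-detection.
    """
    for pg in bam.header.to_dict().get("PG", []):
        for key in ("PN", "ID", "CL"):
            if "bwa" in str(pg.get(key, "")).lower():
                return "mapq"
    return "basequal"


def exon_median_depth(
    bam: pysam.AlignmentFile, exon: ExonModel, policy: ReadFilterPolicy
) -> float:
    """Median of per-base filtered depth over every base of the exon.

    Even-length medians are the mean of the two central values.  No maximum
    depth cap is applied.
    """
    if exon.chromosome not in bam.references:
        raise ValueError(f"chromosome {exon.chromosome} absent from BAM header")
    depth = np.zeros(exon.length, dtype=np.int64)
    for read in bam.fetch(exon.chromosome, exon.start, exon.end):
        if not read_passes_filter(read, policy):
            continue
        for bstart, bend in read.get_blocks():
            lo = max(bstart, exon.start) - exon.start
            hi = min(bend, exon.end) - exon.start
            if hi > lo:
                depth[lo:hi] += 1
    return float(np.median(depth))


def build_depth_profile(
    bam_path: str,
    genes: Sequence[GeneModel],
    policy: ReadFilterPolicy,
    sample_id: Optional[str] = None,
) -> SampleDepthProfile:
    """Raw per-exon median depths for one BAM over the given (callable) genes."""
    rows = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if sample_id is None:
            sample_id = _sample_name(bam, bam_path)
        for gene in genes:
            for exon in gene.exons:
                rows.append(
                    {
                        "gene_id": exon.gene_id,
                        "ordinal": exon.ordinal,
                        "chromosome": exon.chromosome,
                        "start": exon.start,
                        "end": exon.end,
                        "gc_fraction": exon.gc_fraction,
                        "gc_bin": -1,
                        "raw_median": exon_median_depth(bam, exon, policy),
                        "corrected": np.nan,
                    }
                )
    table = pd.DataFrame(rows, columns=DEPTH_COLUMNS)
    return SampleDepthProfile(sample_id=sample_id, table=table)


def _sample_name(bam: pysam.AlignmentFile, bam_path: str) -> str:
    for rg in bam.header.to_dict().get("RG", []):
        if "SM" in rg:
            return rg["SM"]
    import os

    return os.path.splitext(os.path.basename(bam_path))[0]


def _gc_bin(gc_fraction: Optional[float], width_percent: float) -> int:
    """Integer GC bin; -1 flags undefined GC (all-N exon)."""
    if gc_fraction is None or (isinstance(gc_fraction, float) and math.isnan(gc_fraction)):
        return -1
    return min(int(gc_fraction * 100 / width_percent), int(100 / width_percent) - 1)


def global_depth_summary(
    profile: SampleDepthProfile,
) -> tuple[float, dict[int, float]]:
    """Global median m and per-GC-bin medians m_GC of the raw exon depths."""
    raw = profile.table["raw_median"].to_numpy(dtype=float)
    if len(raw) == 0:
        raise ValueError("depth profile holds no exons")
    m = float(np.median(raw))
    bin_medians = {
        int(b): float(np.median(grp["raw_median"]))
        for b, grp in profile.table.groupby("gc_bin")
        if b >= 0
    }
    return m, bin_medians


def gc_correct(
    profile: SampleDepthProfile,
    gc_bin_width: float = 1.0,
    min_bin_size: int = 10,
) -> SampleDepthProfile:
    """GC median correction: corrected depth = raw * m / m_GC of the GC bin.

    GC fractions are binned at ``gc_bin_width`` percent.  Bins holding fewer
    than ``min_bin_size`` exons, and exons with undefined GC, use m_GC = m
    (no correction).  A global median of zero means the sample produced no
    usable depth and is an error.
    """
    table = profile.table.copy()
    table["gc_bin"] = [
        _gc_bin(g, gc_bin_width) for g in table["gc_fraction"].tolist()
    ]
    staged = replace(profile, table=table)
    m, bin_medians = global_depth_summary(staged)
    if m == 0:
        raise ValueError(
            f"sample {profile.sample_id}: global median depth is 0; sample not callable"
        )
    bin_sizes = table["gc_bin"].value_counts().to_dict()
    effective = {
        b: (med if bin_sizes.get(b, 0) >= min_bin_size and med > 0 else m)
        for b, med in bin_medians.items()
    }
    factors = table["gc_bin"].map(lambda b: m / effective.get(b, m))
    table["corrected"] = table["raw_median"] * factors
    return SampleDepthProfile(
        sample_id=profile.sample_id,
        table=table,
        global_median=m,
        bin_medians=effective,
    )
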