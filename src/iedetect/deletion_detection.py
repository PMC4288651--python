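"""Homozygous internal exon deletion calling from GC-corrected exon depths.

Per callable gene, an exon is a deletion candidate when its corrected median
depth falls below c1% of the reference depth (condition 1); the candidates'
complement ē must itself stay above c2% of the same reference (condition 2),
which rejects genes that are uniformly low rather than locally deleted.
Maximal runs of consecutive candidates become calls when their length is at
most min(max_window, L-1).  Candidate state never crosses a gene boundary.

The reference is, by default, the median of the gene's own exon depths
(``gene_median_fraction``); ``sample_percentile`` instead uses the c1-th /
c2-th percentiles of all exon depths sample-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .depth_profile import SampleDepthProfile
from .model import GeneModel

logger = logging.getLogger(__name__)

THRESHOLD_MODES = ("gene_median_fraction", "sample_percentile")


@dataclass
class DetectionConfig:
    """Detection thresholds.

    c1: percent — candidate exons have depth below c1% of the reference
        (default 2, i.e. near-zero depth on a homozygous deletion).
    c2: percent — the non-candidate exons' median must exceed c2% of the
        reference (default 10).
    max_window: longest reportable run in exons (default 7).  Inclusive by
        default; ``strict_window`` reads "less than max_window" literally
        (limit max_window - 1).
    """

    c1: float = 2.0
    c2: float = 10.0
    max_window: int = 7
    threshold_mode: str = "gene_median_fraction"
    strict_window: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.c1 < self.c2 <= 100):
            raise ValueError(f"need 0 < c1 < c2 <= 100, got c1={self.c1}, c2={self.c2}")
        if self.max_window < 1:
            raise ValueError(f"max_window must be >= 1, got {self.max_window}")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")

    @property
    def window_limit(self) -> int:
        return self.max_window - 1 if self.strict_window else self.max_window


@dataclass
class DeletionCall:
    """One candidate IED: a contiguous exon run of one gene in one sample."""

    sample_id: str
    gene_id: str
    chromosome: str
    first: int  # first exon ordinal of the run (1-based)
    last: int  # last exon ordinal, inclusive
    start: int  # genomic span, 0-based half-open
    end: int
    run_depth: float  # median corrected depth over the run
    reference_depth: float  # the comparison value both conditions use
    flanking_depth: float  # median corrected depth of the non-candidate exons
    c1: float
    c2: float

    @property
    def run_length(self) -> int:
        return self.last - self.first + 1

    def key(self) -> tuple[str, str, int, int]:
        return (self.sample_id, self.gene_id, self.first, self.last)


def _thresholds(
    gene_depths: np.ndarray,
    config: DetectionConfig,
    sample_depths: Optional[np.ndarray],
) -> tuple[float, float, float]:
    """(threshold1, threshold2, reference) for one gene."""
    if config.threshold_mode == "gene_median_fraction":
        ref = float(np.median(gene_depths))
        return config.c1 / 100.0 * ref, config.c2 / 100.0 * ref, ref
    if sample_depths is None:
        raise ValueError("sample_percentile mode needs the sample-wide depth vector")
    t1 = float(np.percentile(sample_depths, config.c1))
    t2 = float(np.percentile(sample_depths, config.c2))
    return t1, t2, float(np.median(sample_depths))


def candidate_exons(
    gene_depths: Sequence[float],
    config: DetectionConfig,
    sample_depths: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Condition 1 mask: exon depth strictly below the c1 threshold.

    A depth exactly at the threshold is not a candidate.
    """
    depths = np.asarray(gene_depths, dtype=float)
    t1, _, _ = _thresholds(depths, config, sample_depths)
    return depths < t1


def flanking_condition(
    gene_depths: Sequence[float],
    mask: np.ndarray,
    config: DetectionConfig,
    sample_depths: Optional[np.ndarray] = None,
) -> bool:
    """Condition 2: median depth of non-candidate exons exceeds the c2 threshold.

    False when the mask covers all exons (no ē remains) — a whole-gene
    dropout is not an internal deletion.
    """
    depths = np.asarray(gene_depths, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    flanking = depths[~mask]
    if len(flanking) == 0:
        return False
    _, t2, _ = _thresholds(depths, config, sample_depths)
    return float(np.median(flanking)) > t2


def _maximal_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) 0-based inclusive index pairs."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def call_runs(
    gene: GeneModel,
    gene_depths: Sequence[float],
    config: DetectionConfig,
    sample_id: str = "",
    sample_depths: Optional[np.ndarray] = None,
) -> list[DeletionCall]:
    """Call deletions on one callable gene from its ordered corrected depths.

    Maximal candidate runs are emitted when the run length is at most
    min(window limit, L-1) and the gene passes the flanking condition.
    Over-long runs are suppressed whole, never truncated (truncation would
    move candidate exons into ē and corrupt condition 2).  A gene whose
    reference median is 0 is uninterpretable and skipped with a warning.
    """
    depths = np.asarray(gene_depths, dtype=float)
    L = len(depths)
    if L != gene.n_exons:
        raise ValueError(
            f"gene {gene.gene_id}: {L} depths for {gene.n_exons} exons"
        )
    if L < 2:
        return []
    t1, t2, ref = _thresholds(depths, config, sample_depths)
    if config.threshold_mode == "gene_median_fraction" and ref == 0:
        logger.warning("gene %s: median depth 0, skipped", gene.gene_id)
        return []
    mask = depths < t1
    if not mask.any():
        return []
    if not flanking_condition(depths, mask, config, sample_depths):
        return []
    limit = min(config.window_limit, L - 1)
    flank_med = float(np.median(depths[~mask]))
    calls = []
    for i, j in _maximal_runs(mask):
        length = j - i + 1
        if length > limit:
            continue
        calls.append(
            DeletionCall(
                sample_id=sample_id,
                gene_id=gene.gene_id,
                chromosome=gene.chromosome,
                first=i + 1,
                last=j + 1,
                start=gene.exons[i].start,
                end=gene.exons[j].end,
                run_depth=float(np.median(depths[i : j + 1])),
                reference_depth=ref,
                flanking_depth=flank_med,
                c1=config.c1,
                c2=config.c2,
            )
        )
    return calls


def detect_sample(
    profile: SampleDepthProfile,
    genes: Sequence[GeneModel],
    config: DetectionConfig,
) -> list[DeletionCall]:
    """Run detection over every callable gene of one sample's depth profile."""
    sample_depths = profile.table["corrected"].to_numpy(dtype=float)
    calls: list[DeletionCall] = []
    for gene in genes:
        if gene.callable is False:
            continue
        depths = profile.gene_depths(gene.gene_id)
        if len(depths) == 0:
            continue
        calls.extend(
            call_runs(gene, depths, config, profile.sample_id, sample_depths)
        )
    return calls


def summarize_samples(
    all_calls: Sequence[DeletionCall],
    samples: Sequence[str],
    max_length: Optional[int] = None,
) -> dict[str, pd.DataFrame]:
    """Multi-sample summary statistics.

    Returns three tables: ``by_length`` — candidate counts per run length
    (lengths 1..max on the columns); ``by_gene`` — per gene, the number of
    samples carrying at least one call; ``by_sample`` — total calls per
    sample.
    """
    lengths = [c.run_length for c in all_calls]
    max_len = max_length or (max(lengths) if lengths else 1)
    hist = {k: 0 for k in range(1, max_len + 1)}
    for length in lengths:
        hist[length] = hist.get(length, 0) + 1
    by_length = pd.DataFrame(
        [hist.values()], columns=[str(k) for k in hist], index=["n_calls"]
    )
    gene_samples: dict[str, set[str]] = {}
    for c in all_calls:
        gene_samples.setdefault(c.gene_id, set()).add(c.sample_id)
    by_gene = pd.DataFrame(
        sorted(
            ((g, len(s)) for g, s in gene_samples.items()),
            key=lambda t: (-t[1], t[0]),
        ),
        columns=["gene_id", "n_samples"],
    )
    per_sample = {s: 0 for s in samples}
    for c in all_calls:
        per_sample[c.sample_id] = per_sample.get(c.sample_id, 0) + 1
    by_sample = pd.DataFrame(
        sorted(per_sample.items()), columns=["sample", "n_calls"]
    )
    return {"by_length": by_length, "by_gene": by_gene, "by_sample": by_sample}
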