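"""Readers for the four standard inputs (BED, GTF, FASTA, BAM header checks)
and writers for the tab-separated call reports.

Internal coordinates are 0-based half-open.  BED is already 0-based
half-open; GTF is 1-based inclusive and converted on read; report spans are
written back as 1-based inclusive.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils.iterators
import pyfaidx

from .model import (
    CaptureIndex,
    ChromosomeMismatchError,
    ExonModel,
    GeneModel,
    InputFormatError,
    merge_intervals,
)

logger = logging.getLogger(__name__)

CALL_REPORT_COLUMNS = [
    "sample",
    "gene_id",
    "chromosome",
    "first_exon",
    "last_exon",
    "run_length",
    "span_start",
    "span_end",
    "run_depth",
    "reference_depth",
    "flanking_depth",
    "c1",
    "c2",
]


def _apply_alias(name: str, aliases: Optional[Mapping[str, str]]) -> str:
    if aliases:
        return aliases.get(name, name)
    return name


def read_capture_bed(
    path: str | Path, chrom_aliases: Optional[Mapping[str, str]] = None
) -> CaptureIndex:
    """Read capture-kit target regions from a BED file into a CaptureIndex.

    Track/browser/comment lines are skipped.  Regions are normalized
    (sorted and merged) per chromosome.  Malformed data lines raise
    :class:`InputFormatError` naming the offending line number; an empty
    file (no data lines) is an error.
    """
    path = Path(path)
    regions: dict[str, list[tuple[int, int]]] = defaultdict(list)
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}:{lineno}: BED line has {len(fields)} columns, need >= 3"
                )
            chrom = _apply_alias(fields[0], chrom_aliases)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise InputFormatError(
                    f"{path}:{lineno}: non-integer BED coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from None
            if start >= end:
                raise InputFormatError(
                    f"{path}:{lineno}: BED interval start >= end ({start} >= {end})"
                )
            regions[chrom].append((start, end))
            n_data += 1
    if n_data == 0:
        raise InputFormatError(f"{path}: no capture regions found")
    return CaptureIndex(regions)


def read_gene_models(
    path: str | Path, chrom_aliases: Optional[Mapping[str, str]] = None
) -> list[GeneModel]:
    """Read gene models from a GTF file.

    Only ``exon`` feature rows are used; they are grouped by the ``gene_id``
    attribute.  Overlapping exon records of one gene (transcript isoforms)
    are merged into a single union exon, and ordinals are assigned 1..L in
    genomic order.  GTF 1-based inclusive coordinates become 0-based
    half-open.  A gene with exon records on more than one chromosome is
    skipped with a warning.
    """
    path = Path(path)
    exon_ivals: dict[str, list[tuple[int, int]]] = defaultdict(list)
    gene_meta: dict[str, tuple[str, str]] = {}
    multi_chrom: set[str] = set()
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            raise InputFormatError(f"{path}: exon record without gene_id attribute")
        gid = gene_ids[0]
        chrom = _apply_alias(feat.seqid, chrom_aliases)
        if gid in gene_meta and gene_meta[gid][0] != chrom:
            multi_chrom.add(gid)
            continue
        gene_meta.setdefault(gid, (chrom, feat.strand or "+"))
        # GTF is 1-based inclusive: [start, end] -> [start-1, end)
        exon_ivals[gid].append((feat.start - 1, feat.end))
    for gid in multi_chrom:
        logger.warning("gene %s has exons on multiple chromosomes; skipped", gid)
        exon_ivals.pop(gid, None)
        gene_meta.pop(gid, None)
    if not exon_ivals:
        raise InputFormatError(f"{path}: no exon feature rows found")
    genes = []
    for gid in sorted(exon_ivals):
        chrom, strand = gene_meta[gid]
        merged = merge_intervals(exon_ivals[gid])
        exons = [
            ExonModel(gene_id=gid, ordinal=i, chromosome=chrom, start=s, end=e)
            for i, (s, e) in enumerate(merged, start=1)
        ]
        genes.append(GeneModel(gene_id=gid, chromosome=chrom, strand=strand, exons=exons))
    return genes


def compute_exon_gc(exon: ExonModel, reference: pyfaidx.Fasta) -> Optional[float]:
    """GC fraction of an exon's reference sequence, case-insensitive.

    Ambiguous bases (anything outside ACGT) are excluded from both numerator
    and denominator.  Returns None when no unambiguous base remains, in which
    case the exon later falls back to the uncorrected global median.
    """
    seq = str(reference[exon.chromosome][exon.start : exon.end]).upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def annotate_gc(genes: Sequence[GeneModel], reference: pyfaidx.Fasta) -> None:
    """Fill in gc_fraction for every exon of every gene, in place."""
    for gene in genes:
        for exon in gene.exons:
            exon.gc_fraction = compute_exon_gc(exon, reference)


def check_chromosome_compatibility(
    bam_chromosomes: Iterable[str], needed_chromosomes: Iterable[str]
) -> None:
    """Hard error if any annotation chromosome is absent from the BAM header.

    The error lists both name sets so "chr1" vs "1" dialect clashes are
    immediately visible; reconcile them with the readers' alias maps.
    """
    bam_set = set(bam_chromosomes)
    missing = sorted(set(needed_chromosomes) - bam_set)
    if missing:
        raise ChromosomeMismatchError(
            f"chromosomes {missing} not in BAM header "
            f"(BAM has: {sorted(bam_set)})"
        )


def write_call_report(calls: Sequence, path: str | Path) -> None:
    """Write deletion calls as a TSV report (1-based inclusive spans).

    An empty call list yields a header-only file.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_REPORT_COLUMNS) + "\n")
        for call in calls:
            fh.write(
                "\t".join(
                    [
                        call.sample_id,
                        call.gene_id,
                        call.chromosome,
                        str(call.first),
                        str(call.last),
                        str(call.last - call.first + 1),
                        str(call.start + 1),  # 1-based inclusive
                        str(call.end),
                        f"{call.run_depth:.4g}",
                        f"{call.reference_depth:.4g}",
                        f"{call.flanking_depth:.4g}",
                        f"{call.c1:g}",
                        f"{call.c2:g}",
                    ]
                )
                + "\n"
            )


def write_calls_bed(calls: Sequence, path: str | Path) -> None:
    """Write the genomic spans of calls as a BED file (0-based half-open)."""
    with open(path, "w") as fh:
        for call in calls:
            name = f"{call.sample_id}:{call.gene_id}:exons{call.first}-{call.last}"
            fh.write(f"{call.chromosome}\t{call.start}\t{call.end}\t{name}\n")


def write_callability_report(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Per-gene callability TSV: flag, exon count, worst coverage, failing exons."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcallable\tn_exons\tmin_covered_fraction\tfailing_exons\n")
        for gene in genes:
            fracs = [
                e.covered_fraction for e in gene.exons if e.covered_fraction is not None
            ]
            min_frac = f"{min(fracs):.4f}" if fracs else "NA"
            failing = ",".join(map(str, gene.failing_exons)) if gene.failing_exons else "."
            fh.write(
                f"{gene.gene_id}\t{gene.callable}\t{gene.n_exons}\t{min_frac}\t{failing}\n"
            )


def write_depth_table(profile, path: str | Path) -> None:
    """Per-exon depth TSV (debugging intermediate): raw and corrected medians."""
    table = profile.table.copy()
    table.insert(0, "sample", profile.sample_id)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
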