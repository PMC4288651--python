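"""Self-contained synthetic test inputs: toy reference, annotation, capture
design and aligned reads with planted homozygous exon deletions.

The generator emulates a small exome experiment: genes of a few hundred bp
exons laid out on a toy chromosome, a capture BED covering every exon (with
designated genes given partial coverage to exercise callability), and
single-end 75 bp reads tiling each non-deleted exon to a target background
depth, optionally modulated by a unimodal GC response.  Planted deletion
runs receive zero reads, the read-depth signature of a homozygous deletion.
Everything is driven by one integer seed and is byte-reproducible.

It does not model sequencing errors, insert sizes, mappability structure or
tumor-normal mixtures; reads are single-end because the caller's depth
arithmetic never inspects pairing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pysam

from .model import ExonModel, GeneModel

CHROM = "chr1"
BASES = np.frombuffer(b"ACGT", dtype="S1")


def default_gc_bias(gc: float) -> float:
    """Unimodal depth multiplier: maximal near GC 0.45, dropping toward the
    extremes, floored at 0.25 so deleted and merely GC-poor exons stay
    separable."""
    return float(np.clip(1.0 - 11.2 * (gc - 0.45) ** 2, 0.25, 1.0))


@dataclass
class SimulationSpec:
    """Parameters of one synthetic exome experiment.

    Defaults describe the standard evaluation fixture: 100 genes of 3-15
    exons (60-300 bp), 50x background depth, 75 bp reads, and 20 planted
    homozygous deletion runs of 1-6 exons.
    """

    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (3, 15)
    exon_length: tuple[int, int] = (60, 300)
    background_depth: float = 50.0
    read_length: int = 75
    intron_length: int = 300
    intergenic_length: int = 600
    chromosome_length: Optional[int] = None  # None: sized to fit the layout
    n_planted_deletions: int = 20
    planted_run_length: tuple[int, int] = (1, 6)
    planted_deletions: Optional[list[tuple[str, int, int]]] = None
    gc_bias: bool = False
    gc_range: tuple[float, float] = (0.35, 0.65)
    partial_capture: dict[str, float] = field(default_factory=dict)
    low_mapq_fraction: float = 0.0
    low_basequal_fraction: float = 0.0
    base_quality: int = 35
    low_base_quality: int = 10
    mapq: int = 60
    aligner: str = "bwa"
    seed: int = 0

    def validate(self) -> None:
        for name in ("exons_per_gene", "exon_length", "planted_run_length"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.intron_length < self.read_length:
            raise ValueError("intron_length must be >= read_length (no read bleed)")


@dataclass
class FixtureSet:
    """Paths and ground truth of one generated fixture directory."""

    fasta: Path
    gtf: Path
    bed: Path
    bams: list[Path]
    genes: list[GeneModel]
    truth: list[tuple[str, int, int]]  # (gene_id, first ordinal, run length)
    manifest: Path

    def truth_runs(self) -> set[tuple[str, int, int]]:
        """Planted runs as (gene_id, first, last) for comparison with calls."""
        return {(g, first, first + length - 1) for g, first, length in self.truth}


def _exact_gc_sequence(length: int, gc_target: float, rng: np.random.Generator) -> np.ndarray:
    """Random sequence whose GC count is round(gc_target * length) exactly."""
    n_gc = int(round(gc_target * length))
    seq = np.empty(length, dtype="S1")
    gc_choices = np.frombuffer(b"GC", dtype="S1")
    at_choices = np.frombuffer(b"AT", dtype="S1")
    seq[:n_gc] = gc_choices[rng.integers(0, 2, n_gc)]
    seq[n_gc:] = at_choices[rng.integers(0, 2, length - n_gc)]
    return seq[rng.permutation(length)]


def build_reference_and_annotation(
    spec: SimulationSpec, outdir: str | Path
) -> tuple[Path, Path, Path, list[GeneModel]]:
    """Write FASTA (+ .fai), GTF and capture BED for the spec's gene layout.

    Exon GC targets are drawn uniformly from ``spec.gc_range`` and realized
    exactly (up to rounding) in the emitted sequence.  The BED covers every
    exon fully except for genes listed in ``spec.partial_capture``, whose
    exons are covered only up to the given fraction (0 leaves the exon
    entirely untargeted).
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes: list[GeneModel] = []
    gc_targets: dict[tuple[str, int], float] = {}
    cursor = spec.intergenic_length
    for gi in range(spec.n_genes):
        gid = f"GENE{gi + 1:04d}"
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exons = []
        for ei in range(n_exons):
            length = int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
            exon = ExonModel(
                gene_id=gid,
                ordinal=ei + 1,
                chromosome=CHROM,
                start=cursor,
                end=cursor + length,
            )
            gc_targets[(gid, ei + 1)] = float(
                rng.uniform(spec.gc_range[0], spec.gc_range[1])
            )
            exons.append(exon)
            cursor += length + spec.intron_length
        cursor += spec.intergenic_length - spec.intron_length
        genes.append(GeneModel(gene_id=gid, chromosome=CHROM, strand="+", exons=exons))

    chrom_len = cursor + spec.intergenic_length
    if spec.chromosome_length is not None:
        if spec.chromosome_length < chrom_len:
            raise ValueError(
                f"layout needs {chrom_len} bp but chromosome_length is "
                f"{spec.chromosome_length}"
            )
        chrom_len = spec.chromosome_length

    seq = BASES[rng.integers(0, 4, chrom_len)]
    for gene in genes:
        for exon in gene.exons:
            seq[exon.start : exon.end] = _exact_gc_sequence(
                exon.length, gc_targets[(gene.gene_id, exon.ordinal)], rng
            )

    fasta_path = outdir / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{CHROM}\n")
        raw = seq.tobytes().decode()
        for i in range(0, chrom_len, 60):
            fh.write(raw[i : i + 60] + "\n")
    pysam.faidx(str(fasta_path))

    gtf_path = outdir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        for gene in genes:
            for exon in gene.exons:
                attrs = (
                    f'gene_id "{gene.gene_id}"; '
                    f'transcript_id "{gene.gene_id}.1"; '
                    f'exon_number "{exon.ordinal}";'
                )
                fh.write(
                    f"{CHROM}\tsynthetic\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )

    bed_path = outdir / "capture.bed"
    with open(bed_path, "w") as fh:
        for gene in genes:
            frac = spec.partial_capture.get(gene.gene_id, 1.0)
            for exon in gene.exons:
                if frac <= 0:
                    continue
                end = exon.start + int(round(frac * exon.length))
                fh.write(f"{CHROM}\t{exon.start}\t{end}\n")

    return fasta_path, gtf_path, bed_path, genes


def max_plantable_run(n_exons: int, detectable_only: bool = True) -> int:
    """Longest run plantable in a gene of ``n_exons`` exons.

    Any internal deletion must leave at least one exon (run <= L-1).  With
    ``detectable_only`` the cap tightens to floor((L-1)/2): when half or more
    of a gene's exons are deleted, the gene's median depth collapses to zero
    and the gene-median detection mode has no reference left, so such runs
    are outside the generator's study conditions.
    """
    return (n_exons - 1) // 2 if detectable_only else n_exons - 1


def random_deletions(
    genes: Sequence[GeneModel],
    n: int,
    length_range: tuple[int, int],
    rng: np.random.Generator,
    detectable_only: bool = True,
) -> list[tuple[str, int, int]]:
    """Plant ``n`` internal runs, one per gene, at most one run per gene.

    The run length is drawn from ``length_range`` first, then a gene large
    enough to support it is chosen (see :func:`max_plantable_run`); if none
    remains the length is capped to the largest supportable by an unused
    gene.  Drawing length before gene keeps the realized length distribution
    close to the requested range instead of being squeezed by small genes.
    """
    pool = [g for g in genes if max_plantable_run(g.n_exons, detectable_only) >= 1]
    if n > len(pool):
        raise ValueError(f"cannot plant {n} deletions in {len(pool)} eligible genes")
    order = rng.permutation(len(pool))
    available = [pool[i] for i in order]
    planted = []
    for _ in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        caps = [max_plantable_run(g.n_exons, detectable_only) for g in available]
        fitting = [i for i, cap in enumerate(caps) if cap >= length]
        if fitting:
            idx = fitting[0]
        else:
            idx = max(range(len(available)), key=lambda i: caps[i])
            length = caps[idx]
        gene = available.pop(idx)
        first = int(rng.integers(1, gene.n_exons - length + 2))
        planted.append((gene.gene_id, first, length))
    return sorted(planted)


def _deleted_ordinals(
    planted: Sequence[tuple[str, int, int]]
) -> dict[str, set[int]]:
    deleted: dict[str, set[int]] = {}
    for gid, first, length in planted:
        deleted.setdefault(gid, set()).update(range(first, first + length))
    return deleted


def simulate_bam(
    spec: SimulationSpec,
    fasta_path: str | Path,
    genes: Sequence[GeneModel],
    out_path: str | Path,
    sample_id: str = "sample1",
    seed: Optional[int] = None,
    planted_deletions: Optional[Sequence[tuple[str, int, int]]] = None,
    gc_bias_fn: Optional[Callable[[float], float]] = None,
) -> Path:
    """Simulate a coordinate-sorted, indexed BAM of single-end reads.

    Each non-deleted exon receives uniformly placed reads at expected
    per-base depth ``background_depth * bias(GC)``; exons of planted runs
    receive none.  Fractions of reads can carry MAPQ 0 or uniformly low base
    qualities to exercise the read filters.
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    planted = planted_deletions if planted_deletions is not None else (
        spec.planted_deletions or []
    )
    deleted = _deleted_ordinals(planted)
    bias = gc_bias_fn or (default_gc_bias if spec.gc_bias else (lambda gc: 1.0))

    fasta = pysam.FastaFile(str(fasta_path))
    chrom_len = fasta.get_reference_length(CHROM)
    chrom_seq = fasta.fetch(CHROM)
    fasta.close()

    rl = spec.read_length
    reads: list[tuple[int, str, int, bool]] = []  # (pos, name, mapq, low_bq)
    for gene in genes:
        for exon in gene.exons:
            if exon.ordinal in deleted.get(gene.gene_id, set()):
                continue
            gc = _gc_of(chrom_seq, exon)
            depth = spec.background_depth * bias(gc)
            span = exon.length + rl - 1
            n_reads = int(round(depth * span / rl))
            if n_reads == 0:
                continue
            # Stratified tiling: one read per stratum of the start window with
            # random jitter, so per-base depth stays within ~1 of the target
            # instead of fluctuating by sqrt(depth).
            offsets = (np.arange(n_reads) + rng.random(n_reads)) * span / n_reads
            starts = exon.start - rl + 1 + offsets.astype(np.int64)
            starts = np.clip(starts, 0, chrom_len - rl)
            low_mq = rng.random(n_reads) < spec.low_mapq_fraction
            low_bq = rng.random(n_reads) < spec.low_basequal_fraction
            for k in range(n_reads):
                name = f"r_{gene.gene_id}_{exon.ordinal}_{k}"
                mapq = 0 if low_mq[k] else spec.mapq
                reads.append((int(starts[k]), name, mapq, bool(low_bq[k])))

    reads.sort(key=lambda t: (t[0], t[1]))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": CHROM, "LN": chrom_len}],
        "RG": [{"ID": sample_id, "SM": sample_id}],
        "PG": [{"ID": spec.aligner, "PN": spec.aligner}],
    }
    with pysam.AlignmentFile(str(out_path), "wb", header=header) as bam:
        for pos, name, mapq, low_bq in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigartuples = [(0, rl)]
            a.query_sequence = chrom_seq[pos : pos + rl]
            q = spec.low_base_quality if low_bq else spec.base_quality
            a.query_qualities = pysam.qualitystring_to_array(chr(q + 33) * rl)
            a.set_tag("RG", sample_id)
            a.flag = 0
            bam.write(a)
    pysam.index(str(out_path))
    return out_path


def _gc_of(chrom_seq: str, exon: ExonModel) -> float:
    seq = chrom_seq[exon.start : exon.end].upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    return gc / (gc + at) if gc + at else 0.5


def make_fixtures(
    spec: SimulationSpec,
    outdir: str | Path,
    n_samples: int = 1,
) -> FixtureSet:
    """Generate a complete fixture directory: reference, annotation, capture
    design, one BAM per sample, and a JSON truth manifest of planted runs.

    The planted deletion set is shared across samples.  Each sample's reads
    use a distinct seed derived from the spec seed, so samples differ in
    sampling noise but agree on truth.
    """
    outdir = Path(outdir)
    fasta, gtf, bed, genes = build_reference_and_annotation(spec, outdir)
    rng = np.random.default_rng(spec.seed + 1)
    if spec.planted_deletions is not None:
        planted = list(spec.planted_deletions)
    elif spec.n_planted_deletions > 0:
        planted = random_deletions(
            genes, spec.n_planted_deletions, spec.planted_run_length, rng
        )
    else:
        planted = []
    _check_planted(planted, genes)

    bams = []
    for si in range(n_samples):
        sample_id = f"sample{si + 1}"
        bam = simulate_bam(
            spec,
            fasta,
            genes,
            outdir / f"{sample_id}.bam",
            sample_id=sample_id,
            seed=(spec.seed + 101 + si) % (2**31),
            planted_deletions=planted,
        )
        bams.append(bam)

    manifest_path = outdir / "truth.json"
    manifest = {
        "spec": {
            k: v
            for k, v in asdict(spec).items()
            if k != "planted_deletions"
        },
        "samples": [b.name for b in bams],
        "planted_deletions": [
            {"gene_id": g, "first_exon": f, "run_length": n} for g, f, n in planted
        ],
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")

    return FixtureSet(
        fasta=fasta,
        gtf=gtf,
        bed=bed,
        bams=bams,
        genes=genes,
        truth=planted,
        manifest=manifest_path,
    )


def _check_planted(
    planted: Sequence[tuple[str, int, int]], genes: Sequence[GeneModel]
) -> None:
    by_id = {g.gene_id: g for g in genes}
    for gid, first, length in planted:
        gene = by_id.get(gid)
        if gene is None:
            raise ValueError(f"planted deletion names unknown gene {gid}")
        if length > gene.n_exons - 1:
            raise ValueError(
                f"planted run of {length} exons on {gid} with L={gene.n_exons}: "
                "must leave at least one exon intact"
            )
        if first < 1 or first + length - 1 > gene.n_exons:
            raise ValueError(f"planted run {gid}:{first}+{length} out of range")
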