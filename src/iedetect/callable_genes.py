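"""Capture-kit callability: which genes deletion calling may be attempted on.

A gene is callable when depth dropout over any of its exons cannot be a
capture-design artifact: every exon must be represented in the capture
design (at least one targeted base), and every exon must have at least 90%
of its bases inside target regions (threshold configurable).
"""

from __future__ import annotations

import logging
from typing import Sequence

from .model import CaptureIndex, ExonModel, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERED_FRACTION = 0.9


def exon_covered_fraction(exon: ExonModel, capture: CaptureIndex) -> float:
    """Fraction of the exon's bases lying inside capture target regions."""
    return capture.covered_bases(exon.chromosome, exon.start, exon.end) / exon.length


def is_callable(
    gene: GeneModel,
    capture: CaptureIndex,
    min_fraction: float = DEFAULT_MIN_COVERED_FRACTION,
) -> tuple[bool, list[int]]:
    """Evaluate the two callability conditions on one gene.

    Condition 1: every exon overlaps the capture index by >= 1 base.
    Condition 2: every exon has covered fraction >= ``min_fraction``.
    Returns the flag and the ordinals of failing exons; exon
    ``covered_fraction`` fields are filled in as a side effect.
    """
    failing: list[int] = []
    for exon in gene.exons:
        frac = exon_covered_fraction(exon, capture)
        exon.covered_fraction = frac
        if frac == 0.0 or frac < min_fraction:
            failing.append(exon.ordinal)
    return (not failing, failing)


def annotate_callability(
    genes: Sequence[GeneModel],
    capture: CaptureIndex,
    min_fraction: float = DEFAULT_MIN_COVERED_FRACTION,
) -> list[GeneModel]:
    """Set callable/failing_exons on every gene; returns the callable subset."""
    callable_genes = []
    for gene in genes:
        ok, failing = is_callable(gene, capture, min_fraction)
        gene.callable = ok
        gene.failing_exons = failing
        if ok:
            callable_genes.append(gene)
    logger.info(
        "callability: %d/%d genes callable at min_fraction=%.2f",
        len(callable_genes),
        len(genes),
        min_fraction,
    )
    return callable_genes


def restrict_to_gene_list(
    genes: Sequence[GeneModel], gene_ids: Sequence[str]
) -> list[GeneModel]:
    """Order-preserving restriction to a genes-of-interest list.

    An empty list disables the feature (input returned unchanged).  IDs not
    present among the models are reported as warnings.
    """
    if not gene_ids:
        return list(genes)
    wanted = set(gene_ids)
    known = {g.gene_id for g in genes}
    for missing in sorted(wanted - known):
        logger.warning("gene of interest %s not found in annotation", missing)
    return [g for g in genes if g.gene_id in wanted]
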