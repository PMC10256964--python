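import numpy as np
import pytest

from emats.annotation import GeneModel, TranscriptModel, collapse_meta_exons, flag_alternative
from emats.intervals import GenomeInterval
from emats.simulate import SimConfig


@pytest.fixture
def gene_factory():
    """Build a GeneModel from {transcript_id: [(start, end), ...]}."""

    def make(
        transcripts,
        gene_id="G1",
        chrom="chr1",
        strand="+",
        gene_type="protein_coding",
        span=None,
        collapse=True,
    ):
        txs = []
        for tid, exons in transcripts.items():
            ivs = sorted(
                (GenomeInterval(chrom, s, e, strand) for s, e in exons),
                key=lambda iv: iv.start,
            )
            txs.append(TranscriptModel(tid, gene_id, ivs))
        if span is None:
            lo = min(iv.start for tx in txs for iv in tx.exons)
            hi = max(iv.end for tx in txs for iv in tx.exons)
            span = (lo, hi)
        gene = GeneModel(
            gene_id=gene_id,
            gene_type=gene_type,
            span=GenomeInterval(chrom, span[0], span[1], strand),
            transcripts=txs,
        )
        if collapse:
            gene.meta_exons = collapse_meta_exons(gene)
            for meta in gene.meta_exons:
                meta.is_alternative = flag_alternative(meta, gene)
        return gene

    return make


@pytest.fixture
def small_config():
    """Fast synthetic conditions for structural tests."""
    return SimConfig(seed=7, n_genes=40, n_tissues=3, samples_per_tissue=4)


def union_oracle(pairs):
    """Per-base boolean-array union of (start, end) half-open pairs.

    Merges intervals that share >= 1 base. Bookended intervals touching
    only at a boundary stay separate: a covered run is split at any
    junction no single interval strictly spans.
    """
    hi = max(e for _, e in pairs)
    covered = np.zeros(hi + 1, dtype=bool)
    spanned = np.zeros(hi + 2, dtype=bool)  # junction x lies inside an interval
    for s, e in pairs:
        covered[s:e] = True
        spanned[s + 1 : e] = True
    out = []
    start = None
    for i, on in enumerate(covered):
        if on and (start is None):
            start = i
        elif on and not spanned[i]:  # bookend junction: close and reopen
            out.append((start, i))
            start = i
        elif not on and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(covered)))
    return out
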