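"""Gene models, meta-exon collapsing and gene-architecture metrics.

A gene's annotated exons, pooled over all of its transcripts, are
collapsed into *meta-exons*: the minimal set of maximal non-overlapping
intervals covering every exon. Meta-exons absorb alternative splice
sites, alternative transcription starts and alternative
polyadenylation sites, and are the unit every downstream analysis
(classification, PSI, pairing, variant zoning) operates on.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .intervals import GenomeInterval

Pathish = Union[str, Path]

ROLES = ("first", "internal", "last", "hybrid", "unclassified")


class AnnotationParseError(ValueError):
    """Raised for malformed annotation input, naming the offending line."""


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    exons: list[GenomeInterval] = field(default_factory=list)

    def sort_exons(self) -> None:
        self.exons.sort(key=lambda e: e.start)

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass(eq=False)  # identity semantics: meta-exons are unique objects
class MetaExon:
    """A union-collapsed exon of one gene."""

    interval: GenomeInterval
    gene_id: str
    is_alternative: bool = False
    role: str = "unclassified"
    supporting_transcripts: frozenset = frozenset()

    def overlaps(self, other: "MetaExon") -> bool:
        return self.interval.overlaps(other.interval)


@dataclass
class GeneModel:
    gene_id: str
    gene_type: str
    span: GenomeInterval
    transcripts: list[TranscriptModel] = field(default_factory=list)
    meta_exons: list[MetaExon] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def chrom(self) -> str:
        return self.span.chrom


# ---------------------------------------------------------------------------
# GTF / GFF3 I/O
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(raw: str, lineno: int) -> dict:
    raw = raw.strip()
    if "=" in raw.split(";")[0] and '"' not in raw.split(";")[0]:
        # GFF3 style: key=value;key=value
        attrs = {}
        for chunk in raw.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "=" not in chunk:
                raise AnnotationParseError(
                    f"line {lineno}: malformed GFF3 attribute {chunk!r}"
                )
            k, v = chunk.split("=", 1)
            attrs[k] = v
        # map common GFF3 keys onto GTF-style ones
        if "ID" in attrs and "gene_id" not in attrs:
            attrs.setdefault("gene_id", attrs.get("Parent", attrs["ID"]))
        return attrs
    return dict(_GTF_ATTR.findall(raw))


def _open_text(path: Pathish):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_annotation(
    path: Pathish, gene_type_filter: Optional[str] = "protein_coding"
) -> list[GeneModel]:
    """Parse a GTF/GFF3 annotation into gene models.

    1-based closed coordinates are converted to 0-based half-open.
    Genes whose ``gene_type`` (or ``gene_biotype``) attribute does not
    equal *gene_type_filter* are dropped; pass ``None`` to keep all.
    Gene spans come from ``gene`` feature rows when present, otherwise
    from the min/max over the gene's exons.
    """
    gene_rows: dict[str, dict] = {}
    transcripts: dict[str, TranscriptModel] = {}
    tx_gene_type: dict[str, str] = {}

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, raw = fields
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                start = int(start_s) - 1  # 1-based closed -> 0-based half-open
                end = int(end_s)
            except ValueError:
                raise AnnotationParseError(
                    f"line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if strand not in ("+", "-"):
                raise AnnotationParseError(
                    f"line {lineno}: unknown strand symbol {strand!r}"
                )
            attrs = _parse_attributes(raw, lineno)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise AnnotationParseError(
                    f"line {lineno}: feature lacks gene_id attribute"
                )
            gtype = attrs.get("gene_type", attrs.get("gene_biotype", ""))

            if feature == "gene":
                gene_rows[gene_id] = {
                    "span": GenomeInterval(chrom, start, end, strand),
                    "gene_type": gtype,
                }
            elif feature == "transcript":
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise AnnotationParseError(
                        f"line {lineno}: transcript lacks transcript_id"
                    )
                transcripts.setdefault(tid, TranscriptModel(tid, gene_id))
                if gtype:
                    tx_gene_type.setdefault(gene_id, gtype)
            else:  # exon
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise AnnotationParseError(
                        f"line {lineno}: exon without parent transcript_id"
                    )
                tx = transcripts.setdefault(tid, TranscriptModel(tid, gene_id))
                tx.exons.append(GenomeInterval(chrom, start, end, strand))
                if gtype:
                    tx_gene_type.setdefault(gene_id, gtype)

    genes: dict[str, GeneModel] = {}
    for tx in transcripts.values():
        if not tx.exons:
            continue
        tx.sort_exons()
        gid = tx.gene_id
        if gid not in genes:
            row = gene_rows.get(gid)
            if row is not None:
                span, gtype = row["span"], row["gene_type"]
            else:
                span = None
                gtype = tx_gene_type.get(gid, "")
            genes[gid] = GeneModel(gid, gtype, span)  # span fixed below
        genes[gid].transcripts.append(tx)

    out: list[GeneModel] = []
    for gid, gene in genes.items():
        exons = [e for tx in gene.transcripts for e in tx.exons]
        if gene.span is None:
            gene.span = GenomeInterval(
                exons[0].chrom,
                min(e.start for e in exons),
                max(e.end for e in exons),
                exons[0].strand,
            )
        if gene_type_filter is not None and gene.gene_type != gene_type_filter:
            continue
        gene.meta_exons = collapse_meta_exons(gene)
        for meta in gene.meta_exons:
            meta.is_alternative = flag_alternative(meta, gene)
        out.append(gene)
    out.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return out


def write_gtf(genes: Sequence[GeneModel], path: Pathish) -> None:
    """Write gene/transcript/exon rows in GTF (1-based closed) form."""
    with open(path, "w") as fh:
        for gene in genes:
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_type "{gene.gene_type}";'
            )
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "emats",
                        "gene",
                        str(gene.span.start + 1),
                        str(gene.span.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for tx in gene.transcripts:
                tattrs = (
                    f'gene_id "{gene.gene_id}"; '
                    f'transcript_id "{tx.transcript_id}"; '
                    f'gene_type "{gene.gene_type}";'
                )
                first, last = tx.exons[0], tx.exons[-1]
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            "emats",
                            "transcript",
                            str(first.start + 1),
                            str(last.end),
                            ".",
                            gene.strand,
                            ".",
                            tattrs,
                        ]
                    )
                    + "\n"
                )
                for exon in tx.exons:
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "emats",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                gene.strand,
                                ".",
                                tattrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Meta-exon collapsing and flags
# ---------------------------------------------------------------------------


def collapse_meta_exons(gene: GeneModel) -> list[MetaExon]:
    """Collapse all transcript exons of *gene* into meta-exons.

    Exons overlapping by >= 1 nt are merged; bookended exons sharing
    only a boundary coordinate are kept separate (half-open intervals
    do not overlap). Each meta-exon records every transcript that
    contributes an overlapping exon.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    items = sorted(
        ((e, tx.transcript_id) for tx in gene.transcripts for e in tx.exons),
        key=lambda it: (it[0].start, it[0].end),
    )
    metas: list[MetaExon] = []
    cur_start = cur_end = None
    cur_tx: set[str] = set()
    chrom, strand = gene.chrom, gene.strand

    def _flush() -> None:
        metas.append(
            MetaExon(
                interval=GenomeInterval(chrom, cur_start, cur_end, strand),
                gene_id=gene.gene_id,
                supporting_transcripts=frozenset(cur_tx),
            )
        )

    for exon, tid in items:
        if cur_start is None:
            cur_start, cur_end, cur_tx = exon.start, exon.end, {tid}
        elif exon.start < cur_end:  # strict overlap
            cur_end = max(cur_end, exon.end)
            cur_tx.add(tid)
        else:
            _flush()
            cur_start, cur_end, cur_tx = exon.start, exon.end, {tid}
    if cur_start is not None:
        _flush()
    return metas


def flag_alternative(meta: MetaExon, gene: GeneModel) -> bool:
    """True iff at least one transcript of the gene skips *meta* entirely.

    Overlap is tested at the meta-exon level: a transcript "contains"
    the meta-exon when any of its exons overlaps it by >= 1 nt.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    for tx in gene.transcripts:
        if not any(meta.interval.overlaps(e) for e in tx.exons):
            return True
    return False


# ---------------------------------------------------------------------------
# Architecture metrics
# ---------------------------------------------------------------------------


def gene_length_kb(gene: GeneModel) -> float:
    """Gene length in kilobases: (end - start) / 1000."""
    return (gene.span.end - gene.span.start) / 1000.0


def exon_distance_to_gene_5prime(exon: GenomeInterval, gene: GeneModel) -> int:
    """Distance from an exon to its host gene's 5' coordinate.

    ``exon_start - gene_start`` on the forward strand,
    ``gene_end - exon_end`` on the reverse strand.
    """
    span = gene.span
    if exon.start < span.start or exon.end > span.end:
        raise ValueError(
            f"exon {exon} outside gene span {span} of {gene.gene_id}"
        )
    if exon.chrom != span.chrom or exon.strand != span.strand:
        raise ValueError("exon and gene must share chromosome and strand")
    if span.strand == "+":
        return exon.start - span.start
    return span.end - exon.end


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------


def write_regions(features: Iterable, path: Pathish) -> None:
    """Write meta-exons or wAFE/sSE pairs as BED6.

    The score column is the median PSI scaled by 1000 and rounded
    (0 when no PSI is attached). Pairs emit two lines sharing a pair
    identifier in the name field.
    """
    from .catalog import EmatsPair  # local import to avoid a cycle

    with open(path, "w") as fh:
        fh.write("# BED6: chrom start end name score strand\n")
        for feat in features:
            if isinstance(feat, EmatsPair):
                pid = feat.pair_id
                for tag, meta, psi in (
                    ("wAFE", feat.wafe, feat.wafe_median_psi),
                    ("sSE", feat.sse, feat.sse_median_psi),
                ):
                    _write_bed_line(fh, meta.interval, f"{pid}|{tag}", psi)
            else:
                name = f"{feat.gene_id}|{feat.role}"
                _write_bed_line(
                    fh, feat.interval, name, getattr(feat, "median_psi", None)
                )


def _write_bed_line(fh, iv: GenomeInterval, name: str, psi) -> None:
    score = 0 if psi is None else int(round(psi * 1000))
    fh.write(
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
    )


def read_regions(path: Pathish) -> list[tuple[GenomeInterval, str, int]]:
    """Parse a BED6 file written by :func:`write_regions`."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            out.append(
                (GenomeInterval(chrom, int(start), int(end), strand), name, int(score))
            )
    return out
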