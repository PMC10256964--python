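"""EMATS catalog construction.

An EMATS gene is a protein-coding gene with at least one skipped exon
and two alternative first exons in which a weak alternative first exon
(wAFE: median PSI below the class-wide median) lies within 5 kb
upstream of a strong skipped exon's (sSE: median PSI above the
class-wide median) 5' coordinate, without overlapping it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    GeneModel,
    MetaExon,
    exon_distance_to_gene_5prime,
    gene_length_kb,
)
from .classify import PsiRecord, StrengthCall, median_psi

DEFAULT_MAX_DISTANCE = 5000


@dataclass
class EmatsPair:
    """A (weak AFE, strong SE) pair within one gene."""

    gene_id: str
    wafe: MetaExon
    sse: MetaExon
    distance_5p: int
    wafe_median_psi: Optional[float] = None
    sse_median_psi: Optional[float] = None

    @property
    def pair_id(self) -> str:
        w, s = self.wafe.interval, self.sse.interval
        return f"{self.gene_id}:{w.start}-{w.end}|{s.start}-{s.end}"

    @property
    def key(self) -> tuple:
        return (self.gene_id, self.wafe.interval, self.sse.interval)


@dataclass
class EmatsCatalog:
    scope: str
    pairs: list[EmatsPair] = field(default_factory=list)
    cascade: dict = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return {p.gene_id for p in self.pairs}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            w, s = p.wafe.interval, p.sse.interval
            rows.append(
                {
                    "gene_id": p.gene_id,
                    "chrom": w.chrom,
                    "strand": w.strand,
                    "wafe_start": w.start,
                    "wafe_end": w.end,
                    "sse_start": s.start,
                    "sse_end": s.end,
                    "distance_5p": p.distance_5p,
                    "wafe_median_psi": p.wafe_median_psi,
                    "sse_median_psi": p.sse_median_psi,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id",
                "chrom",
                "strand",
                "wafe_start",
                "wafe_end",
                "sse_start",
                "sse_end",
                "distance_5p",
                "wafe_median_psi",
                "sse_median_psi",
            ],
        )


def find_emats_pairs(
    gene: GeneModel,
    weak_afes: Sequence[MetaExon],
    strong_ses: Sequence[MetaExon],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[EmatsPair]:
    """Enumerate every wAFE/sSE combination satisfying the pairing rules.

    The pair must not overlap, the wAFE 5' coordinate must be
    transcriptionally upstream of the sSE 5' coordinate, and the two 5'
    coordinates must lie within *max_distance* nt (inclusive).
    """
    for exon in list(weak_afes) + list(strong_ses):
        if exon.gene_id != gene.gene_id:
            raise ValueError(
                f"exon of gene {exon.gene_id} passed with gene {gene.gene_id}"
            )
    sign = 1 if gene.strand == "+" else -1
    pairs = []
    for wafe in weak_afes:
        for sse in strong_ses:
            if wafe.overlaps(sse):
                continue
            gap = sign * (sse.interval.five_prime - wafe.interval.five_prime)
            if gap <= 0:  # wAFE must be strictly upstream
                continue
            if gap > max_distance:
                continue
            pairs.append(EmatsPair(gene.gene_id, wafe, sse, gap))
    return pairs


CASCADE_STEPS = [
    "genes_in",
    "protein_coding",
    "with_se",
    "with_two_afes",
    "with_wafe",
    "with_sse",
    "emats_genes",
]


def build_catalog(
    genes: Sequence[GeneModel],
    psi_records: Sequence[PsiRecord],
    strength_calls: Mapping[str, StrengthCall],
    scope: str = "inter-tissue",
    max_distance: int = DEFAULT_MAX_DISTANCE,
    sample_tissue: Optional[Mapping[str, str]] = None,
    medians: Optional[Mapping[str, float]] = None,
) -> EmatsCatalog:
    """Apply the full identification cascade and emit the catalog.

    Cascade: protein-coding -> has >= 1 skipped-exon event -> has >= 2
    alternative-first-exon events -> has a weak AFE -> has a strong SE
    -> pairing. Pairs are deduplicated on (gene, wAFE, sSE) intervals.
    """
    by_event = {r.event_id: r for r in psi_records}
    for event_id in strength_calls:
        if event_id not in by_event:
            raise ValueError(f"strength call for unknown event {event_id}")
    events_by_gene: dict[str, list[PsiRecord]] = {}
    for r in psi_records:
        events_by_gene.setdefault(r.gene_id, []).append(r)
    if medians is None:
        medians = {
            r.event_id: median_psi(r, sample_tissue or {}) for r in psi_records
        }

    def exon_for(gene: GeneModel, record: PsiRecord) -> MetaExon:
        for meta in gene.meta_exons:
            if meta.interval == record.exon:
                return meta
        raise ValueError(
            f"event {record.event_id} has no matching meta-exon"
        )

    cascade = dict.fromkeys(CASCADE_STEPS, 0)
    cascade["genes_in"] = len(genes)
    catalog = EmatsCatalog(scope=scope)
    seen: set[tuple] = set()
    for gene in genes:
        if gene.gene_type != "protein_coding":
            continue
        cascade["protein_coding"] += 1
        events = events_by_gene.get(gene.gene_id, [])
        ses = [r for r in events if r.event_class == "SE"]
        afes = [r for r in events if r.event_class == "AFE"]
        if not ses:
            continue
        cascade["with_se"] += 1
        if len(afes) < 2:
            continue
        cascade["with_two_afes"] += 1
        weak_afes = [
            r
            for r in afes
            if strength_calls.get(r.event_id)
            and strength_calls[r.event_id].call == "weak"
        ]
        strong_ses = [
            r
            for r in ses
            if strength_calls.get(r.event_id)
            and strength_calls[r.event_id].call == "strong"
        ]
        if not weak_afes:
            continue
        cascade["with_wafe"] += 1
        if not strong_ses:
            continue
        cascade["with_sse"] += 1
        pairs = find_emats_pairs(
            gene,
            [exon_for(gene, r) for r in weak_afes],
            [exon_for(gene, r) for r in strong_ses],
            max_distance=max_distance,
        )
        psi_of = {
            exon_for(gene, r).interval: medians.get(r.event_id)
            for r in weak_afes + strong_ses
        }
        emitted = False
        for p in pairs:
            if p.key in seen:
                continue
            seen.add(p.key)
            p.wafe_median_psi = psi_of.get(p.wafe.interval)
            p.sse_median_psi = psi_of.get(p.sse.interval)
            catalog.pairs.append(p)
            emitted = True
        if emitted:
            cascade["emats_genes"] += 1
    cascade["pairs"] = len(catalog.pairs)
    catalog.cascade = cascade
    return catalog


# ---------------------------------------------------------------------------
# Tissue-level summaries
# ---------------------------------------------------------------------------


def call_tissue_specific(
    per_tissue_catalogs: Mapping[str, EmatsCatalog],
    groups: Optional[Mapping[str, str]] = None,
) -> dict[str, set[str]]:
    """Genes identified in one tissue group and no others.

    *groups* maps tissue name -> group label (e.g. every brain
    sub-type -> "brain"), so a gene found in several sub-types of one
    group still counts as specific to that group. Ungrouped tissues
    are their own group.
    """
    if len(per_tissue_catalogs) < 2:
        raise ValueError("tissue-specific calls need >= 2 tissues")
    tissues = set(per_tissue_catalogs)
    groups = dict(groups or {})
    unknown = set(groups) - tissues
    if unknown:
        raise ValueError(f"grouping map names unknown tissues: {sorted(unknown)}")
    group_of = {t: groups.get(t, t) for t in tissues}
    gene_groups: dict[str, set[str]] = {}
    for tissue, cat in per_tissue_catalogs.items():
        for g in cat.genes:
            gene_groups.setdefault(g, set()).add(group_of[tissue])
    specific: dict[str, set[str]] = {g: set() for g in sorted(set(group_of.values()))}
    for gene, seen in gene_groups.items():
        if len(seen) == 1:
            specific[next(iter(seen))].add(gene)
    return specific


def tissue_overlap_matrix(
    per_tissue_catalogs: Mapping[str, EmatsCatalog]
) -> pd.DataFrame:
    """Pairwise Jaccard index of per-tissue EMATS gene sets."""
    names = sorted(per_tissue_catalogs)
    sets = {t: per_tissue_catalogs[t].genes for t in names}
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i in names:
        for j in names:
            union = sets[i] | sets[j]
            if not union:
                mat.loc[i, j] = 0.0
            else:
                mat.loc[i, j] = len(sets[i] & sets[j]) / len(union)
    return mat


def tissue_specific_fold_enrichment(count: int, average: float) -> float:
    """Fold enrichment of one tissue's specific-gene count over the
    per-tissue average."""
    if average <= 0:
        raise ValueError("average must be positive")
    return count / average


# ---------------------------------------------------------------------------
# Architecture summary
# ---------------------------------------------------------------------------


def summarize_architecture(
    catalog: EmatsCatalog, genes: Sequence[GeneModel]
) -> dict:
    """Gene-length, first-exon composition and exon-position summaries.

    Compares EMATS vs non-EMATS gene lengths with a two-sided
    independent (Welch) t-test, reports the obligate-first (FE) vs
    hybrid-first (HFE) percentage among catalog AFEs, and the relative
    position (distance to the gene 5' end over gene length) of FE, HFE
    and SE exons in the catalog.
    """
    emats_ids = catalog.genes
    lengths = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "length_kb": [gene_length_kb(g) for g in genes],
            "is_emats": [g.gene_id in emats_ids for g in genes],
        }
    )
    a = lengths.loc[lengths.is_emats, "length_kb"]
    b = lengths.loc[~lengths.is_emats, "length_kb"]
    if len(a) >= 2 and len(b) >= 2:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        t, p = np.nan, np.nan

    wafes = {}
    for pr in catalog.pairs:
        wafes[(pr.gene_id,) + (pr.wafe.interval,)] = pr.wafe
    n_fe = sum(1 for m in wafes.values() if m.role == "first")
    n_hfe = sum(1 for m in wafes.values() if m.role == "hybrid")
    n_afe = n_fe + n_hfe

    gene_by_id = {g.gene_id: g for g in genes}
    pos_rows = []
    seen_exons = set()
    for pr in catalog.pairs:
        gene = gene_by_id[pr.gene_id]
        glen = gene.span.length
        for meta, kind in ((pr.wafe, None), (pr.sse, "SE")):
            key = (pr.gene_id, meta.interval)
            if key in seen_exons:
                continue
            seen_exons.add(key)
            label = kind or ("FE" if meta.role == "first" else "HFE")
            pos_rows.append(
                {
                    "gene_id": pr.gene_id,
                    "kind": label,
                    "distance_nt": exon_distance_to_gene_5prime(meta.interval, gene),
                    "relative_position": exon_distance_to_gene_5prime(
                        meta.interval, gene
                    )
                    / glen,
                }
            )
    return {
        "gene_lengths": lengths,
        "length_ttest": {"t": float(t), "p": float(p)},
        "fe_pct": 100.0 * n_fe / n_afe if n_afe else np.nan,
        "hfe_pct": 100.0 * n_hfe / n_afe if n_afe else np.nan,
        "positions": pd.DataFrame(
            pos_rows, columns=["gene_id", "kind", "distance_nt", "relative_position"]
        ),
    }
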