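"""Pathogenic-variant selection and positional zoning around EMATS exons.

Each catalog exon (wAFE or sSE) defines five strand-aware zones that
tile its flank without gaps or overlaps: upstream, the acceptor-side
window (the TSS-proximal region of an AFE, the 3' splice site of an
SE), the exon body, the donor-side 5' splice-site window, and
downstream. Window defaults follow canonical splice-site motif
extents: 25 nt acceptor-side, 6 nt donor-side, 1000 nt flank.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .annotation import MetaExon
from .catalog import EmatsCatalog
from .intervals import GenomeInterval

Pathish = Union[str, Path]

ZONES = ("upstream", "tss_or_3ss", "within_exon", "fivess", "downstream")

DEFAULT_WINDOWS = (25, 6, 1000)  # (acc_w, don_w, flank)


@dataclass(frozen=True)
class ZoneCall:
    chrom: str
    pos: int
    pair_id: str
    exon_role: str  # "AFE" or "SE"
    zone: str


def filter_pathogenic(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep pathogenic and likely-pathogenic records.

    A record survives when its clinical significance contains
    "pathogenic" (case-insensitive) and not "conflicting"; benign and
    uncertain calls are dropped. Idempotent.
    """
    if variants.empty:
        return variants.copy()
    sig = variants["significance"].astype(str).str.lower()
    mask = sig.str.contains("pathogenic") & ~sig.str.contains("conflicting")
    return variants.loc[mask].copy()


def zone_ranges(
    exon: Union[MetaExon, GenomeInterval],
    windows: tuple[int, int, int] = DEFAULT_WINDOWS,
) -> dict[str, tuple[int, int]]:
    """Genomic half-open span of each zone around an exon.

    The five spans tile ``[5'-flank, 3'+flank)`` in transcription
    direction with no gaps or overlaps; the acceptor-side window sits
    5' of the exon on both strands.
    """
    acc_w, don_w, flank = windows
    if not (acc_w < flank and don_w < flank):
        raise ValueError("window sizes must be smaller than the flank")
    iv = exon.interval if isinstance(exon, MetaExon) else exon
    if iv.strand == "+":
        return {
            "upstream": (iv.start - flank, iv.start - acc_w),
            "tss_or_3ss": (iv.start - acc_w, iv.start),
            "within_exon": (iv.start, iv.end),
            "fivess": (iv.end, iv.end + don_w),
            "downstream": (iv.end + don_w, iv.end + flank),
        }
    return {
        "upstream": (iv.end + acc_w, iv.end + flank),
        "tss_or_3ss": (iv.end, iv.end + acc_w),
        "within_exon": (iv.start, iv.end),
        "fivess": (iv.start - don_w, iv.start),
        "downstream": (iv.start - flank, iv.start - don_w),
    }


def classify_zone(
    variant,
    exon: Union[MetaExon, GenomeInterval],
    windows: tuple[int, int, int] = DEFAULT_WINDOWS,
) -> Optional[str]:
    """Assign one positional zone to a variant relative to an exon.

    *variant* is anything with ``chrom`` and ``pos`` attributes (or a
    ``(chrom, pos)`` tuple). Returns None beyond the flank.
    """
    iv = exon.interval if isinstance(exon, MetaExon) else exon
    if isinstance(variant, tuple):
        chrom, pos = variant
    else:
        chrom, pos = variant.chrom, variant.pos
    if chrom != iv.chrom:
        raise ValueError(
            f"variant chrom {chrom!r} differs from exon chrom {iv.chrom!r}"
        )
    for zone, (lo, hi) in zone_ranges(iv, windows).items():
        if lo <= pos < hi:
            return zone
    return None


def annotate_zones(
    variants: pd.DataFrame,
    catalog: EmatsCatalog,
    windows: tuple[int, int, int] = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Intersect variants with every catalog exon's flanked region.

    Emits one row per (variant, exon) hit carrying the pair id, the
    exon role (AFE/SE) and the zone. Variants outside every flank are
    dropped. When the variant table names a gene, only exons of that
    gene are considered.
    """
    rows = []
    exons = []
    for p in catalog.pairs:
        exons.append((p.pair_id, p.gene_id, "AFE", p.wafe.interval))
        exons.append((p.pair_id, p.gene_id, "SE", p.sse.interval))
    has_gene = "gene_id" in variants.columns
    for _, var in variants.iterrows():
        for pair_id, gene_id, role, iv in exons:
            if var["chrom"] != iv.chrom:
                continue
            if has_gene and pd.notna(var["gene_id"]) and var["gene_id"] != gene_id:
                continue
            zone = classify_zone((var["chrom"], int(var["pos"])), iv, windows)
            if zone is None:
                continue
            row = var.to_dict()
            row.update(
                {
                    "pair_id": pair_id,
                    "catalog_gene_id": gene_id,
                    "exon_role": role,
                    "zone": zone,
                    "exon_start": iv.start,
                    "exon_end": iv.end,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


def merge_disease_tables(
    morbid_map: pd.DataFrame,
    variants: pd.DataFrame,
    catalog: EmatsCatalog,
    windows: tuple[int, int, int] = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Join a gene-phenotype morbid map onto variants, then zone them.

    Inner join on the gene column, so variants in genes without a
    recorded phenotype drop out; a gene with several phenotypes
    duplicates its variant rows, one per phenotype. The joined table
    is then intersected with the catalog's flanked wAFE/sSE regions.
    """
    key = "gene_id" if "gene_id" in morbid_map.columns else "gene"
    if key not in morbid_map.columns or "phenotype" not in morbid_map.columns:
        raise ValueError("morbid map needs gene_id/gene and phenotype columns")
    if "gene_id" not in variants.columns:
        raise ValueError("variant table needs a gene_id column to join on")
    morbid = morbid_map.rename(columns={key: "gene_id"})[["gene_id", "phenotype"]]
    joined = variants.drop(columns=["phenotype"], errors="ignore").merge(
        morbid, on="gene_id", how="inner"
    )
    return annotate_zones(joined, catalog, windows)


def count_zone_regions(zone_calls: pd.DataFrame) -> dict:
    """Per-zone variant counts plus unique hit-region counts.

    Reports both readings of a "region": window-level (distinct
    (exon, zone) units with >= 1 variant) and exon-level (distinct
    exons with >= 1 variant).
    """
    counts = dict.fromkeys(ZONES, 0)
    if zone_calls.empty:
        return {
            "zone_counts": counts,
            "n_regions_window_level": 0,
            "n_regions_exon_level": 0,
        }
    for zone, n in zone_calls["zone"].value_counts().items():
        counts[zone] = int(n)
    exon_key = ["chrom", "exon_start", "exon_end"]
    return {
        "zone_counts": counts,
        "n_regions_window_level": int(
            zone_calls.drop_duplicates(exon_key + ["zone"]).shape[0]
        ),
        "n_regions_exon_level": int(zone_calls.drop_duplicates(exon_key).shape[0]),
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "significance", "phenotype", "gene_id"]


def read_variants(path: Pathish) -> pd.DataFrame:
    """Read a variant table from TSV (0-based ``pos``) or VCF (1-based).

    VCF significance comes from the ``CLNSIG`` INFO field and the gene
    from ``GENEINFO`` (ClinVar style) when present.
    """
    path = Path(path)
    if path.suffix in (".vcf",) or path.name.endswith(".vcf.gz"):
        import pysam

        rows = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                sig = rec.info.get("CLNSIG", ("",))
                if isinstance(sig, tuple):
                    sig = ",".join(str(s) for s in sig)
                gene = rec.info.get("GENEINFO", None)
                if isinstance(gene, tuple):
                    gene = gene[0]
                if gene:
                    gene = str(gene).split(":")[0]
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos - 1,  # 1-based -> 0-based
                        "ref": rec.ref,
                        "alt": ",".join(rec.alts or ()),
                        "significance": str(sig).replace("_", " "),
                        "phenotype": None,
                        "gene_id": gene,
                    }
                )
        return pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "significance"} - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV lacks columns {sorted(missing)}")
    return df
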