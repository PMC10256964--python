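"""Synthetic data with planted ground truth for every pipeline stage.

The generator emits a gene annotation, per-sample splice-junction
counts, a TPM expression matrix, variant and morbid-map tables, and an
RBP knock-down fraction table — all derived from one seed through
named sub-streams, together with a truth manifest recording what was
planted.

Gene architecture (transcription direction; mirrored on the reverse
strand)::

    AFE2 ----(>5 kb)---- AFE1 - C1 - SE - C2 ----(>5 kb)---- SEd - C3

AFE1/AFE2 are alternative first exons, C1/C2/C3 constitutive exons,
SE the main skipped exon placed ``distance_range`` nt downstream of
AFE1's 5' coordinate, and SEd a decoy skipped exon drawn from the
opposite strength class so the pooled skipped-exon PSI values straddle
0.5 with balanced counts and the class-wide median threshold separates
the two classes by construction; the AFE usage shares of a gene sum to
1, which balances the first-exon pool the same way. EMATS genes place
a weak AFE1 near
a strong SE; non-EMATS genes each violate exactly one criterion,
round-robin: 5' distance beyond 5 kb, strong near-AFE, weak SE, or a
single first exon.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptModel, collapse_meta_exons, flag_alternative
from .intervals import GenomeInterval
from .variants import DEFAULT_WINDOWS, ZONES, zone_ranges

Pathish = Union[str, Path]

# relative (transcription-direction) layout, nt
_AFE2 = (0, 150)
_AFE1 = (6000, 6200)
_C1 = (6230, 6350)
_SE_LEN = 90
_C2_GAP = 40
_C2_LEN = 130
_SED = (16000, 16080)
_C3 = (16500, 16680)
_C3_EMATS = (29500, 29700)  # EMATS genes are longer
_GENE_GAP = 25000

VIOLATIONS = ("distance", "strong_afe", "weak_se", "single_afe")


@dataclass
class CouplingParams:
    beta0: float = 4.0
    beta1_emats: float = 2.0
    beta1_other: float = 0.5
    sigma: float = 0.5


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the default conditions."""

    seed: int = 0
    n_genes: int = 200
    frac_emats: float = 0.15
    n_tissues: int = 5
    samples_per_tissue: int = 30
    depth_mean: float = 50.0
    psi_sample_sd: float = 0.04
    coupling: CouplingParams = field(default_factory=CouplingParams)
    distance_range: tuple[int, int] = (500, 4500)
    zone_mix: tuple[float, ...] = (0.10, 0.20, 0.45, 0.15, 0.10)
    windows: tuple[int, int, int] = DEFAULT_WINDOWS
    pathogenic_frac: float = 0.6
    n_variants_per_exon: int = 3
    morbid_frac: float = 0.7
    # fraction of EMATS genes whose weak AFE is a hybrid (first/internal)
    # exon: it also receives spliced-in reads from the distal first exon
    frac_hybrid_afe: float = 0.35
    n_rbps: int = 250
    n_rbp_outliers: int = 5
    rbp_slope: float = 0.8
    rbp_intercept: float = 0.02
    rbp_scatter: float = 0.01
    rbp_outlier_shift: float = 0.1
    # weak PSI draws are Beta(2,6) truncated to <= 0.5 - strength_margin,
    # strong draws Beta(8,2) truncated to >= 0.5 + strength_margin, so the
    # two strength classes straddle the pooled median by construction
    strength_margin: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_emats <= 1.0:
            raise ValueError("frac_emats must be in [0, 1]")
        if abs(sum(self.zone_mix) - 1.0) > 1e-9 or len(self.zone_mix) != len(ZONES):
            raise ValueError("zone_mix must be 5 probabilities summing to 1")
        c = self.coupling
        if isinstance(c, dict):
            self.coupling = CouplingParams(**c)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("distance_range", "zone_mix", "windows"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


class TruthManifest:
    """Planted ground truth, serialized alongside the generated files."""

    def __init__(self, data: Optional[dict] = None):
        self.data = data or {
            "config": {},
            "genes": {},
            "tissues": [],
            "samples": {},
            "variants": [],
            "rbps": {},
        }

    @property
    def emats_genes(self) -> set[str]:
        return {g for g, rec in self.data["genes"].items() if rec["is_emats"]}

    def planted_pairs(self) -> set[tuple]:
        out = set()
        for g, rec in self.data["genes"].items():
            for p in rec["pairs"]:
                out.add((g, tuple(p["wafe"]), tuple(p["sse"])))
        return out

    def save(self, path: Pathish) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: Pathish) -> "TruthManifest":
        with open(path) as fh:
            return cls(json.load(fh))


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named sub-stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
    )


def _draw_psi(rng: np.random.Generator, strong: bool, margin: float, size: int) -> np.ndarray:
    """Beta-distributed PSI truncated to one side of 0.5 by *margin*."""
    a, b = (8.0, 2.0) if strong else (2.0, 6.0)
    lo, hi = (0.5 + margin, 0.99) if strong else (0.01, 0.5 - margin)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(a, b, size=2 * (size - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = keep[: size - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out


def sample_layout(config: SimConfig) -> tuple[list[str], dict[str, str]]:
    tissues = [f"T{i:02d}" for i in range(config.n_tissues)]
    sample_tissue = {
        f"{t}_{j:03d}": t for t in tissues for j in range(config.samples_per_tissue)
    }
    return tissues, sample_tissue


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _place(rel: tuple[int, int], origin: int, span: int, strand: str, chrom: str) -> GenomeInterval:
    a, b = rel
    if strand == "+":
        return GenomeInterval(chrom, origin + a, origin + b, strand)
    return GenomeInterval(chrom, origin + span - b, origin + span - a, strand)


def generate_annotation(config: SimConfig) -> tuple[list[GeneModel], TruthManifest]:
    """Build the gene models and the truth manifest.

    EMATS genes satisfy all three criteria; each non-EMATS gene
    violates exactly one, assigned round-robin. Genes alternate
    strands and are split over two synthetic chromosomes.
    """
    rng = _rng(config.seed, "annotation")
    tissues, sample_tissue = sample_layout(config)
    manifest = TruthManifest()
    manifest.data["config"] = config.to_dict()
    manifest.data["tissues"] = tissues
    manifest.data["samples"] = sample_tissue

    n_emats = int(round(config.n_genes * config.frac_emats))
    genes: list[GeneModel] = []
    cursors = {"chrS1": 10_000, "chrS2": 10_000}
    lo_d, hi_d = config.distance_range
    margin = config.strength_margin

    for i in range(config.n_genes):
        gene_id = f"G{i:04d}"
        is_emats = i < n_emats
        violation = None if is_emats else VIOLATIONS[(i - n_emats) % len(VIOLATIONS)]
        chrom = "chrS1" if i % 2 == 0 else "chrS2"
        strand = "+" if (i // 2) % 2 == 0 else "-"

        if violation == "distance":
            d = int(rng.integers(5500, 8000))
        else:
            d = int(rng.integers(lo_d, hi_d + 1))
        se_rel = (_AFE1[0] + d, _AFE1[0] + d + _SE_LEN)
        c2_rel = (se_rel[1] + _C2_GAP, se_rel[1] + _C2_GAP + _C2_LEN)
        c3_rel = _C3_EMATS if is_emats else _C3
        span = c3_rel[1]

        origin = cursors[chrom]
        cursors[chrom] = origin + span + _GENE_GAP

        single_afe = violation == "single_afe"
        rel_exons = {
            "AFE1": _AFE1,
            "C1": _C1,
            "SE": se_rel,
            "C2": c2_rel,
            "SEd": _SED,
            "C3": c3_rel,
        }
        if not single_afe:
            rel_exons["AFE2"] = _AFE2
        iv = {
            name: _place(rel, origin, span, strand, chrom)
            for name, rel in rel_exons.items()
        }

        def tx(tid: str, names: list[str]) -> TranscriptModel:
            exons = sorted((iv[n] for n in names), key=lambda e: e.start)
            return TranscriptModel(tid, gene_id, exons)

        transcripts = [
            tx(f"{gene_id}.t1", ["AFE1", "C1", "SE", "C2", "SEd", "C3"]),
            tx(f"{gene_id}.t2", ["AFE1", "C1", "C2", "C3"]),
        ]
        if not single_afe:
            transcripts.append(
                tx(f"{gene_id}.t3", ["AFE2", "C1", "SE", "C2", "SEd", "C3"])
            )
        hybrid_afe1 = is_emats and rng.random() < config.frac_hybrid_afe
        if hybrid_afe1:
            # AFE1 used internally downstream of AFE2 in one isoform
            transcripts.append(
                tx(f"{gene_id}.t4", ["AFE2", "AFE1", "C1", "SE", "C2", "SEd", "C3"])
            )

        gene = GeneModel(
            gene_id=gene_id,
            gene_type="protein_coding",
            span=GenomeInterval(chrom, origin, origin + span, strand),
            transcripts=transcripts,
        )
        gene.meta_exons = collapse_meta_exons(gene)
        for meta in gene.meta_exons:
            meta.is_alternative = flag_alternative(meta, gene)
        genes.append(gene)

        # planted PSI truth, per tissue
        afe1_weak = violation != "strong_afe"
        se_strong = violation != "weak_se"
        u = _draw_psi(rng, strong=not afe1_weak, margin=margin, size=len(tissues))
        p = _draw_psi(rng, strong=se_strong, margin=margin, size=len(tissues))
        # decoy SE from the opposite strength class: balances the pooled
        # skipped-exon PSI distribution around 0.5 without tying the decoy
        # to the main exon's values
        q = _draw_psi(rng, strong=not se_strong, margin=margin, size=len(tissues))

        pairs = []
        if is_emats:
            pairs.append(
                {
                    "wafe": [iv["AFE1"].start, iv["AFE1"].end],
                    "sse": [iv["SE"].start, iv["SE"].end],
                    "distance": d,
                }
            )
        manifest.data["genes"][gene_id] = {
            "is_emats": is_emats,
            "violation": violation,
            "chrom": chrom,
            "strand": strand,
            "span": [origin, origin + span],
            "single_afe": single_afe,
            "hybrid_afe1": hybrid_afe1,
            "exons": {name: [e.start, e.end] for name, e in iv.items()},
            "afe1_usage": dict(zip(tissues, map(float, u))),
            "se_psi": dict(zip(tissues, map(float, p))),
            "sed_psi": dict(zip(tissues, map(float, q))),
            "distance": d,
            "pairs": pairs,
        }
    return genes, manifest


# ---------------------------------------------------------------------------
# Junction counts
# ---------------------------------------------------------------------------


def _junction_row(iv_up: GenomeInterval, iv_down: GenomeInterval) -> tuple:
    """(donor, acceptor) for a junction from iv_up to iv_down
    (transcription order)."""
    return (iv_up.three_prime, iv_down.five_prime)


def generate_junction_counts(
    manifest: TruthManifest, config: SimConfig
) -> pd.DataFrame:
    """Per-sample junction read counts consistent with the planted PSI.

    First-exon downstream reads are multinomial in the planted usage;
    skipped-exon inclusion reads are binomial in the planted PSI with
    Poisson(depth_mean) depth per event; constitutive junctions carry
    the balancing reads. Zero-count junctions are omitted.
    """
    rng = _rng(config.seed, "junctions")
    tissues, sample_tissue = sample_layout(config)
    samples = list(sample_tissue)
    tissue_idx = np.array([tissues.index(sample_tissue[s]) for s in samples])
    n = len(samples)
    sd = config.psi_sample_sd

    chunks = []

    def emit(chrom, strand, donor, acceptor, counts):
        mask = counts > 0
        if not mask.any():
            return
        chunks.append(
            pd.DataFrame(
                {
                    "sample_id": np.asarray(samples)[mask],
                    "chrom": chrom,
                    "donor": donor,
                    "acceptor": acceptor,
                    "strand": strand,
                    "count": counts[mask],
                }
            )
        )

    def per_sample_psi(by_tissue: dict) -> np.ndarray:
        base = np.array([by_tissue[t] for t in tissues])[tissue_idx]
        if sd > 0:
            base = base + rng.normal(0.0, sd, n)
        return np.clip(base, 0.01, 0.99)

    for gene_id, rec in manifest.data["genes"].items():
        chrom, strand = rec["chrom"], rec["strand"]
        iv = {
            name: GenomeInterval(chrom, se[0], se[1], strand)
            for name, se in rec["exons"].items()
        }

        # first-exon usage reads
        u = per_sample_psi(rec["afe1_usage"])
        d_afe = rng.poisson(config.depth_mean, n)
        if rec["single_afe"]:
            afe1 = d_afe
        else:
            afe1 = rng.binomial(d_afe, u)
        dn, ac = _junction_row(iv["AFE1"], iv["C1"])
        emit(chrom, strand, dn, ac, afe1)
        if not rec["single_afe"]:
            dn, ac = _junction_row(iv["AFE2"], iv["C1"])
            emit(chrom, strand, dn, ac, d_afe - afe1)
        if rec.get("hybrid_afe1"):
            # spliced-in reads arriving at AFE1's 5' boundary: about half
            # its downstream load, so the pooled imbalance sits near +1/3
            # (between the internal and terminal thresholds)
            dn, ac = _junction_row(iv["AFE2"], iv["AFE1"])
            emit(chrom, strand, dn, ac, rng.binomial(afe1, 0.5))

        # main skipped exon
        p = per_sample_psi(rec["se_psi"])
        depth = rng.poisson(config.depth_mean, n)
        x = rng.binomial(depth, p)
        dn, ac = _junction_row(iv["C1"], iv["SE"])
        emit(chrom, strand, dn, ac, x)
        dn, ac = _junction_row(iv["SE"], iv["C2"])
        emit(chrom, strand, dn, ac, x)
        dn, ac = _junction_row(iv["C1"], iv["C2"])
        emit(chrom, strand, dn, ac, depth - x)

        # decoy skipped exon
        q = per_sample_psi(rec["sed_psi"])
        depth2 = rng.poisson(config.depth_mean, n)
        y = rng.binomial(depth2, q)
        dn, ac = _junction_row(iv["C2"], iv["SEd"])
        emit(chrom, strand, dn, ac, y)
        dn, ac = _junction_row(iv["SEd"], iv["C3"])
        emit(chrom, strand, dn, ac, y)
        dn, ac = _junction_row(iv["C2"], iv["C3"])
        emit(chrom, strand, dn, ac, depth2 - y)

    if not chunks:
        return pd.DataFrame(columns=["sample_id", "chrom", "donor", "acceptor", "strand", "count"])
    out = pd.concat(chunks, ignore_index=True)
    return out.sort_values(
        ["chrom", "strand", "donor", "acceptor", "sample_id"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(manifest: TruthManifest, config: SimConfig) -> pd.DataFrame:
    """TPM matrix (genes x samples) with a planted PSI->expression slope.

    log2 TPM = beta0 + beta1 * truePSI(SE) + Normal(0, sigma), with
    beta1 = beta1_emats for EMATS genes and beta1_other for the rest.
    """
    rng = _rng(config.seed, "expression")
    tissues, sample_tissue = sample_layout(config)
    samples = list(sample_tissue)
    tissue_idx = np.array([tissues.index(sample_tissue[s]) for s in samples])
    n = len(samples)
    c = config.coupling
    rows = {}
    for gene_id, rec in manifest.data["genes"].items():
        base = np.array([rec["se_psi"][t] for t in tissues])[tissue_idx]
        if config.psi_sample_sd > 0:
            base = base + rng.normal(0.0, config.psi_sample_sd, n)
        p = np.clip(base, 0.01, 0.99)
        beta1 = c.beta1_emats if rec["is_emats"] else c.beta1_other
        log2tpm = c.beta0 + beta1 * p
        if c.sigma > 0:
            log2tpm = log2tpm + rng.normal(0.0, c.sigma, n)
        rows[gene_id] = np.power(2.0, log2tpm)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.index.name = "gene_id"
    return df


# ---------------------------------------------------------------------------
# Variants / morbid map
# ---------------------------------------------------------------------------

_PATHOGENIC = ["Pathogenic", "Likely pathogenic"]
_NON_PATHOGENIC = [
    "Benign",
    "Uncertain significance",
    "Conflicting interpretations of pathogenicity",
]
_BASES = np.array(list("ACGT"))


def generate_variants(
    manifest: TruthManifest, config: SimConfig
) -> pd.DataFrame:
    """Variants planted in the zones of every EMATS pair exon.

    Zone identity per variant is drawn from ``zone_mix``; the position
    is uniform within that zone's genomic span; significance labels
    are pathogenic with probability ``pathogenic_frac``. The true zone
    of each variant is recorded in the manifest.
    """
    rng = _rng(config.seed, "variants")
    rows = []
    truth = []
    for gene_id, rec in manifest.data["genes"].items():
        if not rec["is_emats"]:
            continue
        chrom, strand = rec["chrom"], rec["strand"]
        for pair in rec["pairs"]:
            for role, key in (("AFE", "wafe"), ("SE", "sse")):
                iv = GenomeInterval(chrom, pair[key][0], pair[key][1], strand)
                ranges = zone_ranges(iv, config.windows)
                for _ in range(config.n_variants_per_exon):
                    zone = ZONES[rng.choice(len(ZONES), p=config.zone_mix)]
                    lo, hi = ranges[zone]
                    pos = int(rng.integers(lo, hi))
                    pathogenic = rng.random() < config.pathogenic_frac
                    pool = _PATHOGENIC if pathogenic else _NON_PATHOGENIC
                    sig = pool[int(rng.integers(len(pool)))]
                    ref, alt = rng.choice(_BASES, 2, replace=False)
                    rows.append(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "ref": ref,
                            "alt": alt,
                            "significance": sig,
                            "phenotype": None,
                            "gene_id": gene_id,
                        }
                    )
                    truth.append(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "gene_id": gene_id,
                            "exon_role": role,
                            "exon": [iv.start, iv.end],
                            "zone": zone,
                            "significance": sig,
                        }
                    )
    manifest.data["variants"] = truth
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "significance", "phenotype", "gene_id"],
    )


def generate_morbid_map(manifest: TruthManifest, config: SimConfig) -> pd.DataFrame:
    """Gene-phenotype table covering a fraction of the EMATS genes."""
    rng = _rng(config.seed, "morbid")
    rows = []
    for gene_id, rec in manifest.data["genes"].items():
        if rec["is_emats"] and rng.random() < config.morbid_frac:
            rows.append(
                {"gene_id": gene_id, "phenotype": f"Synthetic disorder {gene_id}"}
            )
    return pd.DataFrame(rows, columns=["gene_id", "phenotype"])


# ---------------------------------------------------------------------------
# RBP knock-down fractions
# ---------------------------------------------------------------------------


def generate_rbp_experiments(config: SimConfig) -> pd.DataFrame:
    """Per-RBP up/down fractions on a planted line with outliers.

    Gene fractions follow ``intercept + slope * SE fraction`` with
    Gaussian scatter; ``n_rbp_outliers`` RBPs are displaced from the
    line (up direction) by ``rbp_outlier_shift``. The ``is_outlier``
    column carries the truth and is stripped before writing the
    experiment table.
    """
    rng = _rng(config.seed, "rbp")
    n = config.n_rbps
    names = [f"RBP{i:03d}" for i in range(n)]
    x_up = rng.uniform(0.01, 0.4, n)
    x_down = rng.uniform(0.01, 0.4, n)
    y_up = config.rbp_intercept + config.rbp_slope * x_up
    y_down = config.rbp_intercept + config.rbp_slope * x_down
    if config.rbp_scatter > 0:
        y_up = y_up + rng.normal(0, config.rbp_scatter, n)
        y_down = y_down + rng.normal(0, config.rbp_scatter, n)
    outliers = rng.choice(n, size=min(config.n_rbp_outliers, n), replace=False)
    is_outlier = np.zeros(n, dtype=bool)
    is_outlier[outliers] = True
    y_up = np.where(is_outlier, y_up + config.rbp_outlier_shift, y_up)
    df = pd.DataFrame(
        {
            "rbp": names,
            "frac_up_genes": np.clip(y_up, 0, 1),
            "frac_down_genes": np.clip(y_down, 0, 1),
            "frac_up_se": x_up,
            "frac_down_se": x_down,
            "is_outlier": is_outlier,
        }
    )
    return df
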