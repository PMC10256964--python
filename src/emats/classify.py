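"""Exon role classification and PSI quantification from splice-junction reads.

Junctions are keyed by ``(chrom, donor, acceptor, strand)`` in the
0-based half-open convention: the donor coordinate is the
transcription-direction 3' boundary of the upstream exon and the
acceptor coordinate the 5' boundary of the downstream exon. On the
forward strand donor = exon end and acceptor = next exon start; on the
reverse strand the roles of genomic start/end swap.

An exon's splice-junction-read (SJR) profile — reads arriving at its
5' boundary (``n_up``) versus reads leaving its 3' boundary
(``n_down``) — determines its role: obligate first exons show a pure
downstream imbalance, last exons a pure upstream one, internal exons
are balanced, and hybrid exons sit in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import GeneModel, MetaExon
from .intervals import GenomeInterval

Pathish = Union[str, Path]

JUNCTION_COLUMNS = ["sample_id", "chrom", "donor", "acceptor", "strand", "count"]


class JunctionCounts:
    """Per-sample splice-junction read counts with a sample->tissue map."""

    def __init__(self, df: pd.DataFrame, sample_tissue: Optional[Mapping[str, str]] = None):
        missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"junction table lacks columns {missing}")
        if (df["count"] < 0).any():
            raise ValueError("junction counts must be non-negative")
        self.df = df
        self.sample_tissue = dict(sample_tissue) if sample_tissue else {}
        if len(df):
            mat = df.pivot_table(
                index=["chrom", "strand", "donor", "acceptor"],
                columns="sample_id",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
        else:
            mat = pd.DataFrame(
                index=pd.MultiIndex.from_arrays(
                    [[], [], [], []], names=["chrom", "strand", "donor", "acceptor"]
                )
            )
        for s in self.sample_tissue:
            if s not in mat.columns:
                mat[s] = 0
        mat = mat[sorted(mat.columns)]
        self._mat = mat
        self.samples: list[str] = list(mat.columns)
        self._donor = mat.groupby(level=["chrom", "strand", "donor"]).sum()
        self._acceptor = mat.groupby(level=["chrom", "strand", "acceptor"]).sum()
        # per (chrom, strand): intron bounds + count matrix for skip lookups
        self._span: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        idx = mat.index
        if len(idx):
            donors = idx.get_level_values("donor").to_numpy()
            acceptors = idx.get_level_values("acceptor").to_numpy()
            lo = np.minimum(donors, acceptors)
            hi = np.maximum(donors, acceptors)
            keys = list(zip(idx.get_level_values("chrom"), idx.get_level_values("strand")))
            arr = mat.to_numpy()
            bykey: dict[tuple[str, str], list[int]] = {}
            for i, k in enumerate(keys):
                bykey.setdefault(k, []).append(i)
            for k, rows in bykey.items():
                rows = np.asarray(rows)
                self._span[k] = (lo[rows], hi[rows], arr[rows])

    # -- lookups ----------------------------------------------------------
    def _row(self, table: pd.DataFrame, key) -> pd.Series:
        if key in table.index:
            return table.loc[key]
        return pd.Series(0, index=self.samples)

    def acceptor_counts(self, chrom: str, strand: str, coord: int) -> pd.Series:
        """Reads of junctions whose acceptor is *coord*, per sample."""
        return self._row(self._acceptor, (chrom, strand, coord))

    def donor_counts(self, chrom: str, strand: str, coord: int) -> pd.Series:
        """Reads of junctions whose donor is *coord*, per sample."""
        return self._row(self._donor, (chrom, strand, coord))

    def spanning_counts(self, exon: GenomeInterval) -> pd.Series:
        """Reads of junctions whose intron fully spans *exon*, per sample."""
        key = (exon.chrom, exon.strand)
        if key not in self._span:
            return pd.Series(0, index=self.samples)
        lo, hi, arr = self._span[key]
        mask = (lo <= exon.start) & (hi >= exon.end)
        return pd.Series(arr[mask].sum(axis=0), index=self.samples)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls, path: Pathish, sample_map: Optional[Pathish] = None
    ) -> "JunctionCounts":
        df = pd.read_csv(path, sep="\t")
        tissue = read_sample_map(sample_map) if sample_map else None
        return cls(df, tissue)

    def to_tsv(self, path: Pathish) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_sample_map(path: Pathish) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"], df["tissue"]))


# ---------------------------------------------------------------------------
# SJR profiles and roles
# ---------------------------------------------------------------------------


@dataclass
class ExonSJRProfile:
    """Up/down splice-junction reads at one exon's boundaries."""

    n_up: int
    n_down: int

    @property
    def hit(self) -> Optional[float]:
        """Downstream SJR imbalance in [-1, 1]; None with zero coverage."""
        total = self.n_up + self.n_down
        if total <= 0:
            return None
        return (self.n_down - self.n_up) / total


def sjr_profile(
    exon: Union[MetaExon, GenomeInterval],
    counts: JunctionCounts,
    sample: Optional[str] = None,
) -> ExonSJRProfile:
    """Compute an exon's SJR profile for one sample (or pooled when None)."""
    iv = exon.interval if isinstance(exon, MetaExon) else exon
    up = counts.acceptor_counts(iv.chrom, iv.strand, iv.five_prime)
    down = counts.donor_counts(iv.chrom, iv.strand, iv.three_prime)
    if sample is not None:
        return ExonSJRProfile(int(up.get(sample, 0)), int(down.get(sample, 0)))
    return ExonSJRProfile(int(up.sum()), int(down.sum()))


def classify_exon(
    profiles: Union[ExonSJRProfile, Iterable[ExonSJRProfile]],
    thresholds: tuple[float, float] = (0.8, 0.2),
    min_reads: int = 10,
) -> str:
    """Assign a role from pooled SJR imbalance.

    ``hit >= t_terminal`` -> first; ``hit <= -t_terminal`` -> last;
    ``|hit| <= t_internal`` -> internal; the two intermediate bands are
    hybrid. Below *min_reads* pooled coverage -> unclassified.
    """
    t_terminal, t_internal = thresholds
    if not (t_terminal > t_internal > 0):
        raise ValueError(
            f"need t_terminal > t_internal > 0, got {thresholds}"
        )
    if isinstance(profiles, ExonSJRProfile):
        profiles = [profiles]
    n_up = sum(p.n_up for p in profiles)
    n_down = sum(p.n_down for p in profiles)
    pooled = ExonSJRProfile(n_up, n_down)
    if n_up + n_down < min_reads or pooled.hit is None:
        return "unclassified"
    hit = pooled.hit
    if hit >= t_terminal:
        return "first"
    if hit <= -t_terminal:
        return "last"
    if abs(hit) <= t_internal:
        return "internal"
    return "hybrid"


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------


def afe_psi(
    gene: GeneModel,
    first_exons: Sequence[MetaExon],
    counts: JunctionCounts,
    sample: Optional[str] = None,
) -> dict[MetaExon, Optional[float]]:
    """First-exon usage: each exon's share of downstream SJRs.

    Shares sum to 1 over the gene's first exons when any downstream
    reads exist; all values are missing (None) otherwise.
    """
    if not first_exons:
        raise ValueError(f"no first exons supplied for gene {gene.gene_id}")
    downs = []
    for meta in first_exons:
        iv = meta.interval
        d = counts.donor_counts(iv.chrom, iv.strand, iv.three_prime)
        downs.append(d.get(sample, 0) if sample is not None else d.sum())
    total = float(sum(downs))
    if total <= 0:
        return {m: None for m in first_exons}
    return {m: d / total for m, d in zip(first_exons, downs)}


def se_psi(inclusion_up: int, inclusion_down: int, skip: int) -> Optional[float]:
    """Skipped-exon PSI from junction counts.

    With inclusion total I read over two junctions and skipping over
    one, PSI = (I/2) / ((I/2) + skip). Undefined (None) with zero
    coverage.
    """
    if inclusion_up < 0 or inclusion_down < 0 or skip < 0:
        raise ValueError("junction counts must be non-negative")
    inc = (inclusion_up + inclusion_down) / 2.0
    denom = inc + skip
    if denom <= 0:
        return None
    return inc / denom


@dataclass
class PsiRecord:
    """One splicing event's per-sample PSI values."""

    event_id: str
    event_class: str  # "AFE" or "SE"
    gene_id: str
    exon: GenomeInterval
    psi_by_sample: dict = field(default_factory=dict)
    role: str = "unclassified"

    def defined(self) -> dict:
        return {
            s: v for s, v in self.psi_by_sample.items() if v is not None and not np.isnan(v)
        }


def median_psi(
    record: PsiRecord,
    sample_tissue: Mapping[str, str],
    how: str = "mean_then_median",
) -> Optional[float]:
    """Median PSI across tissues.

    Default aggregation is the per-tissue mean of defined per-sample
    values followed by the median over tissues; ``how="pooled_median"``
    takes one median over all defined samples instead. Tissues with no
    defined value are ignored; returns None when nothing is defined.
    """
    vals = record.defined()
    if not vals:
        return None
    if how == "pooled_median":
        return float(np.median(list(vals.values())))
    if how != "mean_then_median":
        raise ValueError(f"unknown aggregation {how!r}")
    per_tissue: dict[str, list[float]] = {}
    for s, v in vals.items():
        per_tissue.setdefault(sample_tissue.get(s, s), []).append(v)
    means = [float(np.mean(v)) for v in per_tissue.values()]
    return float(np.median(means))


@dataclass(frozen=True)
class StrengthCall:
    event_id: str
    call: str  # weak / strong / neither


def call_strength(
    records: Sequence[PsiRecord],
    sample_tissue: Mapping[str, str],
    medians: Optional[Mapping[str, float]] = None,
) -> dict[str, StrengthCall]:
    """Call each event weak or strong against its class-wide median.

    The threshold is the median of all events' median PSI within one
    event class; events strictly below are weak, strictly above are
    strong, exact ties get "neither".
    """
    if not records:
        raise ValueError("cannot call strength on an empty event class")
    classes = {r.event_class for r in records}
    if len(classes) != 1:
        raise ValueError(f"records mix event classes {sorted(classes)}")
    if len(records) < 2:
        raise ValueError("need at least two events to define a class median")
    if medians is None:
        medians = {r.event_id: median_psi(r, sample_tissue) for r in records}
    defined = {e: m for e, m in medians.items() if m is not None}
    if not defined:
        raise ValueError("no event has a defined median PSI")
    threshold = float(np.median(list(defined.values())))
    calls = {}
    for r in records:
        m = defined.get(r.event_id)
        if m is None or m == threshold:
            call = "neither"
        elif m < threshold:
            call = "weak"
        else:
            call = "strong"
        calls[r.event_id] = StrengthCall(r.event_id, call)
    return calls


# ---------------------------------------------------------------------------
# Event enumeration over a gene set
# ---------------------------------------------------------------------------


def event_id_for(gene_id: str, event_class: str, iv: GenomeInterval) -> str:
    return f"{gene_id}:{event_class}:{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"


def compute_psi_records(
    genes: Sequence[GeneModel],
    counts: JunctionCounts,
    thresholds: tuple[float, float] = (0.8, 0.2),
    min_reads: int = 10,
) -> list[PsiRecord]:
    """Classify meta-exon roles and build per-sample PSI records.

    Roles are written back onto each gene's meta-exons. AFE events are
    alternative exons classified first or positive-side hybrid; their
    per-sample PSI is the downstream-SJR usage share. SE events are
    alternative internal exons; their PSI is the junction-count
    inclusion ratio. Only annotated meta-exons are ever classified.
    """
    records: list[PsiRecord] = []
    samples = counts.samples
    for gene in genes:
        firsts: list[MetaExon] = []
        for meta in gene.meta_exons:
            pooled = sjr_profile(meta, counts)
            meta.role = classify_exon(pooled, thresholds, min_reads)
            if meta.role == "first" or (
                meta.role == "hybrid" and pooled.hit is not None and pooled.hit > 0
            ):
                firsts.append(meta)

        afe_candidates = [m for m in firsts if m.is_alternative]
        if afe_candidates:
            down = {
                m: counts.donor_counts(
                    m.interval.chrom, m.interval.strand, m.interval.three_prime
                )
                for m in afe_candidates
            }
            total = sum(down.values())
            for meta in afe_candidates:
                with np.errstate(invalid="ignore"):
                    share = down[meta] / total
                psi = {
                    s: (None if total[s] == 0 else float(share[s])) for s in samples
                }
                records.append(
                    PsiRecord(
                        event_id=event_id_for(gene.gene_id, "AFE", meta.interval),
                        event_class="AFE",
                        gene_id=gene.gene_id,
                        exon=meta.interval,
                        psi_by_sample=psi,
                        role=meta.role,
                    )
                )

        for meta in gene.meta_exons:
            if meta.role != "internal" or not meta.is_alternative:
                continue
            iv = meta.interval
            inc_up = counts.acceptor_counts(iv.chrom, iv.strand, iv.five_prime)
            inc_down = counts.donor_counts(iv.chrom, iv.strand, iv.three_prime)
            skip = counts.spanning_counts(iv)
            inc = (inc_up + inc_down) / 2.0
            denom = inc + skip
            psi = {
                s: (None if denom[s] <= 0 else float(inc[s] / denom[s]))
                for s in samples
            }
            records.append(
                PsiRecord(
                    event_id=event_id_for(gene.gene_id, "SE", iv),
                    event_class="SE",
                    gene_id=gene.gene_id,
                    exon=iv,
                    psi_by_sample=psi,
                    role=meta.role,
                )
            )
    return records
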