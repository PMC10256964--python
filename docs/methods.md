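# Methods

## The catalog definition

An EMATS gene (exon-mediated activation of transcription starts) is a
protein-coding gene in which splicing of an internal exon can enhance
usage of a nearby upstream promoter. Operationally the catalog keeps a
gene when all of the following hold:

1. it has at least one skipped exon (SE) whose median percent-spliced-in
   (PSI) across tissues is **above** the median of all SE events (a
   *strong* SE, sSE);
2. it has at least two alternative first exons (AFEs), one of which has
   median PSI **below** the AFE-wide median (a *weak* AFE, wAFE); and
3. a wAFE lies transcriptionally upstream of an sSE, the two exons do
   not overlap, and their 5' coordinates are within 5 kb (inclusive).

Both strength thresholds are *class-relative medians*, so "weak" and
"strong" are defined against the cohort being analyzed, not against
fixed PSI cutoffs. Ties with the class median are called "neither" and
never enter the catalog; the inequality on both sides is strict.

All internal coordinates are 0-based half-open; GTF (1-based closed)
and VCF (1-based) are converted at I/O boundaries only.

## Meta-exons

All exons of a gene, pooled over transcripts, are collapsed into
meta-exons: maximal intervals merged wherever exons share at least one
base. Bookended exons that touch only at a boundary are *not* merged —
under half-open semantics they do not overlap, and merging them would
fuse genuinely distinct acceptor/donor architecture. A meta-exon is
*alternative* when at least one transcript of the gene contains no exon
overlapping it (a single-transcript gene therefore has only
constitutive exons).

## Exon roles from splice-junction reads

Junctions are keyed by (chromosome, donor, acceptor, strand), with
donor = the transcription-direction 3' boundary of the upstream exon.
For an exon, `n_up` counts reads whose acceptor is its 5' boundary and
`n_down` reads whose donor is its 3' boundary. The downstream
imbalance

    hit = (n_down − n_up) / (n_down + n_up)   ∈ [−1, 1]

classifies pooled profiles: `hit ≥ 0.8` obligate first, `≤ −0.8` last,
`|hit| ≤ 0.2` internal, the two bands in between hybrid (the positive
band being hybrid first/internal). Exons with fewer than 10 pooled
reads stay unclassified, and only annotated meta-exons are ever
classified. The two thresholds and the read floor are configurable;
the defaults put the obligate calls close to pure imbalance while
keeping a wide internal band, and the planted hybrid profile
(upstream load ≈ half the downstream load, hit ≈ +1/3) falls squarely
in the hybrid band.

## PSI

* **AFE PSI** is first-exon usage: an AFE's share of the summed
  `n_down` over the gene's first (and positive-hybrid) exons. Shares
  sum to 1 per gene and sample; with zero coverage the values are
  missing, never 0.
* **SE PSI** uses junction counts with effective lengths 2 (inclusion:
  two junctions) and 1 (skipping): with I = upstream + downstream
  inclusion reads, `PSI = (I/2) / (I/2 + skip)`.
* **Median PSI across tissues** is the per-tissue mean of defined
  per-sample values followed by the median over tissues (a pooled
  median over all samples is available as an option). Undefined values
  propagate as missing throughout.

## Variant zones

Each catalog exon defines five strand-aware zones tiling its flank
exactly once: upstream / acceptor-side window / exon body / donor-side
window / downstream. Window defaults are 25 nt acceptor-side (the TSS-
proximal region of an AFE, the 3' splice site of an SE — the geometry
is identical, only the label differs), 6 nt donor-side (the 5' splice
site), and a 1000 nt flank; these follow canonical splice-site motif
extents and are CLI-configurable. Pathogenic filtering keeps clinical
significance strings containing "pathogenic" (case-insensitive,
"likely pathogenic" included) and drops "conflicting" records. The
disease join is an inner join on gene against a morbid-map table, so a
gene with several phenotypes duplicates its variant rows. Because the
"regions" unit is ambiguous, region counts are reported at both the
(exon, zone) window level and the exon level.

## Coupling statistics

Per splicing event, coupling is the Spearman correlation (average
ranks on ties) between per-sample PSI and host-gene TPM. Observations
with PSI exactly 0 or 1 are dropped individually — the literal
per-observation reading of constitutive inclusion/exclusion; a
per-event mode (drop the event only when PSI is constant at 0 or 1)
is available behind a flag. At least 70 surviving pairs are required,
otherwise no correlation is reported. Event-level rho values are
merged per gene by arithmetic mean (median optional). EMATS vs
non-EMATS rho distributions are compared with a two-sided Welch
t-test; the unequal-variance form is the robust default for the group
sizes involved. Quantile binning (quartiles/sextiles) assigns
equal-probability bins with ties broken by rank order.

For the RBP knock-down analysis, per-experiment fractions of
significantly (adjusted p strictly < 0.05) up/down genes and skipped
exons are taken against the totals each tool reported. Gene fractions
are regressed on SE fractions by OLS separately for the up and down
directions, and the union of the top-k (default 17) absolute residuals
is selected, alphabetically tie-broken; residuals below 1e-12 are
treated as exactly zero so collinear input degenerates
deterministically.

## The synthetic study

The generator plants every structure the pipeline is supposed to find.
Defaults (all in `SimConfig`): 200 genes, 15% EMATS, 5 tissues x 30
samples, Poisson junction depth with mean 50 reads per event,
per-sample PSI jitter sd 0.04, wAFE–sSE distances uniform on
[500, 4500] nt. Each gene carries two first exons (one >5 kb from
everything downstream), one main SE at the planted distance from the
proximal AFE, one decoy SE >5 kb from any AFE, and three constitutive
exons; both strands and two chromosomes are used. Non-EMATS genes each
violate exactly one criterion, assigned round-robin: distance drawn
from [5500, 8000] nt, a strong proximal AFE, a weak main SE, or a
single first exon. 35% of EMATS genes make the weak AFE a hybrid exon
via an extra isoform that splices into it from the distal first exon.
EMATS genes are also drawn ~13 kb longer, reproducing the
longer-gene architecture signal the catalog summary tests for.

Two constructions make the class-median strength thresholds exact by
design rather than by luck:

* weak PSI values are Beta(2, 6) draws rejection-truncated to ≤ 0.45
  and strong values Beta(8, 2) truncated to ≥ 0.55 (margin
  `strength_margin = 0.05`), so no planted value sits near the
  threshold;
* AFE usage shares sum to 1 within a gene (so each 2-AFE gene
  contributes one value on each side of 0.5), and every gene carries
  one SE of each strength class, keeping both pools balanced around
  0.5.

The decoy SE's PSI is drawn independently from the opposite strength
class rather than mirrored as 1 − PSI of the main exon: a mirrored
decoy would couple to expression with exactly the opposite sign and
cancel the gene-level merged rho.

Expression is `log2 TPM = β0 + β1·PSI(main SE) + N(0, σ)` per sample,
with β1 = 2.0 for EMATS genes and 0.5 otherwise and σ = 0.5, placing
EMATS genes' merged rho visibly above the rest under the default
depth. Variants are drawn per planted pair exon: a zone from the
`zone_mix` probability vector (default 10/20/45/15/10% across the five
zones, concentrating in the exon body and splice sites), a position
uniform within the zone's span, and a pathogenic label with
probability 0.6. RBP fractions lie on a planted line (slope 0.8,
intercept 0.02, scatter sd 0.01) with 5 of 250 experiments displaced
by 0.1 — ten scatter sd, comfortably beyond the 5-sd recovery bound.

All randomness flows from one seed through named sub-streams (CRC32 of
the stream name mixed into the seed sequence), so adding a generator
never perturbs the draws of another, and a fixed seed reproduces every
file byte for byte.

### What the simulation does and does not emulate

It emulates the statistical skeleton: junction-count sampling noise,
tissue structure, class-relative strength, positional zones, a
planted splicing-to-expression slope, and an RBP residual structure.
It does not emulate realistic chromosome sizes, overlapping or nested
genes, unannotated exons, intron retention, read-level artifacts
(mappability, GC, 3' bias), population structure among samples, or
linkage between variants. Passing the recovery tests therefore shows
the pipeline implements its definitions correctly under calibrated
noise — not that the catalog criteria are robust to every artifact of
real RNA-seq.

## Numerical and scale choices

* Problem sizes in the test-suite and acceptance runs (200 genes for
  recovery, 1000 interval sets for the collapse oracle, 100 vector
  pairs for the Spearman oracle, depth 1000 for estimator error,
  50 genes x 15 samples for the PSI error run) keep every check under
  a minute on one CPU while leaving comfortable statistical margins.
* AFE shares are exact ratios; SE PSI at depth d has estimator error
  O(1/sqrt(d)) — mean absolute error ≈ 0.01 at depth 1000.
* Medians of even-sized pools are midpoints of the two central values;
  the planted 0.1 margin between strength classes dwarfs both this and
  sampling error.
* Empty tissues, all-missing events, zero-coverage exons, and empty
  tables all propagate as missing values or empty outputs rather than
  zeros or errors.

## Known limitations

The exon-role classifier is a deliberate simplification: a single
imbalance ratio with fixed thresholds, not a generative model of SJR
profiles — adequate for clean annotated exons, less so for shallow or
mixed profiles. First/last exon PSI is junction-based usage, which
ignores unspliced (single-exon) transcripts. Tissue-specific calls
depend on the tissue panel supplied: adding tissues can only shrink
specific sets. The disease join matches on gene identity only; no
variant-level functional assessment is attempted.
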