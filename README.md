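# emats

Identification of **EMATS genes** — genes whose transcription can be
activated through splicing of an internal exon (exon-mediated
activation of transcription starts) — from a gene annotation and
splice-junction read counts, with downstream analyses of pathogenic
variants and splicing–expression coupling.

The package is aimed at transcriptomics researchers who want to scan a
gene set for the EMATS architecture, localize clinical variants within
it, or quantify how exon inclusion tracks host-gene expression — and at
method developers who need a fully planted-truth simulator to test such
pipelines without any external data.

## The criteria

A gene enters the catalog when:

1. it is protein-coding with at least one skipped exon (SE) whose
   median PSI across tissues exceeds the SE-wide median (a strong SE,
   *sSE*);
2. it has ≥ 2 alternative first exons (AFEs), at least one with median
   PSI below the AFE-wide median (a weak AFE, *wAFE*); and
3. a wAFE lies within 5 kb upstream of an sSE's 5′ coordinate without
   overlapping it.

Exon roles (first / internal / last / hybrid) come from the
splice-junction read imbalance hit = (n_down − n_up)/(n_down + n_up);
AFE PSI is downstream-junction usage share, SE PSI the junction
inclusion ratio (I/2)/((I/2) + skip). Splicing–expression coupling is
the Spearman ρ between an event's PSI and its gene's TPM over ≥ 70
paired samples, after dropping constitutive (PSI ∈ {0, 1})
observations. See `docs/methods.md` for the full model.

## Worked example

Run the full synthetic pipeline (simulate → scan → variant zoning →
coupling → RBP selection) with one seed:

```bash
emats run --seed 1 --out-dir out/
```

The cascade log printed to stderr mirrors the identification funnel:

```
genes_in        200
protein_coding  200
with_se         200
with_two_afes   158
with_wafe       158
with_sse        158
emats_genes     30
pairs           30
```

200 synthetic genes enter; 42 fail the two-AFE requirement (single-AFE
genes have a constitutive, hence ineligible, first exon); of the 158
remaining, exactly the 30 planted EMATS genes survive the weak-AFE /
strong-SE / ≤ 5 kb pairing, one wAFE–sSE pair each. `out/run_summary.json`
records the downstream results of the same run, e.g. the coupling
comparison

```json
"coupling_test": {
 "mean_emats": 0.1366, "mean_other": 0.0306,
 "t": 5.51, "p": 4.0e-06, "stars": "*****"
}
```

— genes with the EMATS structure show a markedly stronger positive
association between SE inclusion and expression than the rest, as
planted (β1 = 2.0 vs 0.5 on log2 TPM) — and the first-exon composition
`fe_pct: 66.7, hfe_pct: 33.3` (obligate vs hybrid first exons among
catalog wAFEs). Other outputs: `catalog.tsv` (one row per wAFE–sSE
pair with coordinates, distance and median PSIs), `emats_regions.bed`,
`psi_matrix.tsv`, `variant_zones.tsv` with per-zone counts,
`coupling.tsv` (gene-level ρ), and `rbp_selected.tsv`.

Each stage is also a standalone subcommand operating on plain TSV/GTF
files — `emats simulate | annotate | classify | scan | variants |
couple | rbp | report` — and everything is importable from the
library:

```python
from emats import parse_annotation, JunctionCounts, scan_genes

genes = parse_annotation("annotation.gtf", "protein_coding")
counts = JunctionCounts.from_tsv("junctions.tsv", "sample_map.tsv")
result = scan_genes(genes, counts)
result.catalog.to_frame()       # the pair table
result.catalog.cascade          # the funnel counts
```

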