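import numpy as np
import pytest

from emats.annotation import MetaExon, parse_annotation
from emats.catalog import (
    EmatsCatalog,
    build_catalog,
    call_tissue_specific,
    find_emats_pairs,
    summarize_architecture,
    tissue_overlap_matrix,
    tissue_specific_fold_enrichment,
)
from emats.classify import JunctionCounts, PsiRecord
from emats.intervals import GenomeInterval
from emats.pipeline import scan_genes, simulate_to_dir
from emats.simulate import SimConfig, TruthManifest, generate_annotation


def meta(gene_id, start, end, strand="+", chrom="chr1", role="unclassified"):
    return MetaExon(
        GenomeInterval(chrom, start, end, strand), gene_id=gene_id, role=role
    )


class TestFindPairs:
    def test_forward_pair_and_distance(self, gene_factory):
        gene = gene_factory({"t1": [(1000, 1200)]}, span=(1000, 9000))
        pairs = find_emats_pairs(
            gene, [meta("G1", 1000, 1200)], [meta("G1", 3000, 3100)]
        )
        assert len(pairs) == 1 and pairs[0].distance_5p == 2000

    def test_distance_threshold_inclusive(self, gene_factory):
        gene = gene_factory({"t1": [(1000, 1200)]}, span=(1000, 9000))
        at_limit = find_emats_pairs(
            gene, [meta("G1", 1000, 1200)], [meta("G1", 6000, 6100)]
        )
        assert len(at_limit) == 1  # exactly 5000 nt is allowed
        beyond = find_emats_pairs(
            gene, [meta("G1", 1000, 1200)], [meta("G1", 6500, 6600)]
        )
        assert beyond == []

    def test_reverse_strand_five_prime_distance(self, gene_factory):
        gene = gene_factory({"t1": [(8000, 8200)]}, strand="-", span=(1000, 9000))
        pairs = find_emats_pairs(
            gene,
            [meta("G1", 8000, 8200, "-")],
            [meta("G1", 4000, 4100, "-")],
        )
        assert len(pairs) == 1 and pairs[0].distance_5p == 4100

    def test_overlap_and_downstream_wafe_rejected(self, gene_factory):
        gene = gene_factory({"t1": [(1000, 1200)]}, span=(1000, 9000))
        overlapping = find_emats_pairs(
            gene, [meta("G1", 1000, 1200)], [meta("G1", 1100, 1300)]
        )
        assert overlapping == []
        downstream = find_emats_pairs(
            gene, [meta("G1", 3000, 3200)], [meta("G1", 2000, 2100)]
        )
        assert downstream == []

    def test_foreign_exon_rejected(self, gene_factory):
        gene = gene_factory({"t1": [(1000, 1200)]})
        with pytest.raises(ValueError):
            find_emats_pairs(gene, [meta("G2", 1000, 1200)], [])

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_brute_force_oracle(self, gene_factory, strand):
        rng = np.random.default_rng(17)
        gene = gene_factory({"t1": [(0, 10)]}, strand=strand, span=(0, 50_000))
        for _ in range(50):
            wafes = [
                meta("G1", s, s + 100, strand)
                for s in rng.integers(0, 40_000, 4).tolist()
            ]
            sses = [
                meta("G1", s, s + 80, strand)
                for s in rng.integers(0, 40_000, 4).tolist()
            ]
            got = {
                (p.wafe.interval.start, p.sse.interval.start, p.distance_5p)
                for p in find_emats_pairs(gene, wafes, sses)
            }
            expected = set()
            for w in wafes:
                for s in sses:
                    if w.interval.overlaps(s.interval):
                        continue
                    w5, s5 = w.interval.five_prime, s.interval.five_prime
                    upstream = w5 < s5 if strand == "+" else w5 > s5
                    if upstream and abs(s5 - w5) <= 5000:
                        expected.add(
                            (w.interval.start, s.interval.start, abs(s5 - w5))
                        )
            assert got == expected

    def test_monotone_in_max_distance(self, gene_factory):
        rng = np.random.default_rng(23)
        gene = gene_factory({"t1": [(0, 10)]}, span=(0, 50_000))
        wafes = [meta("G1", s, s + 100) for s in rng.integers(0, 40_000, 6).tolist()]
        sses = [meta("G1", s, s + 80) for s in rng.integers(0, 40_000, 6).tolist()]
        near = {
            p.key for p in find_emats_pairs(gene, wafes, sses, max_distance=5000)
        }
        far = {
            p.key for p in find_emats_pairs(gene, wafes, sses, max_distance=10000)
        }
        assert near <= far


def scan_noise_free(tmp_path, n_genes=60, seed=3):
    config = SimConfig(
        seed=seed,
        n_genes=n_genes,
        n_tissues=3,
        samples_per_tissue=4,
        depth_mean=1000.0,
        psi_sample_sd=0.0,
    )
    paths = simulate_to_dir(config, tmp_path / "sim")
    genes = parse_annotation(paths["annotation.gtf"], "protein_coding")
    counts = JunctionCounts.from_tsv(paths["junctions.tsv"], paths["sample_map.tsv"])
    manifest = TruthManifest.load(paths["truth.json"])
    return genes, counts, manifest


class TestBuildCatalog:
    def test_recovers_planted_genes_and_pairs_exactly(self, tmp_path):
        genes, counts, manifest = scan_noise_free(tmp_path)
        result = scan_genes(genes, counts, per_tissue=False)
        assert result.catalog.genes == manifest.emats_genes
        got_pairs = {
            (p.gene_id, (p.wafe.interval.start, p.wafe.interval.end),
             (p.sse.interval.start, p.sse.interval.end))
            for p in result.catalog.pairs
        }
        assert got_pairs == manifest.planted_pairs()

    def test_cascade_is_monotone_and_counts_genes(self, tmp_path):
        genes, counts, _ = scan_noise_free(tmp_path)
        cascade = scan_genes(genes, counts, per_tissue=False).catalog.cascade
        steps = [v for k, v in cascade.items() if k != "pairs"]
        assert steps == sorted(steps, reverse=True)

    def test_single_afe_gene_excluded(self, tmp_path):
        genes, counts, manifest = scan_noise_free(tmp_path)
        single = {
            g for g, rec in manifest.data["genes"].items() if rec["single_afe"]
        }
        assert single  # round-robin guarantees some
        assert not (scan_genes(genes, counts, per_tissue=False).catalog.genes & single)

    def test_hybrid_weak_afes_recovered_with_hybrid_role(self, tmp_path):
        genes, counts, manifest = scan_noise_free(tmp_path, n_genes=80)
        catalog = scan_genes(genes, counts, per_tissue=False).catalog
        roles = {p.gene_id: p.wafe.role for p in catalog.pairs}
        truth = {
            g: rec["hybrid_afe1"]
            for g, rec in manifest.data["genes"].items()
            if rec["is_emats"]
        }
        assert any(truth.values()) and not all(truth.values())
        for gene_id, is_hybrid in truth.items():
            assert roles[gene_id] == ("hybrid" if is_hybrid else "first")

    def test_empty_input_empty_catalog(self):
        catalog = build_catalog([], [], {}, scope="inter-tissue")
        assert catalog.pairs == [] and catalog.genes == set()

    def test_strength_call_for_unknown_event_rejected(self):
        from emats.classify import StrengthCall

        with pytest.raises(ValueError):
            build_catalog([], [], {"ghost": StrengthCall("ghost", "weak")})

    def test_invariant_under_gene_order_permutation(self, tmp_path):
        genes, counts, _ = scan_noise_free(tmp_path, n_genes=30)
        forward = scan_genes(genes, counts, per_tissue=False).catalog
        backward = scan_genes(genes[::-1], counts, per_tissue=False).catalog
        assert {p.key for p in forward.pairs} == {p.key for p in backward.pairs}


def catalog_of(*gene_ids):
    cat = EmatsCatalog(scope="t")
    for g in gene_ids:
        wafe = meta(g, 100, 200)
        sse = meta(g, 1000, 1100)
        from emats.catalog import EmatsPair

        cat.pairs.append(EmatsPair(g, wafe, sse, 900))
    return cat


class TestTissueLevel:
    def test_specific_to_single_tissue(self):
        cats = {"A": catalog_of("g1", "g2"), "B": catalog_of("g2"), "C": catalog_of()}
        specific = call_tissue_specific(cats)
        assert specific == {"A": {"g1"}, "B": set(), "C": set()}

    def test_sub_types_of_one_group_may_share(self):
        cats = {
            "brain-cortex": catalog_of("g1"),
            "brain-amygdala": catalog_of("g1"),
            "liver": catalog_of("g2"),
        }
        groups = {"brain-cortex": "brain", "brain-amygdala": "brain"}
        specific = call_tissue_specific(cats, groups)
        assert specific["brain"] == {"g1"} and specific["liver"] == {"g2"}

    def test_unknown_tissue_in_grouping_map_rejected(self):
        cats = {"A": catalog_of("g1"), "B": catalog_of()}
        with pytest.raises(ValueError):
            call_tissue_specific(cats, {"Z": "brain"})
        with pytest.raises(ValueError):
            call_tissue_specific({"A": catalog_of("g1")})

    def test_groups_partition_specific_genes(self):
        cats = {
            "A": catalog_of("g1", "g3"),
            "B": catalog_of("g2", "g3"),
            "C": catalog_of("g4"),
        }
        specific = call_tissue_specific(cats)
        sets = list(specific.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_jaccard_overlap_matrix(self):
        cats = {
            "A": catalog_of("a", "b", "c"),
            "B": catalog_of("b", "c", "d"),
            "C": catalog_of(),
        }
        mat = tissue_overlap_matrix(cats)
        assert mat.loc["A", "A"] == 1.0
        assert mat.loc["A", "B"] == pytest.approx(0.5)
        assert mat.loc["A", "C"] == 0.0
        assert mat.loc["C", "C"] == 0.0  # empty set has no well-defined overlap
        assert np.allclose(mat.values, mat.values.T)

    def test_fold_enrichment_requires_positive_average(self):
        assert tissue_specific_fold_enrichment(46, 23.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            tissue_specific_fold_enrichment(10, 0.0)


class TestArchitectureSummary:
    def test_fe_hfe_percentages(self, gene_factory):
        from emats.catalog import EmatsPair

        cat = EmatsCatalog(scope="t")
        genes = []
        for i, role in enumerate(["first", "first", "first", "hybrid"]):
            g = f"g{i}"
            genes.append(
                gene_factory({"t1": [(100, 200)], "t2": [(1000, 1100)]}, gene_id=g)
            )
            cat.pairs.append(
                EmatsPair(g, meta(g, 100, 200, role=role), meta(g, 1000, 1100), 900)
            )
        summary = summarize_architecture(cat, genes)
        assert summary["fe_pct"] == pytest.approx(75.0)
        assert summary["hfe_pct"] == pytest.approx(25.0)

    def test_planted_length_bias_detected(self, tmp_path):
        genes, counts, manifest = scan_noise_free(tmp_path)
        catalog = scan_genes(genes, counts, per_tissue=False).catalog
        summary = summarize_architecture(catalog, genes)
        df = summary["gene_lengths"]
        assert (
            df.loc[df.is_emats, "length_kb"].mean()
            > df.loc[~df.is_emats, "length_kb"].mean()
        )
        assert summary["length_ttest"]["p"] < 1e-4
        assert summary["length_ttest"]["t"] > 0
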