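import math
import random

import pytest

from gcmkit.context_refiner import (
    INF,
    RefinementParams,
    assign_genome_genes,
    cluster_genes_by_context,
    compile_gcm,
    gene_distance,
    pairwise_module_distances,
    refine_modules,
)
from gcmkit.fixtures import GenomeSpec, PlantedCluster, make_genome
from gcmkit.modules import Module

from .oracles import single_linkage_clusters


def _catalog(n=100, circular=False, replicons=None, genome_id="g"):
    reps = replicons or (("chr", n, circular),)
    _, _, cat = make_genome(GenomeSpec(genome_id, tuple(reps), seed=5))
    return cat


def _locus(cat, replicon, rank):
    return cat.replicons[replicon][rank].locus_tag


def _module(mid, genes, compounds=None, pfams=None, genome="g"):
    return Module(
        module_id=mid, kind="IRM", map_id="map_t",
        compound_ids=compounds or [f"C_{mid}"],
        pfam_set=set(pfams or ()),
        gene_ids=set(genes),
        gene_assignments={genome: set(genes)},
    )


class TestGeneDistance:
    def test_adjacent_genes(self):
        cat = _catalog()
        assert gene_distance(cat, _locus(cat, "chr", 4), _locus(cat, "chr", 5)) == 1

    def test_same_gene_zero(self):
        cat = _catalog()
        g = _locus(cat, "chr", 7)
        assert gene_distance(cat, g, g) == 0

    def test_circular_wraparound(self):
        cat = _catalog(n=100, circular=True)
        assert gene_distance(cat, _locus(cat, "chr", 0), _locus(cat, "chr", 99)) == 1

    def test_cross_replicon_is_infinite(self):
        cat = _catalog(replicons=(("chr", 50, False), ("plasmid", 20, False)))
        d = gene_distance(
            cat, _locus(cat, "chr", 0), _locus(cat, "plasmid", 0)
        )
        assert d == INF

    def test_unknown_locus_raises(self):
        cat = _catalog()
        with pytest.raises(KeyError, match="nope"):
            gene_distance(cat, "nope", _locus(cat, "chr", 0))


class TestPairwiseModuleDistances:
    def test_minimum_over_gene_pairs(self):
        cat = _catalog()
        m1 = _module("M1", {_locus(cat, "chr", 5), _locus(cat, "chr", 6)})
        m2 = _module("M2", {_locus(cat, "chr", 12)})
        inter, intra = pairwise_module_distances(cat, [m1, m2], "g")
        assert inter[("M1", "M2")] == 6  # min(|5-12|, |6-12|)

    def test_single_gene_module_intra_zero(self):
        cat = _catalog()
        m = _module("M1", {_locus(cat, "chr", 3)})
        _, intra = pairwise_module_distances(cat, [m], "g")
        assert intra["M1"] == 0

    def test_all_ncr2_pairs_present(self):
        cat = _catalog()
        mods = [_module(f"M{i}", {_locus(cat, "chr", 10 * i)}) for i in range(3)]
        inter, _ = pairwise_module_distances(cat, mods, "g")
        assert len(inter) == 3  # 3 choose 2

    def test_module_absent_from_genome_flagged_inf(self):
        cat = _catalog()
        m1 = _module("M1", {_locus(cat, "chr", 5)})
        m2 = Module(module_id="M2", kind="IRM", map_id="map_t",
                    compound_ids=["C2"])
        inter, intra = pairwise_module_distances(cat, [m1, m2], "g")
        assert inter[("M1", "M2")] == INF
        assert intra["M2"] == INF


class TestClusterGenesByContext:
    def test_two_blocks_split_at_large_gap(self):
        cat = _catalog(n=100)
        genes = {_locus(cat, "chr", r) for r in (5, 6, 8, 50, 52)}
        clusters = cluster_genes_by_context(cat, genes, RefinementParams(10))
        ranks = [sorted(cat.gene(g).rank for g in c) for c in clusters]
        assert ranks == [[5, 6, 8], [50, 52]]

    def test_all_within_threshold_one_cluster(self):
        cat = _catalog(n=100)
        genes = {_locus(cat, "chr", r) for r in (5, 10, 15, 20)}
        clusters = cluster_genes_by_context(cat, genes, RefinementParams(10))
        assert len(clusters) == 1

    def test_threshold_one_no_neighbours_all_singletons(self):
        cat = _catalog(n=100)
        genes = {_locus(cat, "chr", r) for r in (5, 10, 20, 40)}
        clusters = cluster_genes_by_context(cat, genes, RefinementParams(1))
        assert all(len(c) == 1 for c in clusters)

    def test_empty_gene_set(self):
        cat = _catalog()
        assert cluster_genes_by_context(cat, set(), RefinementParams(10)) == []

    def test_circular_join_across_origin(self):
        cat = _catalog(n=100, circular=True)
        genes = {_locus(cat, "chr", r) for r in (0, 97, 50)}
        clusters = cluster_genes_by_context(cat, genes, RefinementParams(5))
        as_ranks = {
            frozenset(cat.gene(g).rank for g in c) for c in clusters
        }
        assert as_ranks == {frozenset({0, 97}), frozenset({50})}

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_quadratic_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(20, 200)
        circular = rng.random() < 0.5
        cat = _catalog(n=n, circular=circular)
        genes = {
            _locus(cat, "chr", r)
            for r in rng.sample(range(n), rng.randint(1, min(30, n)))
        }
        t = rng.randint(1, 25)
        ours = cluster_genes_by_context(cat, genes, RefinementParams(t))
        assert {frozenset(c) for c in ours} == single_linkage_clusters(
            cat, genes, t
        )


class TestRefineModules:
    def test_interleaved_irms_merge(self):
        cat = _catalog(n=100)
        m1 = _module("M1", {_locus(cat, "chr", r) for r in (10, 14)},
                     compounds=["CA", "CB"])
        m2 = _module("M2", {_locus(cat, "chr", r) for r in (12, 16)},
                     compounds=["CC"])
        ims = refine_modules([m1, m2], cat, "g")
        assert len(ims) == 1
        assert set(ims[0].compound_ids) == {"CA", "CB", "CC"}
        assert "merged" in ims[0].flags

    def test_distant_blocks_split_one_irm(self):
        cat = _catalog(n=600)
        genes = {_locus(cat, "chr", r) for r in (0, 1, 2, 3, 500, 501, 502, 503)}
        m = _module("M1", genes, compounds=["CA", "CB"])
        ims = refine_modules([m], cat, "g")
        assert len(ims) == 2
        assert all("split" in im.flags for im in ims)
        assert all(set(im.compound_ids) == {"CA", "CB"} for im in ims)

    def test_tight_cluster_is_fixed_point(self):
        cat = _catalog(n=100)
        genes = {_locus(cat, "chr", r) for r in (20, 21, 22)}
        m = _module("M1", genes, compounds=["CA"])
        ims = refine_modules([m], cat, "g")
        assert len(ims) == 1
        assert ims[0].gene_ids == genes
        assert ims[0].compound_ids == ["CA"]
        assert not {"split", "merged"} & ims[0].flags

    def test_singletons_flagged_unclustered(self):
        cat = _catalog(n=100)
        m = _module("M1", {_locus(cat, "chr", 10), _locus(cat, "chr", 80)})
        ims = refine_modules([m], cat, "g")
        assert len(ims) == 2
        assert all("unclustered" in im.flags for im in ims)

    def test_gene_conservation(self):
        cat = _catalog(n=300)
        rng = random.Random(3)
        genes = {_locus(cat, "chr", r) for r in rng.sample(range(300), 40)}
        m = _module("M1", genes)
        ims = refine_modules([m], cat, "g")
        assert set().union(*(im.gene_ids for im in ims)) == genes

    def test_idempotence(self):
        cat = _catalog(n=300)
        rng = random.Random(4)
        genes = {_locus(cat, "chr", r) for r in rng.sample(range(300), 30)}
        ims = refine_modules([_module("M1", genes)], cat, "g")
        again = refine_modules(ims, cat, "g")
        assert [sorted(m.gene_ids) for m in again] == [
            sorted(m.gene_ids) for m in ims
        ]

    @pytest.mark.parametrize("seed", range(6))
    def test_im_count_monotone_in_threshold(self, seed):
        rng = random.Random(100 + seed)
        n = rng.randint(50, 400)
        cat = _catalog(n=n, circular=rng.random() < 0.5)
        genes = {
            _locus(cat, "chr", r)
            for r in rng.sample(range(n), rng.randint(2, 30))
        }
        m = _module("M1", genes)
        counts = [
            len(refine_modules([m], cat, "g", RefinementParams(t)))
            for t in (1, 3, 10, 30)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_cross_replicon_separation(self):
        cat = _catalog(replicons=(("chr", 50, False), ("plasmid", 50, False)))
        genes = {_locus(cat, "chr", 10), _locus(cat, "chr", 11),
                 _locus(cat, "plasmid", 10), _locus(cat, "plasmid", 11)}
        ims = refine_modules([_module("M1", genes)], cat, "g")
        for im in ims:
            reps = {cat.gene(g).replicon_id for g in im.gene_ids}
            assert len(reps) == 1

    def test_linker_resolved_to_nearest_module(self):
        cat = _catalog(n=100)
        near = {_locus(cat, "chr", r) for r in (10, 11)}
        far = {_locus(cat, "chr", r) for r in (40, 41)}
        linker = _locus(cat, "chr", 13)
        m1 = _module("M1", near | {linker}, compounds=["CA"])
        m2 = _module("M2", far | {linker}, compounds=["CB"])
        ims = refine_modules([m1, m2], cat, "g")
        with_linker = [im for im in ims if linker in im.gene_ids]
        assert len(with_linker) == 1
        # the linker sits 2 ranks from M1's genes: only M1's compounds
        # flow into its cluster
        assert set(with_linker[0].compound_ids) == {"CA"}

    def test_no_genes_on_genome_yields_no_ims(self):
        cat = _catalog()
        m = Module(module_id="M1", kind="IRM", map_id="map_t", compound_ids=["C"])
        assert refine_modules([m], cat, "g") == []


class TestConsensusIms:
    def _im(self, mid, genome, compounds, pfams):
        return Module(
            module_id=mid, kind="IM", map_id="map_t",
            compound_ids=compounds, pfam_set=set(pfams),
            gene_assignments={genome: {f"{genome}_g"}},
        )

    def test_pattern_supported_by_two_genomes_survives_min_support_2(self):
        from gcmkit.context_refiner import consensus_ims

        shared_a = self._im("a1", "gA", ["C1", "C2"], {"PF00001"})
        shared_b = self._im("b1", "gB", ["C1", "C2"], {"PF00001"})
        lone = self._im("a2", "gA", ["C3"], {"PF00002"})
        out = consensus_ims({"gA": [shared_a, lone], "gB": [shared_b]},
                            min_support=2)
        assert len(out) == 1
        assert out[0].compound_ids == ["C1", "C2"]
        assert set(out[0].gene_assignments) == {"gA", "gB"}

    def test_default_min_support_keeps_everything(self):
        from gcmkit.context_refiner import consensus_ims

        out = consensus_ims({
            "gA": [self._im("a1", "gA", ["C1"], {"PF00001"})],
            "gB": [self._im("b1", "gB", ["C2"], {"PF00002"})],
        })
        assert len(out) == 2

    def test_invalid_min_support(self):
        from gcmkit.context_refiner import consensus_ims

        with pytest.raises(ValueError):
            consensus_ims({}, min_support=0)


class TestAssignGenomeGenes:
    def test_locus_matching(self, man_suite):
        catalogs, _, _ = man_suite
        m = _module("M1", {"B2048", "B2049", "NOT_THERE"}, genome="x")
        assign_genome_genes([m], catalogs["ecoli_like"], "ecoli_like")
        assert m.gene_assignments["ecoli_like"] == {"B2048", "B2049"}

    def test_pfam_matching(self, man_suite):
        catalogs, gcm, _ = man_suite
        m = Module(module_id="M1", kind="IRM", map_id="map00051",
                   compound_ids=["C"], pfam_set=set(gcm.pfam_set))
        assign_genome_genes([m], catalogs["btheta_like"], "btheta_like", by="pfam")
        assert m.gene_assignments["btheta_like"] == {
            "BT3950", "BT2781", "BT1224", "BT1225",
        }


class TestCompileGcm:
    def _im(self):
        return Module(
            module_id="map_t_g_IM000", kind="IM", map_id="map_t",
            compound_ids=["C1", "C2", "C3"], pfam_set={"PF00001"},
        )

    def test_valid_promotion(self):
        gcm = compile_gcm(self._im(), ["123"], "C1", "C3")
        assert gcm.kind == "GCM"
        assert gcm.compound_ids == ["C1", "C2", "C3"]
        assert gcm.evidence == ["123"]

    def test_orientation_reverses_when_needed(self):
        gcm = compile_gcm(self._im(), ["123"], "C3", "C1")
        assert gcm.compound_ids == ["C3", "C2", "C1"]

    def test_empty_evidence_refused(self):
        with pytest.raises(ValueError, match="evidence"):
            compile_gcm(self._im(), [], "C1", "C3")

    def test_target_not_in_module_lists_valid_compounds(self):
        with pytest.raises(ValueError, match=r"C1.*C2.*C3"):
            compile_gcm(self._im(), ["123"], "C1", "C9")
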