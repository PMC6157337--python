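import math
import random

import pytest

from gcmkit.detector import (
    DetectionParams,
    calls_to_tsv,
    scan_genome,
    scan_pathway,
)
from gcmkit.fixtures import (
    GenomeSpec,
    PlantedCluster,
    make_genome,
    random_genome_spec,
)
from gcmkit.genome_catalog import GeneRecord, GenomeCatalog
from gcmkit.modules import Module
from gcmkit.pathway_io import parse_kgml

from .oracles import assert_scan_matches_oracle, brute_force_scan


def _gcm(pfams, map_id="map_t"):
    return Module(
        module_id=f"{map_id}_GCMX", kind="GCM", map_id=map_id,
        compound_ids=["C1", "C2"], pfam_set=set(pfams),
        source_compound="C1", target_compound="C2", evidence=["1"],
    )


def _rotate(catalog, replicon, shift):
    """Rotate the gene order of a circular replicon by ``shift`` ranks."""
    records = catalog.replicons[replicon]
    n = len(records)
    rotated = []
    for new_rank in range(n):
        src = records[(new_rank + shift) % n]
        rotated.append(GeneRecord(
            replicon_id=replicon, rank=new_rank,
            start_bp=1 + new_rank * 1000, end_bp=900 + new_rank * 1000,
            strand=src.strand, locus_tag=src.locus_tag,
            product=src.product, pfams=src.pfams,
        ))
    return GenomeCatalog(
        genome_id=catalog.genome_id,
        replicons={replicon: rotated},
        circular={replicon: True},
    )


class TestScenarioSuites:
    def test_contiguous_cluster_present_at_full_cutoff(self, man_suite):
        catalogs, gcm, _ = man_suite
        calls = scan_genome(catalogs["ecoli_like"], gcm, DetectionParams(5, 100))
        present = [c for c in calls if c.present]
        assert len(present) == 1
        assert present[0].coverage_percent == 100.0
        assert not present[0].missing_pfams

    def test_dispersed_homologs_absent_at_full_cutoff(self, man_suite):
        catalogs, gcm, _ = man_suite
        calls = scan_genome(catalogs["btheta_like"], gcm, DetectionParams(5, 100))
        assert not any(c.present for c in calls)
        assert len(calls) == 1  # best-coverage window still reported
        assert math.isclose(calls[0].coverage_percent, 25.0)

    def test_dispersed_homologs_present_at_quarter_cutoff(self, man_suite):
        catalogs, gcm, _ = man_suite
        calls = scan_genome(catalogs["btheta_like"], gcm, DetectionParams(5, 25))
        present = [c for c in calls if c.present]
        assert len(present) == 4  # each lone homolog suffices at 25%
        assert all(math.isclose(c.coverage_percent, 25.0) for c in present)

    def test_four_genome_suite_only_contextual_genome_hits(self, four_genome_suite):
        catalogs, gcm = four_genome_suite
        params = DetectionParams(5, 100)
        verdict = {
            gid: any(c.present for c in scan_genome(cat, gcm, params))
            for gid, cat in catalogs.items()
        }
        assert verdict == {
            "genome1": False, "genome2": False, "genome3": False,
            "genome4": True,
        }


class TestCoverageBoundary:
    @pytest.fixture()
    def three_of_four(self):
        spec = GenomeSpec(
            "g34", (("chr", 60, False),),
            (PlantedCluster(("PF90001", "PF90002", "PF90003"), "chr", 20),),
            seed=1,
        )
        _, _, cat = make_genome(spec)
        return cat

    def test_75_percent_passes_at_cutoff_75(self, three_of_four):
        gcm = _gcm(["PF90001", "PF90002", "PF90003", "PF90004"])
        calls = scan_genome(three_of_four, gcm, DetectionParams(5, 75))
        present = [c for c in calls if c.present]
        assert present and math.isclose(present[0].coverage_percent, 75.0)

    def test_75_percent_fails_at_cutoff_80(self, three_of_four):
        gcm = _gcm(["PF90001", "PF90002", "PF90003", "PF90004"])
        calls = scan_genome(three_of_four, gcm, DetectionParams(5, 80))
        assert not any(c.present for c in calls)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_specs_match_brute_force(self, seed):
        spec = random_genome_spec(seed, max_genes=300)
        _, _, cat = make_genome(spec)
        pfams = spec.planted_clusters[0].pfams
        gcm = _gcm(pfams)
        rng = random.Random(seed)
        params = DetectionParams(
            window_size=rng.choice([0, 1, 3, 5, 10]),
            cutoff_percent=rng.choice([25.0, 50.0, 75.0, 100.0]),
        )
        assert_scan_matches_oracle(cat, gcm, params, scan_genome)

    def test_multi_replicon_scan(self):
        spec = GenomeSpec(
            "g2rep",
            (("chr", 120, False), ("plasmid", 40, True)),
            (
                PlantedCluster(("PF90001", "PF90002"), "chr", 10),
                PlantedCluster(("PF90003",), "plasmid", 5),
            ),
            seed=9,
        )
        _, _, cat = make_genome(spec)
        gcm = _gcm(["PF90001", "PF90002", "PF90003"])
        assert_scan_matches_oracle(cat, gcm, DetectionParams(5, 50), scan_genome)


class TestDetectionProperties:
    def test_coverage_monotone_in_window_size(self, four_genome_suite):
        catalogs, gcm = four_genome_suite
        for cat in catalogs.values():
            prev = -1.0
            for w in (0, 2, 5, 10, 30, 60, 200):
                calls = scan_genome(cat, gcm, DetectionParams(w, 100))
                best = max(c.coverage_percent for c in calls)
                assert best >= prev
                prev = best

    def test_present_calls_shrink_as_cutoff_rises(self, man_suite):
        catalogs, gcm, _ = man_suite
        cat = catalogs["btheta_like"]
        prev_spans = None
        for cutoff in (100.0, 75.0, 50.0, 25.0):
            spans = {
                (c.replicon_id, c.rank_span)
                for c in scan_genome(cat, gcm, DetectionParams(5, cutoff))
                if c.present
            }
            if prev_spans is not None:
                assert prev_spans <= spans
            prev_spans = spans

    @pytest.mark.parametrize("shift", [1, 37, 150, 399])
    def test_rotation_invariance_on_circular_replicon(self, man_suite, shift):
        catalogs, gcm, _ = man_suite
        cat = catalogs["ecoli_like"]
        params = DetectionParams(5, 100)
        base = scan_genome(cat, gcm, params)
        rotated = scan_genome(
            _rotate(cat, "chromosome", shift), gcm, params
        )
        assert [c.present for c in base] == [c.present for c in rotated]
        assert [c.coverage_percent for c in base] == [
            c.coverage_percent for c in rotated
        ]

    def test_shuffle_destroys_planted_context(self):
        """Random gene orders almost never show a full-coverage window."""
        pfams = tuple(f"PF9000{i}" for i in range(1, 7))
        spec = GenomeSpec(
            "gshuf", (("chr", 500, False),),
            (PlantedCluster(pfams, "chr", 100),), seed=11,
        )
        _, _, cat = make_genome(spec)
        records = cat.replicons["chr"]
        gcm = _gcm(pfams)
        rng = random.Random(1234)
        hits = 0
        n_perm = 200
        for _ in range(n_perm):
            shuffled = list(records)
            rng.shuffle(shuffled)
            perm_cat = GenomeCatalog(
                genome_id="perm",
                replicons={"chr": [
                    GeneRecord(
                        replicon_id="chr", rank=i, start_bp=1 + i * 1000,
                        end_bp=900 + i * 1000, strand=r.strand,
                        locus_tag=r.locus_tag, pfams=r.pfams,
                    )
                    for i, r in enumerate(shuffled)
                ]},
                circular={"chr": False},
            )
            best, _q = brute_force_scan(perm_cat, gcm.pfam_set, 5, 100.0)
            hits += best >= 100.0
        assert hits / n_perm < 0.05

    def test_window_zero_requires_single_gene_stack(self):
        spec = GenomeSpec(
            "g0", (("chr", 30, False),),
            (PlantedCluster(("PF90001", "PF90002"), "chr", 10),), seed=2,
        )
        _, _, cat = make_genome(spec)
        gcm = _gcm(["PF90001", "PF90002"])
        calls = scan_genome(cat, gcm, DetectionParams(0, 100))
        assert not any(c.present for c in calls)  # pfams on separate genes

    def test_empty_pfam_set_rejected(self, man_suite):
        catalogs, _, _ = man_suite
        bad = Module(module_id="X_GCM", kind="IM", map_id="m",
                     compound_ids=["C1"])
        with pytest.raises(ValueError, match="empty Pfam set"):
            scan_genome(catalogs["ecoli_like"], bad, DetectionParams(5, 100))


class TestScanPathway:
    def test_one_present_one_absent(self, man_suite):
        catalogs, gcm, kgml = man_suite
        graph = parse_kgml(kgml)
        other = Module(
            module_id="map00051_GCM_other", kind="GCM", map_id="map00051",
            compound_ids=["C00096", "C01222"], pfam_set={"PF97001", "PF97002"},
            source_compound="C00096", target_compound="C01222", evidence=["2"],
        )
        calls, table, annotated = scan_pathway(
            catalogs["ecoli_like"], [gcm, other], graph, DetectionParams(5, 100)
        )
        by_id = {}
        for c in calls:
            by_id.setdefault(c.gcm_id, []).append(c.present)
        assert any(by_id["map00051_GCM_man"])
        assert not any(by_id["map00051_GCM_other"])
        assert table.count("\n") == len(calls) + 1

    def test_empty_gcm_catalog_status_message(self, man_suite):
        catalogs, _, kgml = man_suite
        graph = parse_kgml(kgml)
        calls, table, _ = scan_pathway(
            catalogs["ecoli_like"], [], graph, DetectionParams(5, 100)
        )
        assert calls == []
        assert table.startswith("# no GCMs")

    def test_table_has_expected_columns(self, man_suite):
        catalogs, gcm, _ = man_suite
        calls = scan_genome(catalogs["ecoli_like"], gcm, DetectionParams(5, 100))
        header = calls_to_tsv(calls).splitlines()[0].split("\t")
        assert header[:5] == [
            "gcm_id", "genome_id", "replicon", "start_rank", "end_rank",
        ]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(window_size=-1)
        with pytest.raises(ValueError):
            DetectionParams(cutoff_percent=0)
        with pytest.raises(ValueError):
            DetectionParams(cutoff_percent=101)
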