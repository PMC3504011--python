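import numpy as np
import pytest
from scipy import stats

from gsurveyminer import (
    PlantedRepeat,
    SimConfig,
    fabricate_hit_table,
    simulate_library,
)
from gsurveyminer.annotation import classify_library
from gsurveyminer.synthetic_data import (
    classification_recovery,
    repeat_recovery,
)
from gsurveyminer.tandem_repeat import BUILTIN_PROFILES, find_tandem_repeats


class TestDeterminism:
    def test_same_seed_identical_library_and_truth(self):
        cfg = SimConfig(
            seed=5, n_contigs=30,
            planted_repeats=(PlantedRepeat("AC", 12),),
            contaminant_fractions={"virus": 0.05},
        )
        lib1, truth1 = simulate_library(cfg)
        lib2, truth2 = simulate_library(cfg)
        assert [(c.id, c.sequence, c.n_reads) for c in lib1] == [
            (c.id, c.sequence, c.n_reads) for c in lib2
        ]
        assert truth1.records == truth2.records

    def test_truth_covers_every_contig(self):
        cfg = SimConfig(
            seed=6, n_contigs=25,
            contaminant_fractions={"prokaryote": 0.05, "rrna": 0.02},
        )
        lib, truth = simulate_library(cfg)
        assert {c.id for c in lib} == set(truth.records)
        for c in lib:
            assert truth.records[c.id].n_reads == c.n_reads


class TestPlantedRepeats:
    def test_clean_plant_recovered_at_planted_coordinates(self):
        cfg = SimConfig(
            seed=7, n_contigs=0,
            planted_repeats=(PlantedRepeat("AC", 30, mutation_rate=0.0),),
        )
        lib, truth = simulate_library(cfg)
        (contig,) = lib.contigs
        (planted,) = truth.planted_repeats()
        matches = find_tandem_repeats(
            contig.sequence, BUILTIN_PROFILES["mayer_micro"],
            contig_id=contig.id,
        )
        (m,) = matches
        assert (m.start, m.end) == (planted.start, planted.end)
        assert m.perfection == 100 and m.motif == "AC"

    def test_mutated_plant_has_reduced_perfection(self):
        cfg = SimConfig(
            seed=8, n_contigs=0,
            planted_repeats=(PlantedRepeat("AC", 40, mutation_rate=0.05),),
        )
        _, truth = simulate_library(cfg)
        (planted,) = truth.planted_repeats()
        assert planted.perfection < 100

    def test_infeasible_plant_errors(self):
        cfg = SimConfig(
            seed=9, n_contigs=0, flank_bp=10,
            planted_repeats=(PlantedRepeat("ACGTACGTAC", 50),),
        )
        with pytest.raises(ValueError, match="ACGTACGTAC"):
            simulate_library(cfg)


class TestContaminantSpikes:
    def test_spiked_fraction_within_exact_binomial_bounds(self):
        cfg = SimConfig(
            seed=11, n_contigs=14_000,
            contaminant_fractions={"virus": 0.075},
        )
        _, truth = simulate_library(cfg)
        n = truth.planned_total_reads
        assert n >= 15_000
        lo = stats.binom.ppf(0.005, n, 0.075)
        hi = stats.binom.ppf(0.995, n, 0.075)
        assert lo <= truth.category_read_counts["virus"] <= hi

    def test_multicopy_categories_form_multiread_contigs(self):
        cfg = SimConfig(
            seed=12, n_contigs=200,
            contaminant_fractions={"rrna": 0.2},
        )
        lib, truth = simulate_library(cfg)
        rrna_counts = [
            truth.records[c.id].n_reads
            for c in lib
            if truth.records[c.id].category == "rrna"
        ]
        assert max(rrna_counts) > 1


class TestFabricatedHits:
    def _library(self):
        cfg = SimConfig(
            seed=13, n_contigs=120,
            contaminant_fractions={
                "virus": 0.06, "prokaryote": 0.03, "rrna": 0.03,
                "transposable_element": 0.02, "mitochondrial": 0.02,
            },
        )
        return simulate_library(cfg)

    def test_classification_exact_off_decoys(self):
        _, truth = self._library()
        hits, decoys = fabricate_hit_table(
            truth, decoy_fraction=0.2, seed=3
        )
        labels = classify_library(hits)
        cm = classification_recovery(labels, truth, exclude=decoys)
        off_diag = cm.values.sum() - np.trace(
            cm.reindex(index=cm.columns, columns=cm.columns)
            .fillna(0)
            .values
        )
        assert off_diag == 0

    def test_decoys_are_designed_misses(self):
        _, truth = self._library()
        hits, decoys = fabricate_hit_table(
            truth, decoy_fraction=1.0, seed=4
        )
        labels = classify_library(hits)
        for cid in decoys:
            assert labels[cid].category != truth.records[cid].category

    def test_deterministic_given_seed(self):
        _, truth = self._library()
        a = fabricate_hit_table(truth, decoy_fraction=0.2, seed=5)
        b = fabricate_hit_table(truth, decoy_fraction=0.2, seed=5)
        assert a == b


class TestRecoveryMetrics:
    def test_perfect_detection(self, planted_library):
        _, truth = planted_library
        planted = truth.planted_repeats()
        r = repeat_recovery(planted, planted)
        assert r["sensitivity"] == 1.0 and r["precision"] == 1.0

    def test_no_detections(self, planted_library):
        _, truth = planted_library
        r = repeat_recovery([], truth.planted_repeats())
        assert r["sensitivity"] == 0.0
        assert np.isnan(r["precision"])
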