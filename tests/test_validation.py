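"""RNA-consistency rules, the three-flag conjunction, and ranking."""

import pytest

from adcscreen.errors import ValidationError
from adcscreen.screening import QuasiHScoreMatrix, run_screening, score_matrix
from adcscreen.simulate import simulate_dataset
from adcscreen.types import FpkmTable, NormalTissueProfile, OrdinalLevel, ValidationFlags
from adcscreen.validation import (
    PriorityProfile,
    RnaRule,
    apply_validation,
    candidate_set,
    priority_profile,
    rank_candidates,
    rna_consistency,
)
from adcscreen.vocab import FPKM_TUMOR_TYPES

from conftest import small_config


def matrix_for(gene_id, scores):
    return QuasiHScoreMatrix(
        scores={(gene_id, t): s for t, s in zip(FPKM_TUMOR_TYPES, scores)}
    )


def fpkm_for(gene_id, values):
    return FpkmTable(
        values={(gene_id, t): v for t, v in zip(FPKM_TUMOR_TYPES, values)}
    )


class TestRnaConsistency:
    def test_perfect_rank_concordance(self):
        scores = [10.0, 50.0, 90.0, 140.0, 200.0, 280.0]
        m = matrix_for("E1", scores)
        f = fpkm_for("E1", [s * 0.1 + 1 for s in scores])
        res = rna_consistency("E1", m, f)
        assert res.consistent and res.statistic == pytest.approx(1.0)

    def test_too_few_pairs_is_indeterminate_and_fails_by_default(self):
        m = matrix_for("E1", [10.0, 100.0, 200.0])
        f = fpkm_for("E1", [1.0, 2.0, 3.0])
        res = rna_consistency("E1", m, f)
        assert res.indeterminate and not res.consistent
        lenient = RnaRule(indeterminate_passes=True)
        assert rna_consistency("E1", m, f, lenient).consistent

    def test_support_rule(self):
        m = matrix_for("E1", [200.0, 160.0, 30.0])
        good = fpkm_for("E1", [5.0, 2.0, 0.0])
        bad = fpkm_for("E1", [5.0, 0.5, 0.0])
        rule = RnaRule(method="support")
        assert rna_consistency("E1", m, good, rule).consistent
        assert not rna_consistency("E1", m, bad, rule).consistent

    def test_planted_discordant_genes_mostly_rejected(self):
        """Monte-Carlo: genes whose FPKM is independent of the IHC score fail
        the default rank-correlation rule at close to the null rate."""
        outcomes = []
        for seed in range(20):
            dataset, truth = simulate_dataset(small_config(seed))
            matrix = score_matrix(dataset.pathology)
            for g in sorted(truth.of_class("fails_rna")):
                outcomes.append(
                    rna_consistency(g, matrix, dataset.fpkm).consistent
                )
        rejected = sum(1 for c in outcomes if not c) / len(outcomes)
        assert rejected >= 0.75

    def test_planted_concordant_candidates_mostly_accepted(self):
        outcomes = []
        for seed in range(20):
            dataset, truth = simulate_dataset(small_config(seed))
            matrix = score_matrix(dataset.pathology)
            for g in sorted(truth.of_class("candidate")):
                outcomes.append(rna_consistency(g, matrix, dataset.fpkm).consistent)
        assert sum(outcomes) / len(outcomes) >= 0.9


class TestApplyValidation:
    @pytest.mark.parametrize(
        "flags, expected",
        [((True, True, True), True), ((True, True, False), False),
         ((False, True, True), False), ((True, False, True), False)],
    )
    def test_conjunction_rule(self, flags, expected):
        f = {"E1": ValidationFlags(*flags)}
        (rec,) = apply_validation({"E1"}, f)
        assert rec.is_candidate is expected

    def test_empty_potential_set(self):
        assert apply_validation(set(), {}) == []

    def test_missing_flag_lists_genes(self):
        with pytest.raises(ValidationError, match="E2"):
            apply_validation({"E1", "E2"}, {"E1": ValidationFlags(True, True, True)})

    def test_computed_rna_overrides_flag(self):
        from adcscreen.validation import RnaResult

        f = {"E1": ValidationFlags(True, True, True)}
        rna = {"E1": RnaResult("E1", False, -0.2, 10)}
        (rec,) = apply_validation({"E1"}, f, rna)
        assert not rec.rna_consistent and not rec.is_candidate


class TestPriorityProfile:
    def test_cutoff_boundary_and_undefined_cells(self):
        m = QuasiHScoreMatrix(scores={("E1", "glioma"): 160.0,
                                      ("E1", "melanoma"): 150.0,
                                      ("E1", "carcinoid"): 149.0})
        p = priority_profile("E1", m, NormalTissueProfile(gene_id="E1"))
        assert p.n_tumors_ge_cutoff == 2
        assert p.max_quasi_h == 160.0

    def test_normal_tissue_counters(self):
        prof = NormalTissueProfile(gene_id="E1")
        for t in ("breast", "ovary", "pancreas"):
            prof.levels[(t, "glandular cells")] = OrdinalLevel.MEDIUM
        prof.levels[("testis", "endothelial cells")] = OrdinalLevel.HIGH
        prof.levels[("spleen", "endothelial cells")] = OrdinalLevel.LOW
        p = priority_profile("E1", QuasiHScoreMatrix(), prof)
        assert p.n_normal_high_or_medium == 4
        assert p.n_normal_high == 1

    def test_all_not_detected(self):
        prof = NormalTissueProfile(gene_id="E1")
        for t in ("breast", "ovary"):
            prof.levels[(t, "glandular cells")] = OrdinalLevel.NOT_DETECTED
        p = priority_profile("E1", QuasiHScoreMatrix(), prof)
        assert p.n_normal_high_or_medium == 0


class TestRanking:
    def test_tie_broken_by_narrower_normal_footprint(self):
        a = PriorityProfile("E1", 200.0, 3, 5, 0)
        b = PriorityProfile("E2", 200.0, 3, 2, 0)
        assert [p.gene_id for p in rank_candidates([a, b])] == ["E2", "E1"]

    def test_full_tie_falls_back_to_gene_id(self):
        a = PriorityProfile("E2", 200.0, 3, 2, 0)
        b = PriorityProfile("E1", 200.0, 3, 2, 0)
        assert [p.gene_id for p in rank_candidates([a, b])] == ["E1", "E2"]

    def test_permutation_no_drops_or_duplicates(self):
        profiles = [PriorityProfile(f"E{i}", float(300 - i), i % 4, i % 7, 0)
                    for i in range(25)]
        ranked = rank_candidates(profiles)
        assert sorted(p.gene_id for p in ranked) == sorted(p.gene_id for p in profiles)
        assert rank_candidates(profiles) == ranked

    def test_single_record(self):
        p = PriorityProfile("E1", 150.0, 1, 1, 0)
        assert rank_candidates([p]) == [p]


class TestCandidateSubsetChain:
    def test_candidates_subset_of_potential(self, small_sim):
        dataset, truth = small_sim
        res = run_screening(dataset)
        records = apply_validation(res.potential, dataset.flags)
        cands = candidate_set(records)
        assert cands <= res.potential
        assert cands == truth.of_class("candidate")
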