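"""Funnel stages and the quasi H-score."""

import random

import pytest

from adcscreen.errors import ConfigError, ValidationError
from adcscreen.screening import (
    CriticalTissueSet,
    QuasiHScoreMatrix,
    ScreenConfig,
    filter_critical_normal,
    filter_protein_evidence,
    quasi_h_score,
    run_screening,
    surfaceome_filter,
    threshold_filter,
)
from adcscreen.types import (
    GeneRecord,
    HpaDataset,
    NormalTissueProfile,
    OrdinalLevel,
    SurfaceomeSet,
    TumorLevelCounts,
)
from adcscreen.vocab import CRITICAL_TISSUES, NORMAL_TISSUES


def profile(gene_id, **tissue_levels):
    p = NormalTissueProfile(gene_id=gene_id)
    for tissue, level in tissue_levels.items():
        p.levels[(tissue.replace("_", " "), "glandular cells")] = level
    return p


class TestEvidenceFilter:
    def test_partition_is_exhaustive_and_disjoint(self):
        genes = [
            GeneRecord("E1", "A", has_protein_evidence=True),
            GeneRecord("E2", "B", has_protein_evidence=False),
            GeneRecord("E3", "C", has_protein_evidence=True),
        ]
        kept, dropped = filter_protein_evidence(genes)
        assert [g.gene_id for g in kept] == ["E1", "E3"]
        assert [g.gene_id for g in dropped] == ["E2"]

    def test_empty_input(self):
        assert filter_protein_evidence([]) == ([], [])


class TestCriticalNormalFilter:
    def test_high_in_one_critical_cell_type_excludes(self):
        p = profile("E1", stomach=OrdinalLevel.HIGH, breast=OrdinalLevel.LOW)
        kept, dropped = filter_critical_normal([p])
        assert not kept and dropped == [p]

    def test_medium_everywhere_never_excludes(self):
        p = NormalTissueProfile(gene_id="E1")
        for t in CRITICAL_TISSUES:
            p.levels[(t, "glandular cells")] = OrdinalLevel.MEDIUM
        kept, dropped = filter_critical_normal([p])
        assert kept == [p] and not dropped

    def test_high_in_noncritical_tissue_retained(self):
        p = profile("E1", cerebral_cortex=OrdinalLevel.HIGH)
        kept, _ = filter_critical_normal([p])
        assert kept == [p]

    def test_tissue_aggregation_is_max_over_cell_types(self):
        p = NormalTissueProfile(gene_id="E1")
        p.levels[("colon", "glandular cells")] = OrdinalLevel.LOW
        p.levels[("colon", "endothelial cells")] = OrdinalLevel.HIGH
        _, dropped = filter_critical_normal([p])
        assert dropped == [p]

    def test_unknown_tissue_named_in_error(self):
        p = profile("E1", atlantis=OrdinalLevel.LOW)
        with pytest.raises(ValidationError, match="atlantis"):
            filter_critical_normal([p])

    def test_default_set_is_the_13_critical_tissues(self):
        assert len(CriticalTissueSet()) == 13
        assert CriticalTissueSet().tissues <= set(NORMAL_TISSUES)


class TestQuasiHScore:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (dict(n_high=12), 300.0),
            (dict(n_not_detected=10), 0.0),
            (dict(n_low=5, n_medium=3, n_high=2), 170.0),
            (dict(n_low=1, n_not_detected=3), 25.0),
        ],
    )
    def test_examples(self, counts, expected):
        assert quasi_h_score(TumorLevelCounts("E1", "glioma", **counts)) == expected

    def test_zero_patients_is_undefined_not_zero(self):
        assert quasi_h_score(TumorLevelCounts("E1", "glioma")) is None

    def test_negative_count_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            TumorLevelCounts("E1", "glioma", n_high=-1)


class TestThresholdFilter:
    def test_boundary_is_inclusive(self):
        m = QuasiHScoreMatrix(scores={("E1", "glioma"): 120.0, ("E1", "melanoma"): 150.0})
        retained, _ = threshold_filter(m)
        assert retained == {"E1"}

    def test_just_below_cutoff_dropped(self):
        m = QuasiHScoreMatrix(scores={("E1", "glioma"): 149.9})
        retained, _ = threshold_filter(m)
        assert retained == set()

    def test_all_undefined_dropped(self):
        m = QuasiHScoreMatrix(scores={})
        retained, max_scores = threshold_filter(m, genes={"E1"})
        assert retained == set() and "E1" not in max_scores

    def test_cutoff_range_checked(self):
        with pytest.raises(ConfigError):
            threshold_filter(QuasiHScoreMatrix(), cutoff=0.0)


class TestSurfaceomeFilter:
    def test_intersection(self):
        surf = SurfaceomeSet(members=frozenset({"B", "C", "D"}))
        retained, excluded = surfaceome_filter({"A", "B", "C"}, surf)
        assert retained == {"B", "C"} and excluded == {"A"}

    def test_empty_surfaceome(self):
        retained, excluded = surfaceome_filter({"A"}, SurfaceomeSet())
        assert retained == set() and excluded == {"A"}


class TestRunScreening:
    def test_planted_classes_survive_to_potential(self, small_sim):
        dataset, truth = small_sim
        res = run_screening(dataset)
        expected = truth.of_class(
            "candidate", "fails_rna", "fails_literature", "fails_membranous"
        )
        assert res.potential == expected
        res.audit.check()

    def test_audit_counts_telescope(self, small_sim):
        dataset, _ = small_sim
        audit = run_screening(dataset).audit
        for prev, cur in zip(audit.stages, audit.stages[1:]):
            assert cur.n_in == prev.n_out
        assert audit.stages[0].n_in == len(dataset.genes)

    def test_order_independence(self, small_sim):
        dataset, _ = small_sim
        rng = random.Random(0)
        shuffled = HpaDataset(
            genes=rng.sample(dataset.genes, len(dataset.genes)),
            profiles=dataset.profiles,
            pathology=rng.sample(dataset.pathology, len(dataset.pathology)),
            surfaceome=dataset.surfaceome,
            fpkm=dataset.fpkm,
            flags=dataset.flags,
        )
        a, b = run_screening(dataset), run_screening(shuffled)
        assert a.potential == b.potential
        assert a.matrix.scores == b.matrix.scores
        assert [s.name for s in a.audit.stages] == [s.name for s in b.audit.stages]
        assert [s.excluded for s in a.audit.stages] == [s.excluded for s in b.audit.stages]

    def test_only_non_membrane_genes(self):
        genes = [GeneRecord(f"E{i}", f"G{i}", is_membrane=False) for i in range(4)]
        ds = HpaDataset(genes=genes, profiles={}, pathology=[],
                        surfaceome=SurfaceomeSet())
        res = run_screening(ds)
        assert res.potential == set()
        assert res.audit.stages[0].n_out == 0
        assert res.audit.stages[0].excluded == tuple(sorted(g.gene_id for g in genes))

    def test_single_candidate_survives_every_stage(self):
        p = NormalTissueProfile(gene_id="E1")
        p.levels[("breast", "glandular cells")] = OrdinalLevel.HIGH
        ds = HpaDataset(
            genes=[GeneRecord("E1", "G1")],
            profiles={"E1": p},
            pathology=[TumorLevelCounts("E1", "glioma", n_high=10)],
            surfaceome=SurfaceomeSet(members=frozenset({"E1"})),
        )
        res = run_screening(ds)
        assert res.potential == {"E1"}
        assert all(s.n_out == 1 for s in res.audit.stages)

    def test_unknown_pathology_gene_rejected(self):
        ds = HpaDataset(genes=[], profiles={},
                        pathology=[TumorLevelCounts("EX", "glioma", n_high=1)],
                        surfaceome=SurfaceomeSet())
        with pytest.raises(ValidationError, match="EX"):
            run_screening(ds)

    def test_cutoff_config_validated(self):
        with pytest.raises(ConfigError):
            ScreenConfig(cutoff=301.0)
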