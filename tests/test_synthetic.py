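"""Ground-truth guarantees of the synthetic-data generator."""

import numpy as np
import pytest

from neoexome import filters as F
from neoexome.io_formats import DepthTrack
from neoexome.signatures import build_catalog
from neoexome.synthetic import (
    CohortSpec,
    PLANTABLE_REASONS,
    SimulationConfig,
    generate_cohort,
    generate_depth_track,
    generate_pair,
    generate_timepoint_pair,
)


def _cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestGeneratePair:
    def test_planted_depth_failures_exact(self, matrix):
        cfg = SimulationConfig(seed=4, n_snvs=20, n_indels=0,
                               planted_failures={"tumour_depth": 5})
        tumour, _, truth = generate_pair(cfg, matrix)
        low = [r for r in tumour if r.kind == "SNV" and 1 <= r.tumour_depth <= 49]
        assert len(low) == 5
        assert truth.n_planted("tumour_depth") == 5
        audit = F.filter_snvs([r for r in tumour if r.kind == "SNV"])
        assert audit.reason_counts == {"tumour_depth": 5}

    def test_empty_config_gives_empty_tables(self, matrix):
        tumour, germ, truth = generate_pair(SimulationConfig(seed=0, n_snvs=0, n_indels=0), matrix)
        assert tumour == [] and germ == [] and truth.fates == {}

    def test_every_record_has_exactly_one_fate(self, matrix):
        cfg = SimulationConfig(seed=2, n_snvs=30, n_indels=10,
                               planted_failures={"vaf": 3, "repeat_adjacency": 2})
        tumour, _, truth = generate_pair(cfg, matrix)
        assert sorted(truth.fates) == sorted(r.uid for r in tumour)

    def test_round_trip_with_filters_all_reason_codes(self, matrix):
        """Planted records are rejected for exactly the planted reason; no others."""
        planted = {code: 2 for code in PLANTABLE_REASONS}
        cfg = SimulationConfig(seed=8, n_snvs=40, n_indels=15, planted_failures=planted)
        tumour, _, truth = generate_pair(cfg, matrix)
        audit = F.filter_variants(tumour)
        for uid, (fate, reasons) in truth.fates.items():
            if fate == "pass":
                assert uid in audit.kept
            else:
                assert audit.rejected[uid] == reasons
        expected_counts = {}
        for _, (fate, reasons) in truth.fates.items():
            if fate == "fail":
                expected_counts[reasons[0]] = expected_counts.get(reasons[0], 0) + 1
        assert audit.reason_counts == expected_counts

    def test_deterministic_under_seed(self, matrix):
        cfg = SimulationConfig(seed=3, n_snvs=25, n_indels=5, planted_failures={"vaf": 2})
        t1, g1, _ = generate_pair(cfg, matrix)
        t2, g2, _ = generate_pair(cfg, matrix)
        assert [r.__dict__ for r in t1] == [r.__dict__ for r in t2]
        assert [r.__dict__ for r in g1] == [r.__dict__ for r in g2]

    def test_single_signature_catalog_identified_by_cosine(self, matrix):
        cfg = SimulationConfig(seed=5, n_snvs=5000, n_indels=0,
                               signature_weights={"Signature 1": 1.0})
        tumour, _, _ = generate_pair(cfg, matrix)
        catalog = build_catalog(tumour)
        sims = [_cosine(catalog.proportions(), matrix.values[i]) for i in range(30)]
        assert int(np.argmax(sims)) == 0  # Signature 1 row
        assert max(sims) > 0.99

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            generate_pair(SimulationConfig(signature_weights={"Signature 1": 0.6}))
        with pytest.raises(ValueError, match="reason code"):
            generate_pair(SimulationConfig(planted_failures={"bogus": 1}))


class TestDepthTrack:
    def test_extremes(self):
        all_callable = generate_depth_track(1000, 1.0, seed=0)
        assert (all_callable.per_base() >= 20).all()
        none_callable = generate_depth_track(1000, 0.0, seed=0)
        assert (none_callable.per_base() < 20).all()

    def test_half_callable_to_one_base(self):
        track = generate_depth_track(10_000, 0.5, seed=1)
        assert abs(track.bases_at_least(20) - 5000) <= 1

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            generate_depth_track(0, 0.5, seed=0)

    def test_round_trips_as_depth_track(self):
        track = generate_depth_track(500, 0.3, seed=2)
        assert isinstance(track, DepthTrack)
        assert track.length == 500


class TestCohort:
    def test_requested_marginals_exact(self):
        cohort = generate_cohort(CohortSpec(seed=1))
        assert len(cohort) == 40
        assert sum(p.breast_pcr for p in cohort) == 22
        assert sum(p.breast_ln_pcr for p in cohort) == 18
        assert sum(p.ypt0_ypn0 for p in cohort) == 13
        assert sum(p.ncr for p in cohort) == 4
        assert sum(p.surgery == "breast_conserving" for p in cohort) == 19
        assert sum(p.dfs_event for p in cohort) == 7
        assert all(not p.violations() for p in cohort)

    def test_saturated_and_zero_counts(self):
        denominators = dict(CohortSpec().denominators)
        full = CohortSpec(breast_pcr=dict(denominators),
                          breast_ln_pcr=dict(denominators),
                          n_ypt0_ypn0=0, n_ncr=0)
        assert sum(p.breast_pcr for p in generate_cohort(full)) == 40
        empty = CohortSpec(breast_pcr={k: 0 for k in denominators},
                           breast_ln_pcr={k: 0 for k in denominators},
                           n_ypt0_ypn0=0, n_ncr=0)
        assert sum(p.breast_pcr for p in generate_cohort(empty)) == 0

    def test_counts_exceeding_denominators_rejected(self):
        spec = CohortSpec(breast_pcr={"HER2_amplified": 16, "TNBC": 0,
                                      "HR_pos_HER2_neg_RS_ge_25": 0})
        with pytest.raises(ValueError, match="exceeds"):
            generate_cohort(spec)

    def test_deterministic(self):
        a = generate_cohort(CohortSpec(seed=9))
        b = generate_cohort(CohortSpec(seed=9))
        assert [p.__dict__ for p in a] == [p.__dict__ for p in b]


class TestTimepointPair:
    def test_clone_fates_and_memberships(self, matrix):
        cfg = SimulationConfig(seed=6, clone_vafs_diagnostic=[0.4, 0.2],
                               clone_vafs_residual=[0.35], mean_tumour_depth=150)
        diag, resid, truth = generate_timepoint_pair(cfg, matrix, variants_per_clone=10)
        assert len(diag) == 20 and len(resid) == 10
        assert truth.clone_fates == {"D0": "persistent", "D1": "extinct"}
        # persistent clone reuses the same loci at the residual timepoint
        diag_loci = {r.uid.split(":", 1)[1] for r in diag
                     if truth.clones[r.uid] == "D0"}
        resid_loci = {r.uid.split(":", 1)[1] for r in resid}
        assert resid_loci == diag_loci

    def test_emergent_clone_gets_new_loci(self, matrix):
        cfg = SimulationConfig(seed=7, clone_vafs_diagnostic=[0.4],
                               clone_vafs_residual=[0.35, 0.15],
                               clone_map_residual=[0, None])
        diag, resid, truth = generate_timepoint_pair(cfg, matrix, variants_per_clone=8)
        assert truth.clone_fates == {"D0": "persistent", "R1": "emergent"}
        emergent_loci = {r.uid.split(":", 1)[1] for r in resid if truth.clones[r.uid] == "R1"}
        diag_loci = {r.uid.split(":", 1)[1] for r in diag}
        assert not emergent_loci & diag_loci
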