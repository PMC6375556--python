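"""Binomial-mixture VAF clustering and clone-fate tracking."""

import numpy as np
import pytest

from conftest import make_snv
from neoexome.clonal import CloneCluster, cluster_vafs, river_table, track_clones
from neoexome.synthetic import SimulationConfig, generate_timepoint_pair


def _snvs_at(vaf, n, depth=100, start=0, sample="T1"):
    rng = np.random.default_rng(start + 1)
    out = []
    for i in range(n):
        alt = int(rng.binomial(depth, vaf))
        out.append(make_snv(sample_id=sample, pos=start + i, tumour_depth=depth,
                            tumour_alt_reads=alt, vaf=alt / depth))
    return out


class TestClustering:
    def test_single_clone_yields_one_cluster(self):
        recs = [make_snv(pos=i, tumour_depth=100, tumour_alt_reads=50, vaf=0.5) for i in range(20)]
        clusters = cluster_vafs(recs, seed=0)
        assert len(clusters) == 1
        assert clusters[0].mean_vaf == pytest.approx(0.5, abs=0.01)

    def test_two_planted_clones_recovered(self):
        recs = _snvs_at(0.45, 50, depth=200) + _snvs_at(0.10, 50, depth=200, start=1000)
        clusters = cluster_vafs(recs, seed=1)
        assert len(clusters) == 2
        means = sorted(c.mean_vaf for c in clusters)
        assert means[0] == pytest.approx(0.10, abs=0.03)
        assert means[1] == pytest.approx(0.45, abs=0.03)

    def test_three_identical_variants_one_cluster(self):
        recs = [make_snv(pos=i, tumour_depth=80, tumour_alt_reads=24, vaf=0.3) for i in range(3)]
        clusters = cluster_vafs(recs, seed=0)
        assert len(clusters) == 1 and clusters[0].mean_vaf == pytest.approx(0.3)

    def test_minimum_input_size(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_vafs([make_snv()], seed=0)

    def test_deterministic_under_seed(self):
        recs = _snvs_at(0.4, 30) + _snvs_at(0.15, 30, start=500)
        a = cluster_vafs(recs, seed=7)
        b = cluster_vafs(recs, seed=7)
        assert [c.members for c in a] == [c.members for c in b]

    def test_cluster_sizes_at_least_two(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(25):
            vaf = rng.uniform(0.05, 0.6)
            alt = int(rng.binomial(120, vaf))
            recs.append(make_snv(pos=i, tumour_depth=120, tumour_alt_reads=alt, vaf=alt / 120))
        for c in cluster_vafs(recs, seed=2):
            assert c.size >= 2


class TestTracking:
    def _cluster(self, sample, loci, vaf):
        return CloneCluster(sample, [f"{sample}:chr1:{p}:C>T" for p in loci], vaf)

    def test_identical_membership_is_persistent(self):
        d = self._cluster("D1", range(10), 0.5)
        r = self._cluster("R1", range(10), 0.4)
        (traj,) = track_clones([d], [r], "P1")
        assert traj.fate == "persistent" and len(traj.defining_variants) == 10

    def test_residual_only_cluster_is_emergent(self):
        d = self._cluster("D1", range(10), 0.5)
        r_old = self._cluster("R1", range(10), 0.4)
        r_new = self._cluster("R1", range(100, 110), 0.2)
        fates = {t.fate for t in track_clones([d], [r_old, r_new], "P1")}
        assert fates == {"persistent", "emergent"}

    def test_disjoint_memberships_all_extinct_and_emergent(self):
        d = [self._cluster("D1", range(10), 0.5), self._cluster("D1", range(20, 30), 0.2)]
        r = [self._cluster("R1", range(100, 110), 0.3)]
        fates = [t.fate for t in track_clones(d, r, "P1")]
        assert fates.count("extinct") == 2 and fates.count("emergent") == 1

    def test_every_cluster_in_exactly_one_trajectory(self):
        d = [self._cluster("D1", range(0, 8), 0.5), self._cluster("D1", range(8, 16), 0.25)]
        r = [self._cluster("R1", range(0, 8), 0.45), self._cluster("R1", range(50, 60), 0.1)]
        trajectories = track_clones(d, r, "P1")
        seen_d = [t.diagnostic for t in trajectories if t.diagnostic]
        seen_r = [t.residual for t in trajectories if t.residual]
        assert sorted(id(c) for c in seen_d) == sorted(id(c) for c in d)
        assert sorted(id(c) for c in seen_r) == sorted(id(c) for c in r)

    def test_shared_variant_within_sample_rejected(self):
        a = self._cluster("D1", range(5), 0.5)
        b = self._cluster("D1", range(4, 9), 0.2)
        with pytest.raises(ValueError, match="share"):
            track_clones([a, b], [], "P1")


class TestRiverTable:
    def test_empty(self):
        assert river_table([]).empty

    def test_persistent_clone_two_rows(self):
        d = CloneCluster("D1", ["D1:chr1:1:C>T", "D1:chr1:2:C>T"], 0.5)
        r = CloneCluster("R1", ["R1:chr1:1:C>T", "R1:chr1:2:C>T"], 0.4)
        (traj,) = track_clones([d], [r], "P1")
        table = river_table([traj])
        assert len(table) == 2
        assert set(table["timepoint"]) == {"diagnostic", "residual"}
        assert table.set_index("timepoint")["fraction"]["diagnostic"] == 0.5


def test_generated_five_clone_scenario_matches_truth(matrix):
    cfg = SimulationConfig(
        seed=12,
        clone_vafs_diagnostic=[0.45, 0.30, 0.15],
        clone_vafs_residual=[0.40, 0.22, 0.10],
        clone_map_residual=[0, 1, None],
        mean_tumour_depth=200,
    )
    diag, resid, truth = generate_timepoint_pair(cfg, matrix, variants_per_clone=35)
    d_clusters = cluster_vafs(diag, seed=0)
    r_clusters = cluster_vafs(resid, seed=0)
    trajectories = track_clones(d_clusters, r_clusters, "P1")
    fates = sorted(t.fate for t in trajectories)
    assert fates == sorted(truth.clone_fates.values())
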