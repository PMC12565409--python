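"""Motif distance, clustering, shared motifs and consistency screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from palmotifs import (
    FrequencyMatrix,
    MotifRecord,
    MotifType,
    PlantConfig,
    cluster_motifs,
    generate_atlas,
    motif_distance,
    palindromicity,
    reverse_complement,
    screen_cluster,
    screen_clusters,
    shared_motif,
)
from palmotifs.matrix import total_variation_columns

from conftest import random_pwm


def brute_force_distance(a, b, min_overlap=5, lam=0.5):
    """Independent re-evaluation: exhaustive loop over every alignment."""
    best = np.inf
    wmax = max(a.width, b.width)
    for bm in (b, reverse_complement(b)):
        for offset in range(-b.width + 1, a.width):
            a_lo, a_hi = max(0, offset), min(a.width, offset + bm.width)
            overlap = a_hi - a_lo
            if overlap < min_overlap:
                continue
            tv = total_variation_columns(
                a.probs[:, a_lo:a_hi], bm.probs[:, a_lo - offset: a_lo - offset + overlap]
            ).mean()
            best = min(best, tv + lam * (1 - overlap / wmax))
    return best


def as_record(mid, pwm, nsites=60):
    return MotifRecord(id=mid, matrix=pwm, nsites=nsites, coverage=1.0)


class TestMotifDistance:
    def test_identical_motifs_distance_zero(self):
        pwm = random_pwm(np.random.default_rng(0), 10)
        aln = motif_distance(pwm, pwm)
        assert aln.distance == pytest.approx(0.0, abs=1e-12)
        assert aln.offset == 0 and aln.orientation == "same"

    def test_exact_reverse_complement_distance_zero(self):
        pwm = random_pwm(np.random.default_rng(1), 9)
        aln = motif_distance(pwm, reverse_complement(pwm))
        assert aln.distance == pytest.approx(0.0, abs=1e-12)
        assert aln.orientation == "revcomp"

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_pwm(rng, 17)
        b = random_pwm(rng, int(rng.integers(6, 20)))
        assert motif_distance(a, b).distance == pytest.approx(
            brute_force_distance(a, b), abs=1e-12
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_premetric_and_joint_rc_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_pwm(rng, 12), random_pwm(rng, 15)
        dab = motif_distance(a, b).distance
        assert dab >= 0
        assert motif_distance(b, a).distance == pytest.approx(dab, abs=1e-12)
        d_rc = motif_distance(reverse_complement(a), reverse_complement(b)).distance
        assert d_rc == pytest.approx(dab, abs=1e-12)

    def test_narrow_motifs_rejected(self):
        pwm = random_pwm(np.random.default_rng(2), 3)
        with pytest.raises(ValueError):
            motif_distance(pwm, pwm, min_overlap=5)


class TestClustering:
    def _two_group_motifs(self):
        rng = np.random.default_rng(7)
        a, b = random_pwm(rng, 12), random_pwm(rng, 12)
        motifs = [as_record(f"a{i}", a) for i in range(5)]
        motifs += [as_record(f"b{i}", b) for i in range(5)]
        return motifs, a, b

    def test_two_separated_groups_yield_two_clusters(self):
        motifs, a, b = self._two_group_motifs()
        gap = motif_distance(a, b).distance
        cs = cluster_motifs(motifs, cutoff=gap / 2)
        assert len(cs.clusters) == 2
        assert sorted(len(c.member_ids) for c in cs.clusters) == [5, 5]

    def test_small_groups_removed_by_five_member_rule(self):
        rng = np.random.default_rng(8)
        a, b = random_pwm(rng, 12), random_pwm(rng, 12)
        motifs = [as_record(f"a{i}", a) for i in range(4)]
        motifs += [as_record(f"b{i}", b) for i in range(2)]
        cs = cluster_motifs(motifs, cutoff=0.05, min_members=5)
        assert cs.clusters == []
        assert sorted(cs.unclustered) == sorted(m.id for m in motifs)

    def test_all_identical_gives_one_cluster(self):
        pwm = random_pwm(np.random.default_rng(9), 10)
        motifs = [as_record(f"m{i}", pwm) for i in range(6)]
        cs = cluster_motifs(motifs, cutoff=0.1)
        assert len(cs.clusters) == 1
        assert len(cs.clusters[0].member_ids) == 6

    def test_permutation_invariant_up_to_relabelling(self):
        motifs, a, b = self._two_group_motifs()
        cs1 = cluster_motifs(motifs, cutoff=0.3)
        rng = np.random.default_rng(10)
        shuffled = [motifs[i] for i in rng.permutation(len(motifs))]
        cs2 = cluster_motifs(shuffled, cutoff=0.3)
        groups1 = {frozenset(c.member_ids) for c in cs1.clusters}
        groups2 = {frozenset(c.member_ids) for c in cs2.clusters}
        assert groups1 == groups2

    def test_newick_export_contains_all_leaves(self):
        motifs, _, _ = self._two_group_motifs()
        cs = cluster_motifs(motifs, cutoff=0.3)
        nwk = cs.to_newick()
        assert nwk.endswith(";")
        for m in motifs:
            assert m.id in nwk


class TestSharedMotif:
    def test_identical_members_average_to_member(self):
        pwm = random_pwm(np.random.default_rng(11), 10)
        members = [as_record(f"m{i}", pwm) for i in range(4)]
        sm = shared_motif(members)
        np.testing.assert_allclose(sm.matrix.probs, pwm.probs, atol=1e-9)

    def test_reverse_complement_pair_aligns_before_averaging(self):
        pwm = random_pwm(np.random.default_rng(12), 11)
        members = [as_record("fwd", pwm), as_record("rev", reverse_complement(pwm))]
        sm = shared_motif(members)
        d = min(
            np.abs(sm.matrix.probs - pwm.probs).max(),
            np.abs(sm.matrix.probs - reverse_complement(pwm).probs).max(),
        )
        assert d <= 1e-9

    def test_palindromic_members_give_palindromic_shared_motif(self):
        base = random_pwm(np.random.default_rng(13), 10)
        sym = FrequencyMatrix(probs=0.5 * (base.probs + reverse_complement(base).probs))
        members = [as_record(f"m{i}", sym) for i in range(3)]
        sm = shared_motif(members)
        assert palindromicity(sm.matrix) == pytest.approx(1.0, abs=1e-9)


class TestScreening:
    def test_tight_cluster_retained_and_idempotent(self):
        pwm = random_pwm(np.random.default_rng(14), 10)
        motifs = [as_record(f"m{i}", pwm) for i in range(5)]
        cs = cluster_motifs(motifs, cutoff=0.2)
        cluster = cs.clusters[0]
        assert screen_cluster(cluster, motifs, match_thresh=0.1) is True
        assert screen_cluster(cluster, motifs, match_thresh=0.1) is True

    def test_injected_outlier_flips_retained_flag(self):
        rng = np.random.default_rng(15)
        pwm = random_pwm(rng, 10)
        members = [as_record(f"m{i}", pwm) for i in range(5)]
        cs = cluster_motifs(members, cutoff=0.2)
        cluster = cs.clusters[0]
        assert screen_cluster(cluster, members, match_thresh=0.15) is True
        scrambled = FrequencyMatrix(probs=pwm.probs[:, rng.permutation(10)])
        outlier = as_record("outlier", scrambled)
        assert (
            motif_distance(cluster.shared_motif.matrix, scrambled).distance > 0.15
        ), "outlier construction must exceed the threshold"
        assert screen_cluster(cluster, members + [outlier], match_thresh=0.15) is False
        assert cluster.retained is False


class TestAtlasRecovery:
    def test_planted_families_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        types = [MotifType.TYPE_2, MotifType.TYPE_3, MotifType.TYPE_1, MotifType.TYPE_4]
        fams = [
            PlantConfig(motif_type=t, width=17, spacer=13, seed=20 + i)
            for i, t in enumerate(types)
        ]
        motifs, labels = generate_atlas(fams, motifs_per_family=6, seed=2)
        cs = cluster_motifs(motifs, cutoff=0.15)
        screen_clusters(cs, motifs, match_thresh=0.15)
        assert len(cs.retained_clusters) == 4
        assignment = {}
        for ci, c in enumerate(cs.clusters):
            for mid in c.member_ids:
                assignment[mid] = ci
        pred = [assignment[m.id] for m in motifs]
        assert adjusted_rand_score(labels, pred) == pytest.approx(1.0)

    def test_jitter_zero_gives_identical_copies(self):
        fams = [PlantConfig(seed=1), PlantConfig(motif_type=MotifType.TYPE_3, seed=2)]
        motifs, _ = generate_atlas(fams, motifs_per_family=3, jitter_concentration=0)
        first_family = motifs[:3]
        for m in first_family[1:]:
            np.testing.assert_array_equal(m.matrix.probs, first_family[0].matrix.probs)
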