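import math

import numpy as np
import pytest

from otuecs import (
    Partition,
    binomial_likelihood,
    ecs_score,
    ecs_series,
    feature_counts,
    jackknife_cv,
    partition_log_likelihood,
    randomized_null,
    term_features,
)
from otuecs.ecs import _ScoringContext
from otuecs.errors import DataError, DegenerateNullError
from otuecs.signals import FeatureAssignment


def fa_from_sets(sets: dict[str, set[str]]) -> FeatureAssignment:
    return FeatureAssignment(
        "terms", {s: frozenset(f) for s, f in sets.items()}
    )


class TestBinomialLikelihood:
    def test_skin_enrichment_example(self):
        assert round(binomial_likelihood(15, 5, 0.30), 3) == 0.206

    def test_rare_term_enrichment_example(self):
        assert binomial_likelihood(15, 5, 0.009) == pytest.approx(1.6e-7, rel=0.05)

    def test_negative_enrichment_example(self):
        assert round(binomial_likelihood(15, 0, 0.30), 3) == 0.005

    def test_certainty_boundaries(self):
        assert binomial_likelihood(7, 7, 1.0) == 1.0
        assert binomial_likelihood(7, 3, 1.0) == 0.0
        assert binomial_likelihood(7, 0, 0.0) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_likelihood(5, 6, 0.5)
        with pytest.raises(ValueError):
            binomial_likelihood(5, -1, 0.5)

    def test_large_n_no_overflow(self):
        assert binomial_likelihood(10**6, 500_000, 0.5) > 0.0


def naive_ll(partition: Partition, fa: FeatureAssignment) -> float:
    """All-cells double loop over every OTU x every feature."""
    members = partition.members()
    ll = 0.0
    for otu, ms in members.items():
        in_univ = [s for s in ms if s in fa.universe]
        n = len(in_univ)
        if n == 0:
            continue
        for f, p in fa.p.items():
            k = sum(1 for s in in_univ if f in fa.features_of[s])
            ll += math.log(binomial_likelihood(n, k, p))
    return ll


def random_instance(rng, n_seq=40, n_feat=12, n_otus=6):
    sets = {}
    feats = [f"f{j}" for j in range(n_feat)]
    for i in range(n_seq):
        probs = rng.random(n_feat)
        chosen = {f for f, q in zip(feats, probs) if q < 0.3}
        if not chosen:
            chosen = {feats[int(rng.integers(n_feat))]}
        sets[f"s{i}"] = chosen
    fa = fa_from_sets(sets)
    part = Partition(
        {f"s{i}": f"o{rng.integers(n_otus)}" for i in range(n_seq)}
    )
    return part, fa


class TestPartitionLogLikelihood:
    def test_p_one_gives_zero(self):
        fa = fa_from_sets({"s1": {"a"}, "s2": {"a"}})
        part = Partition({"s1": "o1", "s2": "o1"})
        assert partition_log_likelihood(feature_counts(part, fa), fa) == 0.0

    def test_worked_composition(self):
        """One OTU of 15 with skin (p=.3, k=5) and a rare term (p=.009, k=5)."""
        counts_n = {"o1": 15}
        k = {("o1", "skin"): 5, ("o1", "hydrothermal"): 5}
        from otuecs.signals import FeatureCountMatrix

        fa = FeatureAssignment.with_background(
            "terms", {}, {"skin": 0.30, "hydrothermal": 0.009}
        )
        ll = partition_log_likelihood(FeatureCountMatrix(counts_n, k), fa)
        assert ll == pytest.approx(
            math.log(binomial_likelihood(15, 5, 0.30))
            + math.log(binomial_likelihood(15, 5, 0.009))
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_naive_all_cells_loop(self, seed):
        rng = np.random.default_rng(seed)
        part, fa = random_instance(rng)
        got = partition_log_likelihood(feature_counts(part, fa), fa)
        ctx = _ScoringContext(part, fa)
        want = naive_ll(part, fa)
        assert got == pytest.approx(want, rel=1e-9)
        assert ctx.ll_observed() == pytest.approx(want, rel=1e-9)

    def test_p_one_with_missing_count_errors(self):
        from otuecs.signals import FeatureCountMatrix

        fa = FeatureAssignment.with_background("terms", {}, {"a": 1.0})
        with pytest.raises(DataError):
            partition_log_likelihood(
                FeatureCountMatrix({"o1": 3}, {("o1", "a"): 2}), fa
            )


class TestRandomizedNull:
    def test_seed_reproducible(self):
        rng = np.random.default_rng(0)
        part, fa = random_instance(rng)
        _, _, s1 = randomized_null(part, fa, R=50, seed=9)
        _, _, s2 = randomized_null(part, fa, R=50, seed=9)
        assert np.array_equal(s1, s2)

    def test_single_otu_degenerate(self):
        fa = fa_from_sets({"s1": {"a"}, "s2": {"b"}, "s3": {"a"}})
        part = Partition({"s1": "o1", "s2": "o1", "s3": "o1"})
        with pytest.raises(DegenerateNullError):
            randomized_null(part, fa, R=20, seed=0)

    def test_r_too_small(self):
        rng = np.random.default_rng(0)
        part, fa = random_instance(rng)
        with pytest.raises(ValueError):
            randomized_null(part, fa, R=1)

    def test_null_mean_matches_independent_monte_carlo(self):
        """Null mean agrees with a larger, independently coded shuffle."""
        rng = np.random.default_rng(4)
        part, fa = random_instance(rng, n_seq=30, n_feat=6, n_otus=4)
        mu, sigma, _ = randomized_null(part, fa, R=400, seed=12)

        ids = sorted(set(part.assignment) & fa.universe)
        labels = [part.assignment[s] for s in ids]
        oracle_rng = np.random.default_rng(999)
        samples = []
        for _ in range(2000):
            perm = oracle_rng.permutation(len(ids))
            shuffled = Partition(
                {ids[i]: labels[perm[i]] for i in range(len(ids))}
            )
            samples.append(naive_ll(shuffled, fa))
        oracle_mu = float(np.mean(samples))
        tol = 3 * sigma * (1 / math.sqrt(400) + 1 / math.sqrt(2000))
        assert abs(mu - oracle_mu) <= tol


class TestEcsScore:
    def test_perfect_separation_strong_signal(self):
        sets = {f"a{i}": {"fa"} for i in range(50)}
        sets |= {f"b{i}": {"fb"} for i in range(50)}
        fa = fa_from_sets(sets)
        part = Partition(
            {s: ("o1" if s.startswith("a") else "o2") for s in sets}
        )
        res = ecs_score(part, fa, R=200, seed=5)
        assert res.abs_z > 3
        assert res.ecs > 3  # consistent partition scores positive

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(8)
        part, fa = random_instance(rng)
        relabel = {"o0": "x5", "o1": "x4", "o2": "x3", "o3": "x2",
                   "o4": "x1", "o5": "x0"}
        part2 = Partition(
            {s: relabel[o] for s, o in part.assignment.items()}
        )
        r1 = ecs_score(part, fa, R=100, seed=7)
        r2 = ecs_score(part2, fa, R=100, seed=7)
        assert r1.ecs == pytest.approx(r2.ecs, abs=1e-12)

    def test_sign_convention(self):
        """ecs == -z and z == (ll_obs - mu)/sigma."""
        rng = np.random.default_rng(2)
        part, fa = random_instance(rng)
        res = ecs_score(part, fa, R=100, seed=3)
        assert res.z == pytest.approx(
            (res.ll_obs - res.mu_rand) / res.sigma_rand
        )
        assert res.ecs == pytest.approx(-res.z)

    def test_null_calibration_is_size_invariant(self):
        """Raw LL scales with dataset size; the null Z calibration does not.

        Duplicating every sequence and feature 2x changes LL_obs and
        mu_rand strongly, but random partitions still score mean ~0 and
        sd ~1 at either size — the baseline shift the Z-normalization
        removes.
        """
        rng = np.random.default_rng(21)
        base_sets = {f"s{i}": {f"f{rng.integers(5)}"} for i in range(40)}
        fa1 = fa_from_sets(base_sets)
        doubled = {}
        for s, f in base_sets.items():
            ff = {x + "_1" for x in f} | {x + "_2" for x in f}
            doubled[s] = ff
            doubled[s + "_dup"] = ff
        fa2 = fa_from_sets(doubled)

        null1, null2, ll1, ll2 = [], [], [], []
        for rep in range(25):
            p1 = Partition({s: f"o{rng.integers(5)}" for s in base_sets})
            p2 = Partition({s: f"o{rng.integers(5)}" for s in doubled})
            r1 = ecs_score(p1, fa1, R=150, seed=rep)
            r2 = ecs_score(p2, fa2, R=150, seed=rep)
            null1.append(r1.ecs)
            null2.append(r2.ecs)
            ll1.append(r1.ll_obs)
            ll2.append(r2.ll_obs)
        # the raw likelihood is size-dependent ...
        assert abs(np.mean(ll2)) > 2 * abs(np.mean(ll1))
        # ... the score's null calibration is not
        for null in (null1, null2):
            assert abs(float(np.mean(null))) < 0.6
            assert 0.5 < float(np.std(null)) < 1.6

    def test_null_calibration_smoke(self):
        """Random partitions of random features give ecs near N(0,1)."""
        rng = np.random.default_rng(13)
        _, fa = random_instance(rng, n_seq=60, n_feat=8)
        scores = []
        for rep in range(40):
            part = Partition(
                {f"s{i}": f"o{rng.integers(8)}" for i in range(60)}
            )
            scores.append(ecs_score(part, fa, R=100, seed=1000 + rep).ecs)
        assert abs(float(np.mean(scores))) < 0.5
        assert 0.6 < float(np.std(scores)) < 1.5


class TestJackknife:
    def test_reproducible(self, small_dataset):
        fa = term_features(small_dataset.annotations)
        part = small_dataset.true_partition()
        cv1 = jackknife_cv(part, fa, blocks=4, R=60, seed=2)
        cv2 = jackknife_cv(part, fa, blocks=4, R=60, seed=2)
        assert cv1 == cv2
        assert cv1 > 0 and np.isfinite(cv1)

    def test_minimal_two_blocks(self):
        sets = {f"a{i}": {"fa"} for i in range(6)}
        sets |= {f"b{i}": {"fb"} for i in range(6)}
        fa = fa_from_sets(sets)
        part = Partition(
            {s: ("o1" if s.startswith("a") else "o2") for s in sets}
        )
        cv = jackknife_cv(part, fa, blocks=2, R=50, seed=1)
        assert np.isfinite(cv)

    def test_universe_too_small(self):
        fa = fa_from_sets({"s1": {"a"}, "s2": {"b"}})
        part = Partition({"s1": "o1", "s2": "o2"})
        with pytest.raises(ValueError):
            jackknife_cv(part, fa, blocks=20, R=10, seed=0)


class TestEcsSeries:
    def test_duplicate_partition_identical_rows(self, small_dataset):
        fa = term_features(small_dataset.annotations)
        part = small_dataset.true_partition()
        df = ecs_series([part, part], fa, R=80, seed=4)
        assert len(df) == 2
        assert df["ecs"].iloc[0] == pytest.approx(df["ecs"].iloc[1])

    def test_sorted_by_n(self, small_dataset):
        from otuecs import cut, hclust, pairwise_matrix

        fa = term_features(small_dataset.annotations)
        D = pairwise_matrix(small_dataset.seqs)
        dend = hclust(D, "complete")
        parts = cut(dend, [0.99, 0.9], method="complete")
        df = ecs_series(parts, fa, R=60, seed=3)
        assert list(df["n_otus"]) == sorted(df["n_otus"])

    def test_mixed_sequence_sets_rejected(self):
        fa = fa_from_sets({"s1": {"a"}, "s2": {"b"}})
        p1 = Partition({"s1": "o1", "s2": "o2"})
        p2 = Partition({"s1": "o1"})
        with pytest.raises(DataError):
            ecs_series([p1, p2], fa, R=10, seed=0)
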