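from itertools import combinations_with_replacement
from math import comb

import numpy as np
import pandas as pd
import pytest

from mirblock import (
    apply_blocking,
    apply_blocking_matrix,
    average_replicates,
    detection_gain,
    dispersion_profile,
    dominant_fraction,
    downsample,
    foldchange_concordance,
    spearman_replicates,
)
from mirblock.depletion import pool_replicates
from mirblock.simulate import SimConfig, simulate_cohort
from tests.conftest import make_matrix


def enumeration_expectation(counts, depth):
    """Exact per-species expectation of an unordered without-replacement
    draw, by enumerating every distinct read subset (oracle; tiny n only)."""
    reads = [sp for sp, c in counts.items() for _ in range(c)]
    total_weight = 0
    sums = {sp: 0.0 for sp in counts}
    seen = {}
    for combo in combinations_with_replacement(sorted(counts), depth):
        tally = {sp: combo.count(sp) for sp in counts}
        key = tuple(sorted(tally.items()))
        if key in seen or any(tally[sp] > counts[sp] for sp in counts):
            continue
        weight = np.prod([comb(counts[sp], tally[sp]) for sp in counts])
        seen[key] = weight
        total_weight += weight
        for sp in counts:
            sums[sp] += weight * tally[sp]
    return {sp: sums[sp] / total_weight for sp in counts}


class TestDownsample:
    def test_identity_at_full_depth(self):
        v = pd.Series({"A": 6, "B": 4})
        assert downsample(v, 10, seed=0).tolist() == [6, 4]

    def test_forced_outcome(self):
        v = pd.Series({"A": 10, "B": 0})
        for seed in range(5):
            assert downsample(v, 4, seed=seed).tolist() == [4, 0]

    def test_depth_above_total_rejected(self):
        with pytest.raises(ValueError, match="11.*10|10.*11"):
            downsample(pd.Series({"A": 6, "B": 4}), 11)

    def test_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = pd.Series(rng.integers(0, 50, size=8))
            depth = int(rng.integers(1, v.sum() + 1))
            for kwargs in ({}, {"with_replacement": True}, {"deterministic": True}):
                assert downsample(v, depth, seed=rng, **kwargs).sum() == depth

    def test_mean_matches_enumeration_oracle(self):
        counts = {"A": 6, "B": 4}
        exact = enumeration_expectation(counts, 5)
        assert exact["A"] == pytest.approx(3.0)  # d*c/total
        v = pd.Series(counts)
        draws = np.array([downsample(v, 5, seed=s).tolist() for s in range(4000)])
        mc_sd = np.sqrt(draws[:, 0].var() / len(draws))
        assert draws[:, 0].mean() == pytest.approx(exact["A"], abs=4 * mc_sd + 1e-9)

    def test_seeded_bit_reproducibility(self):
        v = pd.Series(np.arange(1, 20))
        a = downsample(v, 50, seed=123)
        b = downsample(v, 50, seed=123)
        assert a.tolist() == b.tolist()


class TestAverageReplicates:
    def test_symmetric_disjoint_replicates(self):
        r1 = pd.Series({"A": 4, "B": 0})
        r2 = pd.Series({"A": 0, "B": 4})
        outs = np.array(
            [average_replicates(r1, r2, seed=s).tolist() for s in range(3000)]
        )
        assert (outs.sum(axis=1) == 4).all()
        # summed library {A:4,B:4} down-sampled to 4: E[A] = 2 by symmetry
        assert outs[:, 0].mean() == pytest.approx(2.0, abs=0.06)

    def test_total_is_common_value(self):
        r1 = pd.Series({"A": 3, "B": 3})
        out = average_replicates(r1, r1.copy(), seed=1)
        assert out.sum() == 6

    def test_min_total_used_when_unequal(self):
        out = average_replicates(pd.Series({"A": 10}), pd.Series({"A": 4}), seed=0)
        assert out.sum() == 4

    def test_zero_replicate_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            average_replicates(pd.Series({"A": 4}), pd.Series({"A": 0}))

    def test_mismatched_species_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            average_replicates(
                pd.Series({"A": 4, "B": 1}), pd.Series({"A": 1, "C": 4})
            )


class TestApplyBlocking:
    def test_efficiency_one_removes_species(self):
        lib = pd.Series({"X": 100, "Y": 5})
        assert apply_blocking(lib, {"X": 1.0}, seed=0).tolist() == [0, 5]

    def test_efficiency_zero_identity(self):
        lib = pd.Series({"X": 100, "Y": 5})
        assert apply_blocking(lib, {"X": 0.0, "Y": 0.0}, seed=0).tolist() == [100, 5]

    def test_binomial_moments(self):
        lib = pd.Series({"X": 10000})
        survivors = np.array(
            [apply_blocking(lib, {"X": 0.99}, seed=s)["X"] for s in range(300)]
        )
        sd = np.sqrt(10000 * 0.99 * 0.01)
        assert survivors.mean() == pytest.approx(100, abs=3 * sd / np.sqrt(300))
        assert survivors.std() == pytest.approx(sd, rel=0.3)

    def test_never_increases_counts(self):
        rng = np.random.default_rng(1)
        lib = pd.Series(rng.integers(0, 100, size=10), index=[f"m{i}" for i in range(10)])
        out = apply_blocking(lib, {f"m{i}": rng.random() for i in range(10)}, seed=2)
        assert (out <= lib).all()

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            apply_blocking(pd.Series({"X": 5}), {"X": 1.5})

    def test_deterministic_mode(self):
        lib = pd.Series({"X": 1000})
        assert apply_blocking(lib, {"X": 0.995}, deterministic=True)["X"] == 5


class TestDominantFraction:
    def test_arithmetic(self):
        lib = pd.Series({"X": 60, "rest": 40})
        assert dominant_fraction(lib, "X") == pytest.approx(0.6)

    def test_zero_count_species(self):
        assert dominant_fraction(pd.Series({"X": 0, "Y": 10}), "X") == 0.0

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            dominant_fraction(pd.Series({"X": 1}), "Z")

    def test_full_blocking_zeroes_fraction(self):
        lib = pd.Series({"X": 50, "Y": 50})
        out = apply_blocking(lib, {"X": 1.0}, seed=0)
        assert dominant_fraction(out, "X") == 0.0


def _paired_matrices(u_cols, b_cols, species):
    u = make_matrix(
        u_cols, {l: dict(condition="unblocked", sample=l.split("_")[0]) for l in u_cols},
        species=species,
    )
    b = make_matrix(
        b_cols, {l: dict(condition="blocked", sample=l.split("_")[0]) for l in b_cols},
        species=species,
    )
    return u, b


class TestDetectionGain:
    def test_identical_conditions_zero_gain(self):
        species = [f"m{i}" for i in range(5)]
        cols = {"S1_u": [50, 20, 10, 5, 15]}
        u, b = _paired_matrices(cols, {"S1_b": cols["S1_u"]}, species)
        curve = detection_gain(u, b, [1, 5, 10], depth=100, deterministic=True)
        assert (curve.per_sample_delta.to_numpy() == 0).all()

    def test_fixed_vectors_delta(self):
        species = ["X", "A", "B", "C"]
        u, b = _paired_matrices(
            {"S1_u": {"X": 89, "A": 10, "B": 1}},
            {"S1_b": {"A": 50, "B": 30, "C": 20}},
            species,
        )
        curve = detection_gain(u, b, [10], depth=100, deterministic=True)
        assert curve.per_sample_delta.loc["S1", 10] == 1  # 3 detected vs 2

    def test_threshold_above_depth_gives_zero(self):
        species = ["X", "A"]
        u, b = _paired_matrices({"S1_u": {"X": 9, "A": 1}}, {"S1_b": {"X": 5, "A": 5}}, species)
        curve = detection_gain(u, b, [101], depth=10, deterministic=True)
        assert curve.per_sample_delta.loc["S1", 101] == 0

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(5)
        species = [f"m{i}" for i in range(30)]
        u, b = _paired_matrices(
            {"S1_u": rng.integers(0, 100, 30), "S2_u": rng.integers(0, 100, 30)},
            {"S1_b": rng.integers(0, 100, 30), "S2_b": rng.integers(0, 100, 30)},
            species,
        )
        depth = int(min(u.totals().min(), b.totals().min()))
        fwd = detection_gain(u, b, [1, 5, 10], depth, deterministic=True)
        rev = detection_gain(b, u, [1, 5, 10], depth, deterministic=True)
        assert (fwd.per_sample_delta.to_numpy() == -rev.per_sample_delta.to_numpy()).all()

    def test_no_matched_samples_rejected(self):
        species = ["m0"]
        u, _ = _paired_matrices({"S1_u": {"m0": 5}}, {"S1_b": {"m0": 5}}, species)
        _, b = _paired_matrices({"S9_u": {"m0": 5}}, {"S9_b": {"m0": 5}}, species)
        with pytest.raises(ValueError, match="no samples"):
            detection_gain(u, b, [1], depth=5)

    def test_blocking_dominant_species_strictly_gains_detection(self):
        # the headline mechanism, end to end on synthetic libraries
        cfg = SimConfig(
            n_species=300, depth=100_000, n_samples=3, n_replicates=1,
            dominant_species=(("hsa-miR-16-5p", 0.4),), dominant_jitter=0.05,
            nb_dispersion=0.0, seed=11,
        )
        sim = simulate_cohort(cfg)
        blocked = apply_blocking_matrix(sim.matrix, {"hsa-miR-16-5p": 0.995}, seed=12)
        depth = int(blocked.totals().min())
        curve = detection_gain(sim.matrix, blocked, [10], depth, seed=13)
        assert (curve.per_sample_delta[10] > 0).all()


class TestDispersionProfile:
    def test_identical_replicates_zero_dispersion(self):
        m = make_matrix({"r1": [5, 10, 100], "r2": [5, 10, 100]}, species=["a", "b", "c"])
        prof = dispersion_profile(m)
        assert (prof.table["dispersion"] == 0).all()

    def test_subpoisson_variance_clamped_to_zero(self):
        m = make_matrix({"r1": {"a": 8}, "r2": {"a": 12}}, species=["a"])
        row = dispersion_profile(m).table.loc["a"]
        assert row["base_mean"] == 10
        assert row["dispersion"] == 0.0  # var 8 < mean 10

    def test_overdispersed_counts(self):
        m = make_matrix({"r1": {"a": 50}, "r2": {"a": 150}}, species=["a"])
        row = dispersion_profile(m).table.loc["a"]
        assert row["dispersion"] == pytest.approx((5000 - 100) / 100**2)

    def test_single_replicate_rejected(self):
        m = make_matrix({"r1": {"a": 5}}, species=["a"])
        with pytest.raises(ValueError, match="2 replicate"):
            dispersion_profile(m)


class TestFoldchangeConcordance:
    def test_identical_conditions_rho_one(self):
        rng = np.random.default_rng(3)
        species = [f"m{i}" for i in range(40)]
        cols_u = {f"S{i}_u": rng.integers(0, 500, 40) for i in range(1, 4)}
        cols_b = {f"S{i}_b": cols_u[f"S{i}_u"] for i in range(1, 4)}
        u, b = _paired_matrices(cols_u, cols_b, species)
        res = foldchange_concordance(u, b, base_mean_min=10, deterministic=True)
        assert len(res.per_pair) == 3
        assert res.per_pair["rho"].tolist() == pytest.approx([1.0, 1.0, 1.0])
        assert res.mean_rho == pytest.approx(1.0)

    @pytest.mark.parametrize("n_samples,n_pairs", [(2, 1), (5, 10)])
    def test_pair_count(self, n_samples, n_pairs):
        rng = np.random.default_rng(4)
        species = [f"m{i}" for i in range(30)]
        cols_u = {f"S{i}_u": rng.integers(0, 500, 30) for i in range(n_samples)}
        cols_b = {f"S{i}_b": rng.integers(0, 500, 30) for i in range(n_samples)}
        u, b = _paired_matrices(cols_u, cols_b, species)
        res = foldchange_concordance(u, b, base_mean_min=10, deterministic=True)
        assert len(res.per_pair) == n_pairs

    def test_single_sample_rejected(self):
        species = ["m0", "m1"]
        u, b = _paired_matrices({"S1_u": [5, 5]}, {"S1_b": [5, 5]}, species)
        with pytest.raises(ValueError, match="2 samples"):
            foldchange_concordance(u, b)


class TestSpearmanReplicates:
    def test_identical(self):
        assert spearman_replicates(pd.Series([1, 5, 3]), pd.Series([1, 5, 3])) == 1.0

    def test_reversed(self):
        assert spearman_replicates(pd.Series([1, 2, 3]), pd.Series([3, 2, 1])) == -1.0

    def test_monotone_transform(self):
        assert spearman_replicates(pd.Series([1, 2, 3]), pd.Series([2, 4, 6])) == 1.0

    def test_constant_vector_flagged_nan(self):
        assert np.isnan(spearman_replicates(pd.Series([2, 2, 2]), pd.Series([1, 2, 3])))


class TestPoolReplicates:
    def test_single_library_passthrough(self):
        v = pd.Series({"a": 3})
        assert pool_replicates([v]) is v

    def test_pooled_total_is_min(self):
        r1 = pd.Series({"a": 10, "b": 10})
        r2 = pd.Series({"a": 6, "b": 2})
        assert pool_replicates([r1, r2], seed=0).sum() == 8
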