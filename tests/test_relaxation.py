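"""Intrinsic R2 baseline, decay fitting, NOE ratios and cluster detection."""

import numpy as np
import pytest

from coiltools import (IntrinsicR2Model, ProteinSequence, R2Profile,
                       detect_clusters, fit_exponential_decay,
                       fit_scale_factor, het_noe, intrinsic_r2_profile,
                       simulate_r2_dataset, unfolded_im7_variant)
from coiltools.errors import InsufficientDataError
from coiltools.relaxation import _baseline_shape
from coiltools.sequence import AMINO_ACIDS
from coiltools.synthetic import DECAY_TIMES_S


def brute_force_baseline(seq, table, scale=1.0):
    """Naive double-loop evaluation of the sequence-dependent baseline."""
    n = len(seq)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            aa = seq.residues[j]
            out[i] += table.rg[aa] ** 3 * np.exp(-abs(i - j) / table.lam[aa])
    return scale * out


class TestIntrinsicBaseline:
    @pytest.mark.parametrize("residues, lam, center, terminal", [
        # identical non-Ala/Gly residues: lambda = 7
        ("LLLLL", 7, 4.2367, 3.8345),
        # all-alanine: lambda = 2
        ("AAAAA", 2, 2.9488, None),
    ])
    def test_normalised_five_mer_values(self, properties, residues, lam,
                                        center, terminal):
        seq = ProteinSequence("x", residues)
        scale = 1.0 / properties.rg[residues[0]] ** 3
        profile = intrinsic_r2_profile(seq, IntrinsicR2Model(scale, properties))
        assert profile.rates[2] == pytest.approx(center, abs=1e-4)
        if terminal is not None:
            assert profile.rates[0] == pytest.approx(terminal, abs=1e-4)

    def test_linearity_in_scale(self, variant, properties):
        one = intrinsic_r2_profile(variant, IntrinsicR2Model(1.0, properties))
        two = intrinsic_r2_profile(variant, IntrinsicR2Model(2.0, properties))
        np.testing.assert_allclose(two.rates, 2 * one.rates, rtol=1e-14)

    def test_vectorised_equals_brute_force(self, properties, rng):
        for _ in range(5):
            n = int(rng.integers(5, 60))
            seq = ProteinSequence(
                "r", "".join(rng.choice(list(AMINO_ACIDS), n)))
            np.testing.assert_allclose(
                _baseline_shape(seq, properties),
                brute_force_baseline(seq, properties), rtol=1e-12)

    def test_homopolymer_palindromy_and_center_maximum(self, properties):
        seq = ProteinSequence("poly", "V" * 31)
        rates = intrinsic_r2_profile(
            seq, IntrinsicR2Model(1.0, properties)).rates
        np.testing.assert_allclose(rates, rates[::-1], rtol=1e-12)
        assert np.argmax(rates) == len(rates) // 2
        assert rates[0] < rates[len(rates) // 2]

    def test_glycine_substitution_never_raises_rates(self, properties, rng):
        """Replacing any residue by Gly (smallest rg, lambda 2) can only
        lower every baseline rate."""
        seq = ProteinSequence("r", "".join(
            rng.choice([aa for aa in AMINO_ACIDS if aa not in "AG"], 40)))
        base = _baseline_shape(seq, properties)
        for position in (0, 10, 25, 39):
            mutated = list(seq.residues)
            mutated[position] = "G"
            rates = _baseline_shape(ProteinSequence("m", "".join(mutated)),
                                    properties)
            assert np.all(rates <= base + 1e-12)


class TestScaleFit:
    def test_exact_proportionality(self, variant, properties):
        shape = _baseline_shape(variant, properties)
        observed = R2Profile(variant.indices, 2.5 * shape)
        scale, baseline = fit_scale_factor(observed, variant, properties)
        assert scale == pytest.approx(2.5, rel=1e-12)
        np.testing.assert_allclose(baseline.rates, 2.5 * shape, rtol=1e-12)

    def test_robust_to_inflated_outlier(self, variant, properties):
        shape = _baseline_shape(variant, properties)
        rates = 2.5 * shape.copy()
        rates[40] *= 5.0
        observed = R2Profile(variant.indices, rates)
        scale, _ = fit_scale_factor(observed, variant, properties)
        # oracle: grid search of the least-absolute-deviations loss
        grid = np.linspace(1.0, 5.0, 4001)
        losses = [np.abs(rates - k * shape).sum() for k in grid]
        oracle = grid[int(np.argmin(losses))]
        assert scale == pytest.approx(oracle, abs=2e-3)
        assert scale == pytest.approx(2.5, rel=0.01)

    def test_insufficient_overlap_rejected(self, variant, properties):
        observed = R2Profile(np.array([12]), np.array([3.0]))
        with pytest.raises(InsufficientDataError):
            fit_scale_factor(observed, variant, properties)


class TestDecayFit:
    def test_noiseless_round_trip(self):
        times = np.array(DECAY_TIMES_S)
        fit = fit_exponential_decay(times, 10.0 * np.exp(-5.0 * times))
        assert fit.rate == pytest.approx(5.0, abs=1e-6)
        assert fit.i0 == pytest.approx(10.0, abs=1e-6)
        assert not fit.flagged

    def test_constant_intensities_flagged(self):
        times = np.array(DECAY_TIMES_S)
        fit = fit_exponential_decay(times, np.ones_like(times))
        assert fit.flagged
        assert fit.rate == pytest.approx(0.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_exponential_decay([0.0, 0.1], [1.0, 0.5])

    def test_duplicate_points_inflate_uncertainty(self, rng):
        times = np.array(list(DECAY_TIMES_S) + [DECAY_TIMES_S[0],
                                                DECAY_TIMES_S[5]])
        clean = np.exp(-8.0 * times)
        noisy = clean + rng.normal(0, 0.02, len(times))
        with_dup = fit_exponential_decay(times, noisy, noise=0.02)
        without = fit_exponential_decay(times[:-2], noisy[:-2], noise=0.02)
        assert with_dup.sigma >= without.sigma * 0.5  # inflation path runs
        assert with_dup.sigma > 0

    def test_mean_recovery_within_one_percent(self):
        """200 seeded replicates at 2% noise recover an 8 s^-1 rate to 1%."""
        times = np.array(DECAY_TIMES_S)
        rates = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            intensities = np.exp(-8.0 * times) + rng.normal(0, 0.02,
                                                            len(times))
            rates.append(fit_exponential_decay(times, intensities,
                                               noise=0.02).rate)
        assert np.mean(rates) == pytest.approx(8.0, rel=0.01)


class TestClusterDetection:
    def test_constructed_single_cluster(self):
        residues = np.arange(20, 61)
        baseline = R2Profile(residues, np.full(41, 2.0))
        rates = np.full(41, 2.0)
        rates[(residues >= 40) & (residues <= 44)] = 4.0
        observed = R2Profile(residues, rates, errors=np.full(41, 0.5))
        calls = detect_clusters(observed, baseline, min_run=3, z=2.0)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (40, 44)
        assert calls[0].center == 42
        assert calls[0].mean_excess == pytest.approx(2.0)

    def test_identical_profiles_give_no_clusters(self):
        residues = np.arange(1, 31)
        profile = R2Profile(residues, np.linspace(2, 4, 30))
        assert detect_clusters(profile, profile) == []

    def test_no_overlap_rejected(self):
        a = R2Profile(np.arange(1, 11), np.ones(10))
        b = R2Profile(np.arange(50, 60), np.ones(10))
        with pytest.raises(InsufficientDataError):
            detect_clusters(a, b)

    def test_synthetic_four_clusters_recovered(self, variant, properties):
        observed, _, truth = simulate_r2_dataset(seed=7)
        _, baseline = fit_scale_factor(observed, variant, properties)
        centers = [c.center for c in detect_clusters(observed, baseline)]
        for center, _, _ in truth:
            assert any(abs(c - center) <= 1 for c in centers)


class TestHetNoe:
    def test_ratio_and_sigma(self):
        record = het_noe(0.29, 1.0, sigma_sat=0.01, sigma_ref=0.02)
        assert record.noe == pytest.approx(0.29)
        expected = 0.29 * np.hypot(0.01 / 0.29, 0.02 / 1.0)
        assert record.sigma == pytest.approx(expected)
        assert not record.above_rigid_limit

    def test_equal_intensities_give_unity(self):
        record = het_noe(2.0, 2.0, sigma_sat=0.1, sigma_ref=0.1)
        assert record.noe == 1.0
        assert record.above_rigid_limit  # 1.0 > rigid limit 0.78

    def test_rigid_limit_flag_warns(self):
        with pytest.warns(UserWarning, match="rigid limit"):
            het_noe(0.9, 1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            het_noe(0.5, 0.0)
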