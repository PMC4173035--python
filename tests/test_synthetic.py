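"""Synthetic data generators: noise models, cell populations, qPCR-style
relative quantification."""

import numpy as np
import pytest
from scipy import stats

from hes7clock import (
    InvalidInputError,
    InvalidParameterError,
    NoiseModel,
    WILD_TYPE,
    add_noise,
    generate_qpcr_samples,
    integrate,
    relative_expression,
    simulate_cell_population,
    utr_loss_scenario,
)


@pytest.fixture(scope="module")
def clean_trajectory():
    # >= 10^4 samples for the law-of-large-numbers check
    return integrate(WILD_TYPE, t_end=600.0, dt=0.05)


class TestAddNoise:
    def test_zero_sigma_is_identity(self, clean_trajectory):
        noisy = add_noise(clean_trajectory, NoiseModel(sigma=0.0, seed=1))
        np.testing.assert_array_equal(noisy.mrna, clean_trajectory.mrna)
        np.testing.assert_array_equal(noisy.protein, clean_trajectory.protein)

    def test_same_seed_bit_identical(self, clean_trajectory):
        a = add_noise(clean_trajectory, NoiseModel(sigma=0.05, seed=11))
        b = add_noise(clean_trajectory, NoiseModel(sigma=0.05, seed=11))
        np.testing.assert_array_equal(a.mrna, b.mrna)
        np.testing.assert_array_equal(a.protein, b.protein)

    def test_different_seed_differs(self, clean_trajectory):
        a = add_noise(clean_trajectory, NoiseModel(sigma=0.05, seed=11))
        b = add_noise(clean_trajectory, NoiseModel(sigma=0.05, seed=12))
        assert not np.array_equal(a.mrna, b.mrna)

    def test_multiplicative_noise_is_unbiased(self, clean_trajectory):
        noisy = add_noise(clean_trajectory, NoiseModel(sigma=0.05, seed=3))
        mask = clean_trajectory.mrna > 0
        assert mask.sum() >= 10_000
        ratio = noisy.mrna[mask] / clean_trajectory.mrna[mask]
        assert ratio.mean() == pytest.approx(1.0, abs=0.005)

    def test_additive_noise_truncates_at_zero(self):
        t = np.arange(0.0, 10.0, 0.1)
        traj_in = integrate(WILD_TYPE, t_end=60.0, dt=0.05)
        noisy = add_noise(traj_in, NoiseModel("additive-gaussian", 0.5, seed=5))
        assert noisy.mrna.min() >= 0.0
        assert noisy.protein.min() >= 0.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            NoiseModel(kind="poisson", sigma=0.1)


class TestCellPopulation:
    def test_single_cell_no_spread_no_noise_is_deterministic(self):
        cells = simulate_cell_population(
            WILD_TYPE, n_cells=1, phase_spread_min=0.0,
            noise=NoiseModel(sigma=0.0, seed=0), t_end=600.0,
        )
        direct = integrate(WILD_TYPE, t_end=600.0, dt=0.05)
        assert len(cells) == 1
        np.testing.assert_allclose(cells[0].mrna, direct.mrna, rtol=1e-12)

    def test_same_seed_identical_population(self):
        kw = dict(n_cells=5, phase_spread_min=120.0,
                  noise=NoiseModel(sigma=0.05, seed=21), t_end=600.0)
        a = simulate_cell_population(WILD_TYPE, **kw)
        b = simulate_cell_population(WILD_TYPE, **kw)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.mrna, cb.mrna)

    def test_snapshot_graded_when_oscillating_uniform_when_arrested(self):
        # spread of one period across cells: a fixed-time snapshot shows the
        # wave-like graded profile; an arrested mutant shows a uniform one
        noise = NoiseModel(sigma=0.0, seed=2)
        osc = simulate_cell_population(
            WILD_TYPE, n_cells=30, phase_spread_min=120.0, noise=noise,
            t_end=600.0,
        )
        arrested_params = utr_loss_scenario(0.7, 0.0).params
        arr = simulate_cell_population(
            arrested_params, n_cells=30, phase_spread_min=120.0, noise=noise,
            t_end=600.0,
        )
        i_snap = len(osc[0].times) - 1  # late snapshot, past the transient
        snap_osc = np.array([c.mrna[i_snap] for c in osc])
        snap_arr = np.array([c.mrna[i_snap] for c in arr])
        cv_osc = snap_osc.std() / snap_osc.mean()
        cv_arr = snap_arr.std() / snap_arr.mean()
        assert cv_osc > 10.0 * cv_arr

    def test_invalid_population_arguments(self):
        with pytest.raises(InvalidParameterError):
            simulate_cell_population(WILD_TYPE, 0, 0.0, NoiseModel())
        with pytest.raises(InvalidParameterError):
            simulate_cell_population(WILD_TYPE, 1, -5.0, NoiseModel())


class TestRelativeExpression:
    def test_exact_seventy_percent_reduction(self):
        wt = np.array([1.0, 1.2, 0.9, 1.1])
        ref = np.ones_like(wt)
        mut = 0.7 * wt
        res = relative_expression(wt, ref, mut, ref)
        assert res.group_means["wild-type"] == pytest.approx(1.0, rel=1e-12)
        assert res.group_means["mutant"] == pytest.approx(0.7, rel=1e-12)

    def test_identical_groups_are_null(self):
        x = np.array([1.0, 1.1, 0.9, 1.05])
        ref = np.ones_like(x)
        res = relative_expression(x, ref, x, ref)
        assert res.group_means["mutant"] == pytest.approx(1.0, rel=1e-12)
        assert res.p_value > 0.99

    def test_positive_quantities_required(self):
        good = np.array([1.0, 1.0])
        with pytest.raises(InvalidInputError):
            relative_expression(np.array([1.0, -1.0]), good, good, good)
        with pytest.raises(InvalidInputError):
            relative_expression(np.array([1.0]), np.array([1.0]), good, good)

    def test_generator_recovery_is_unbiased(self):
        # Monte-Carlo: recovered ratio consistent with the generating 0.7
        # within three standard errors of the replicate mean
        ratios = []
        for seed in range(400):
            q = generate_qpcr_samples(true_ratio=0.7, seed=seed)
            res = relative_expression(
                q["wild_type_target"], q["wild_type_reference"],
                q["mutant_target"], q["mutant_reference"],
            )
            ratios.append(res.group_means["mutant"])
        ratios = np.array(ratios)
        assert abs(ratios.mean() - 0.7) < 3.0 * stats.sem(ratios)

    def test_generator_determinism_and_shapes(self):
        a = generate_qpcr_samples(seed=9)
        b = generate_qpcr_samples(seed=9)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        assert len(a["wild_type_target"]) == 14
        assert len(a["mutant_target"]) == 13
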