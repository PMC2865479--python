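import numpy as np
import pytest

from sexconstraint import synthetic
from sexconstraint.phylo import read_newick
from sexconstraint.simulate import (
    CalibrationError,
    LineageState,
    MODELS,
    ModelName,
    SimulationConfig,
    TipPhenotypes,
    _batch_correlation,
    block_reversal,
    brownian_step,
    calibrate_pull_constant,
    constraint_pull,
    simulate_tip_matrix,
    simulate_tips,
)

F = ModelName.CONSTRAINT_ON_FEMALES
M = ModelName.CONSTRAINT_ON_MALES
U = ModelName.MUTUAL_CONSTRAINT


class TestBrownianStep:
    def test_adds_independent_unit_normal_increments(self, rng):
        # Monte-Carlo check of the N(0, 1) increment distribution
        n = 20000
        inc_m = np.empty(n)
        inc_f = np.empty(n)
        for i in range(n):
            s = brownian_step(LineageState(1.0, -2.0), rng)
            inc_m[i] = s.male - 1.0
            inc_f[i] = s.female + 2.0
        se_mean = 1.0 / np.sqrt(n)
        assert abs(inc_m.mean()) < 3 * se_mean
        assert abs(inc_f.mean()) < 3 * se_mean
        se_sd = 1.0 / np.sqrt(2 * n)
        assert abs(inc_m.std() - 1.0) < 3 * se_sd
        assert abs(inc_f.std() - 1.0) < 3 * se_sd
        assert abs(np.corrcoef(inc_m, inc_f)[0, 1]) < 3 * se_mean


class TestBlockReversal:
    def test_female_reset_to_male_under_female_constraint(self):
        s = block_reversal(F, LineageState(1.0, 2.0))
        assert (s.male, s.female) == (1.0, 1.0)

    def test_male_reset_to_female_under_male_constraint(self):
        s = block_reversal(M, LineageState(1.0, 2.0))
        assert (s.male, s.female) == (2.0, 2.0)

    def test_both_set_to_mean_under_mutual(self):
        s = block_reversal(U, LineageState(1.0, 2.0))
        assert (s.male, s.female) == (1.5, 1.5)

    @pytest.mark.parametrize("model", MODELS)
    def test_unchanged_when_female_not_above_male(self, model):
        s = block_reversal(model, LineageState(2.0, 1.0))
        assert (s.male, s.female) == (2.0, 1.0)


class TestConstraintPull:
    def test_one_sided_pull_moves_only_constrained_sex(self):
        s = constraint_pull(F, LineageState(2.0, 0.0), 0.5)
        assert (s.male, s.female) == (2.0, 1.0)
        s = constraint_pull(M, LineageState(2.0, 0.0), 0.5)
        assert (s.male, s.female) == (1.0, 0.0)

    def test_mutual_pull_is_simultaneous_and_mean_preserving(self):
        s = constraint_pull(U, LineageState(2.0, 0.0), 0.25)
        assert (s.male, s.female) == (1.5, 0.5)

    @pytest.mark.parametrize("model", MODELS)
    def test_zero_pull_is_identity(self, model):
        s = constraint_pull(model, LineageState(3.0, -1.0), 0.0)
        assert (s.male, s.female) == (3.0, -1.0)

    @pytest.mark.parametrize("model,c", [(F, 1.5), (F, -0.1), (U, 0.6)])
    def test_out_of_range_pull_constant_raises(self, model, c):
        with pytest.raises(ValueError):
            constraint_pull(model, LineageState(1.0, 0.0), c)


class TestSimulateTips:
    def _hand_trace(self, model, c, draws):
        """Scalar three-step chain along ((A,B),C); preorder node order
        is [root, (A,B), A, B, C]."""
        states = [LineageState(0.0, 0.0)]
        parents = [-1, 0, 1, 1, 0]
        for i in range(1, 5):
            p = states[parents[i]]
            s = LineageState(p.male + draws[i, 0, 0],
                             p.female + draws[i, 0, 1])
            s = block_reversal(model, s)
            s = constraint_pull(model, s, c)
            states.append(s)
        return states[2], states[3], states[4]  # tips A, B, C

    @pytest.mark.parametrize("model", MODELS)
    def test_matches_hand_trace_of_three_steps(self, model, rng):
        tree = read_newick("((A,B),C);")
        c = 0.3
        draws = rng.standard_normal((5, 1, 2))
        male, female = simulate_tip_matrix(tree, model, c, 1, draws=draws)
        expected = self._hand_trace(model, c, draws)
        for t, exp in enumerate(expected):
            assert male[0, t] == pytest.approx(exp.male, abs=1e-12)
            assert female[0, t] == pytest.approx(exp.female, abs=1e-12)

    @pytest.mark.parametrize("model", MODELS)
    @pytest.mark.parametrize("c_frac", [0.0, 0.3, 1.0])
    def test_no_reversed_dimorphism_ever(self, yule23, model, c_frac):
        c = c_frac * model.c_max
        male, female = simulate_tip_matrix(yule23, model, c, 500, rng=7)
        assert (female <= male + 1e-12).all()

    @pytest.mark.parametrize("model", MODELS)
    def test_c_max_forces_monochromatism(self, yule23, model):
        male, female = simulate_tip_matrix(
            yule23, model, model.c_max, 50, rng=3
        )
        assert np.allclose(male, female)
        assert np.allclose(_batch_correlation(male, female), 1.0)

    def test_requires_speciational_tree(self):
        tree = read_newick("((A:2,B:1):1,C:3);")
        with pytest.raises(ValueError, match="speciational"):
            simulate_tip_matrix(tree, F, 0.3, 10, rng=0)

    def test_deterministic_given_seed(self, yule23):
        cfg = SimulationConfig(model=F, pull_constant=0.4, seed=9)
        a = simulate_tips(yule23, cfg)
        b = simulate_tips(yule23, cfg)
        assert np.array_equal(a.male, b.male)
        assert np.array_equal(a.female, b.female)
        assert a.species == yule23.tip_labels

    def test_mutual_model_conserves_the_sex_mean(self, yule23, rng):
        # steps 2-3 never move (male+female)/2; only Brownian does
        n_nodes = yule23.branch_table().n_nodes
        draws = rng.standard_normal((n_nodes, 100, 2))
        m1, f1 = simulate_tip_matrix(yule23, U, 0.35, 100, draws=draws)
        m0, f0 = simulate_tip_matrix(yule23, U, 0.0, 100, draws=draws,
                                     apply_block=False, apply_pull=False)
        assert np.allclose((m1 + f1) / 2, (m0 + f0) / 2)

    @pytest.mark.parametrize("c", [0.2, 0.8])
    def test_one_sided_models_are_exact_mirrors(self, yule23, rng, c):
        # male-constraint on the sign/sex-swapped draws reproduces the
        # female-constraint trajectories with sexes swapped and negated
        n_nodes = yule23.branch_table().n_nodes
        draws = rng.standard_normal((n_nodes, 200, 2))
        mirrored = -draws[:, :, ::-1]
        mf, ff = simulate_tip_matrix(yule23, F, c, 200, draws=draws)
        mm, fm = simulate_tip_matrix(yule23, M, c, 200, draws=mirrored)
        assert np.allclose(mm, -ff)
        assert np.allclose(fm, -mf)

    def test_pure_brownian_gives_uncorrelated_sexes(self, yule23):
        male, female = simulate_tip_matrix(
            yule23, F, 0.0, 4000, rng=11,
            apply_block=False, apply_pull=False,
        )
        assert abs(_batch_correlation(male, female).mean()) < 0.05


class TestCalibration:
    def test_target_one_returns_c_max(self, yule23):
        assert calibrate_pull_constant(yule23, F, 1.0, seed=0) == 1.0
        assert calibrate_pull_constant(yule23, U, 1.0, seed=0) == 0.5

    def test_mean_correlation_monotone_in_c(self, yule23, rng):
        # brute-force grid under common random numbers
        n_nodes = yule23.branch_table().n_nodes
        draws = rng.standard_normal((n_nodes, 400, 2))
        means = []
        for c in np.linspace(0.0, 1.0, 11):
            male, female = simulate_tip_matrix(yule23, F, c, 400,
                                               draws=draws)
            means.append(_batch_correlation(male, female).mean())
        assert (np.diff(means) >= -1e-9).all()

    def test_calibrating_to_the_baseline_returns_near_zero(self, yule23):
        # measure the baseline with the calibrator's own draw stream,
        # then ask it to hit that value
        n_nodes = yule23.branch_table().n_nodes
        draws = np.random.default_rng(21).standard_normal(
            (n_nodes, 500, 2)
        )
        male, female = simulate_tip_matrix(yule23, F, 0.0, 500,
                                           draws=draws)
        baseline = float(_batch_correlation(male, female).mean())
        c = calibrate_pull_constant(yule23, F, baseline, seed=21)
        assert c < 0.05

    def test_higher_target_needs_higher_c(self, yule23):
        c_low = calibrate_pull_constant(yule23, F, 0.6, seed=5)
        c_high = calibrate_pull_constant(yule23, F, 0.9, seed=5)
        assert c_high > c_low

    def test_calibrated_c_hits_the_target_correlation(self, yule23):
        target = 0.893
        c = calibrate_pull_constant(yule23, F, target, seed=8)
        male, female = simulate_tip_matrix(yule23, F, c, 4000, rng=88)
        assert _batch_correlation(male, female).mean() == pytest.approx(
            target, abs=0.02
        )

    def test_unachievable_target_raises(self, yule23):
        with pytest.raises(CalibrationError, match="baseline"):
            calibrate_pull_constant(yule23, F, 0.05, seed=0)
        with pytest.raises(CalibrationError):
            calibrate_pull_constant(yule23, F, 1.2, seed=0)


class TestContainers:
    def test_tip_phenotypes_validation(self):
        with pytest.raises(ValueError):
            TipPhenotypes(["a", "b"], [1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            TipPhenotypes(["a", "a", "b"], [1, 2, 3], [0, 1, 2])

    def test_tsv_round_trip(self, tmp_path, yule23):
        cfg = SimulationConfig(model=U, pull_constant=0.2, seed=4)
        tips = simulate_tips(yule23, cfg)
        path = tmp_path / "tips.tsv"
        tips.to_tsv(path)
        back = TipPhenotypes.from_tsv(path)
        assert back.species == tips.species
        assert np.allclose(back.male, tips.male)
        assert np.allclose(back.female, tips.female)

    def test_config_rejects_out_of_range_c(self):
        with pytest.raises(ValueError):
            SimulationConfig(model=U, pull_constant=0.7)
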