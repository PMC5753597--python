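import numpy as np
import pytest

from perturbtensor import (
    DataTensor,
    cell_specificity,
    cross_validate,
    deg_labels,
    deg_roc,
    density_experiment,
    gen_lowrank_tensor,
    gen_paired_drug_tensor,
    make_cv_folds,
    pct,
    winner_map,
    withhold,
)
from perturbtensor.baselines import complete_tensor_baseline
from perturbtensor.dnpp import DNPPConfig, complete_tensor_dnpp
from perturbtensor.evaluation import complete_falrtc_pair, profile_pct
from perturbtensor.synthetic import apply_missingness

from conftest import unit


def random_tensor(D, G, C, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((D, G, C))
    vals /= np.linalg.norm(vals, axis=1, keepdims=True)
    return DataTensor(
        [f"d{i:03d}" for i in range(D)], [f"g{i:03d}" for i in range(G)],
        [f"c{i:03d}" for i in range(C)], vals, np.ones((D, C), dtype=bool),
    )


class TestCVFolds:
    def test_folds_partition_observed_pairs(self):
        t = random_tensor(20, 6, 5)
        plan = make_cv_folds(t, k=10, seed=1)
        all_pairs = [p for f in plan.folds for p in f]
        assert len(all_pairs) == t.n_observed == 100
        assert len(set(all_pairs)) == 100
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_reproduces_plan(self):
        t = random_tensor(20, 6, 5)
        a = make_cv_folds(t, k=10, seed=3)
        b = make_cv_folds(t, k=10, seed=3)
        assert a.folds == b.folds

    def test_different_seeds_differ(self):
        t = random_tensor(20, 6, 5)
        a = make_cv_folds(t, k=10, seed=3)
        b = make_cv_folds(t, k=10, seed=4)
        assert a.folds != b.folds

    def test_too_few_profiles_rejected(self, tiny_tensor):
        with pytest.raises(ValueError):
            make_cv_folds(tiny_tensor, k=10, seed=0)

    def test_folds_avoid_emptying_drugs_when_avoidable(self):
        _, t = gen_lowrank_tensor(15, 6, 4, rank=1, seed=5)
        masked = apply_missingness(t, 0.5, seed=6)
        plan = make_cv_folds(masked, k=5, seed=7)
        drug_total = masked.mask.sum(axis=1)
        for fold in plan.folds:
            held = np.zeros(15, dtype=int)
            for d, _ in fold:
                held[d] += 1
            assert not np.any((drug_total >= 2) & (held == drug_total))


class TestPCT:
    def test_perfect_prediction_is_one(self, tiny_tensor):
        pairs = tiny_tensor.observed_pairs()
        assert pct(tiny_tensor, tiny_tensor.values, pairs) == pytest.approx(1.0)

    def test_negated_prediction_is_minus_one(self, tiny_tensor):
        pairs = tiny_tensor.observed_pairs()
        assert pct(tiny_tensor, -tiny_tensor.values, pairs) == pytest.approx(-1.0)

    def test_hand_computed_correlation(self):
        t = DataTensor(["d"], ["g0", "g1", "g2", "g3"], ["c"],
                       unit([1.0, 2.0, 3.0, 4.0]).reshape(1, 4, 1),
                       np.ones((1, 1), dtype=bool))
        pred = np.array([2.0, 1.0, 4.0, 3.0]).reshape(1, 4, 1)
        assert pct(t, pred, [(0, 0)]) == pytest.approx(0.6)

    def test_constant_prediction_is_nan_sentinel(self, tiny_tensor):
        pred = np.ones_like(tiny_tensor.values)
        assert np.isnan(pct(tiny_tensor, pred, tiny_tensor.observed_pairs()))

    def test_empty_omega_rejected(self, tiny_tensor):
        with pytest.raises(ValueError):
            pct(tiny_tensor, tiny_tensor.values, [])

    def test_overall_equals_pooled_fold_entries(self):
        """PCT over all held-out pairs equals PCT over the concatenation of
        the per-fold pair sets (bookkeeping consistency)."""
        t = random_tensor(12, 8, 4, seed=8)
        plan = make_cv_folds(t, k=4, seed=9)
        rng = np.random.default_rng(10)
        pred = t.values + 0.3 * rng.standard_normal(t.values.shape)
        all_pairs = [p for f in plan.folds for p in f]
        concat = [p for f in plan.folds for p in f]
        assert pct(t, pred, all_pairs) == pct(t, pred, concat)


class TestDEG:
    def test_percentile_flag_counts(self):
        rng = np.random.default_rng(11)
        prof = rng.permutation(np.linspace(-1, 1, 100))
        assert deg_labels(prof, 10).sum() == 10
        prof978 = rng.permutation(np.linspace(0.01, 1, 978)) * \
            rng.choice([-1, 1], 978)
        assert deg_labels(prof978, 1).sum() == 10

    def test_tied_profile_flags_everything(self):
        assert deg_labels(np.full(50, 0.3), 10).all()

    def test_roc_limits(self):
        t = random_tensor(50, 100, 1, seed=12)
        pairs = t.observed_pairs()
        _, _, auc = deg_roc(t, t.values, pairs, 10)
        assert auc == pytest.approx(1.0)
        _, _, auc_neg = deg_roc(t, -t.values, pairs, 10)
        assert auc_neg == pytest.approx(1.0)  # labels use absolute values

    def test_permuted_predictions_are_chance_level(self):
        t = random_tensor(100, 200, 1, seed=13)
        rng = np.random.default_rng(14)
        perm = t.values.copy()
        for d in range(100):
            perm[d, :, 0] = rng.permutation(perm[d, :, 0])
        _, _, auc = deg_roc(t, perm, t.observed_pairs(), 10)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_auc_invariant_to_monotone_transform(self):
        t = random_tensor(20, 50, 1, seed=15)
        rng = np.random.default_rng(16)
        pred = t.values + 0.5 * rng.standard_normal(t.values.shape)
        _, _, auc1 = deg_roc(t, pred, t.observed_pairs(), 10)
        # cubing preserves |.| ordering within each profile
        _, _, auc2 = deg_roc(t, pred ** 3, t.observed_pairs(), 10)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_bad_percentile_rejected(self):
        with pytest.raises(ValueError):
            deg_labels(np.ones(10), 0)


class TestWinnerMap:
    def test_exact_method_wins_everywhere(self):
        t = random_tensor(10, 8, 3, seed=17)
        rng = np.random.default_rng(18)
        noisy = t.values + rng.standard_normal(t.values.shape)
        pairs = t.observed_pairs()
        none_abst = np.zeros(t.mask.shape, dtype=bool)
        winners = winner_map(
            t, {"exact": (t.values, none_abst), "noisy": (noisy, none_abst)},
            pairs,
        )
        assert set(winners.values()) == {"exact"}

    def test_tie_broken_by_method_order(self):
        t = random_tensor(5, 6, 2, seed=19)
        pairs = t.observed_pairs()
        none_abst = np.zeros(t.mask.shape, dtype=bool)
        winners = winner_map(
            t, {"beta": (t.values, none_abst), "alpha": (t.values, none_abst)},
            pairs,
        )
        assert set(winners.values()) == {"beta"}

    def test_abstention_ranks_last(self):
        t = random_tensor(5, 6, 2, seed=20)
        pairs = t.observed_pairs()
        all_abst = np.ones(t.mask.shape, dtype=bool)
        rng = np.random.default_rng(21)
        bad = -t.values + 0.1 * rng.standard_normal(t.values.shape)
        winners = winner_map(
            t,
            {"abstainer": (t.values, all_abst),
             "anticorrelated": (bad, np.zeros(t.mask.shape, dtype=bool))},
            pairs,
        )
        assert set(winners.values()) == {"anticorrelated"}

    def test_fixture_structure_flips_winners(self):
        """DNPP dominates on the twin-pair fixture; the tensor method
        dominates on the rank-2 fixture."""
        methods = {
            "falrtc": complete_falrtc_pair,
            "dnpp": lambda m: complete_tensor_dnpp(m, DNPPConfig(k=1)),
        }

        paired = gen_paired_drug_tensor(30, 20, 8, seed=22)
        held_p = [(d, c) for d in range(0, 10, 2) for c in (0, 4)]
        masked_p = withhold(paired, held_p)
        preds_p = {m: f(masked_p) for m, f in methods.items()}
        winners_p = winner_map(paired, preds_p, held_p)
        frac_dnpp_paired = np.mean([w == "dnpp" for w in winners_p.values()])

        truth, rank2 = gen_lowrank_tensor(30, 20, 8, rank=2, seed=23)
        masked_r = apply_missingness(rank2, 0.6, seed=24)
        held_r = [p for p in rank2.observed_pairs()
                  if not masked_r.mask[p[0], p[1]]]
        preds_r = {m: f(masked_r) for m, f in methods.items()}
        winners_r = winner_map(rank2, preds_r, held_r)
        frac_dnpp_rank2 = np.mean([w == "dnpp" for w in winners_r.values()])

        assert frac_dnpp_paired > 0.5 > frac_dnpp_rank2


class TestCrossValidate:
    def test_report_shapes_and_bounds(self):
        _, t = gen_lowrank_tensor(20, 15, 6, rank=2, noise_sd=0.1, seed=25)
        methods = {
            "mean2d": lambda m: complete_tensor_baseline(m, "mean2d"),
            "mean1d": lambda m: complete_tensor_baseline(m, "mean1d"),
        }
        report = cross_validate(t, methods, k=5, seed=26)
        for m in methods:
            assert len(report.pct_per_fold[m]) == 5
            vals = [v for v in report.pct_per_fold[m] if np.isfinite(v)]
            assert all(-1.0 <= v <= 1.0 for v in vals)
            assert np.isfinite(report.pct_overall[m])
            assert len(report.pct_per_profile[m]) == t.n_observed


class TestDensityExperiment:
    def test_single_cell_matches_direct_recomputation(self):
        _, t = gen_lowrank_tensor(15, 10, 5, rank=1, seed=27)
        methods = {"mean1d": lambda m: complete_tensor_baseline(m, "mean1d")}
        df = density_experiment(t, [0.4], methods, reps=1, seed=28)
        assert len(df) == 1
        # independent recomputation with the same RNG stream
        rng = np.random.default_rng(28)
        pairs = t.observed_pairs()
        n = len(pairs)
        perm = rng.permutation(n)
        n_eval = max(1, int(round(0.1 * n)))
        eval_pairs = [pairs[i] for i in perm[:n_eval]]
        train_pool = [pairs[i] for i in perm[n_eval:]]
        n_train = int(np.floor(0.4 * 15 * 5))
        keep = {tuple(train_pool[i]) for i in
                rng.choice(len(train_pool), size=n_train, replace=False)}
        masked = withhold(t, [p for p in pairs if p not in keep])
        pred, abst = complete_tensor_baseline(masked, "mean1d")
        assert df["pct"].iloc[0] == pytest.approx(
            pct(t, pred, eval_pairs, abst)
        )

    def test_infeasible_density_skipped(self):
        _, t = gen_lowrank_tensor(10, 8, 4, rank=1, seed=29)
        methods = {"mean1d": lambda m: complete_tensor_baseline(m, "mean1d")}
        df = density_experiment(t, [0.99], methods, reps=2, seed=30)
        assert df.empty

    def test_rep_count_shape(self):
        _, t = gen_lowrank_tensor(12, 6, 4, rank=1, seed=31)
        methods = {"mean2d": lambda m: complete_tensor_baseline(m, "mean2d")}
        df = density_experiment(t, [0.3, 0.5], methods, reps=3, seed=32)
        assert len(df) == 6
        assert df.groupby("density")["pct"].std().notna().all()


class TestCellSpecificity:
    def test_identical_profiles_give_zero(self):
        v = unit([1.0, 2.0, 3.0])
        vals = np.stack([v, v], axis=1).reshape(1, 3, 2)
        t = DataTensor(["d"], ["a", "b", "c"], ["c1", "c2"], vals,
                       np.ones((1, 2), dtype=bool))
        assert cell_specificity(t, 0) == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_profiles_give_two(self):
        v = unit([1.0, -1.0, 0.5])
        vals = np.stack([v, -v], axis=1).reshape(1, 3, 2)
        t = DataTensor(["d"], ["a", "b", "c"], ["c1", "c2"], vals,
                       np.ones((1, 2), dtype=bool))
        assert cell_specificity(t, 0) == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_profiles_give_one(self):
        vals = np.stack([[1.0, 0, 0], [0, 1.0, 0]], axis=1).reshape(1, 3, 2)
        t = DataTensor(["d"], ["a", "b", "c"], ["c1", "c2"], vals,
                       np.ones((1, 2), dtype=bool))
        assert cell_specificity(t, 0) == pytest.approx(1.0, abs=1e-12)

    def test_single_cell_is_undefined(self, tiny_tensor):
        assert np.isnan(cell_specificity(tiny_tensor, 1))

    def test_global_sign_flip_invariant_single_flip_not(self):
        t = random_tensor(1, 10, 4, seed=33)
        base = cell_specificity(t, 0)
        flipped = t.copy()
        flipped.values = -flipped.values
        assert cell_specificity(flipped, 0) == pytest.approx(base, abs=1e-12)
        one = t.copy()
        one.values[0, :, 0] *= -1
        assert cell_specificity(one, 0) != pytest.approx(base, abs=1e-6)
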