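"""C-index, time-dependent AUC, AIC, KM stratification, bootstrap, NRI."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import fatomics as f
from fatomics.evaluation import (
    aic,
    bootstrap_validate,
    categorical_nri,
    concordance_index,
    km_stratify,
    time_dependent_auc,
)
from fatomics.modeling import breslow_partial_loglik
from fatomics.phantom import CohortSpec, simulate_survival


def brute_force_c_index(scores, time, event):
    """Independent O(n^2) oracle: enumerate comparable pairs one by one."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if time[i] < time[j]:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def _cohort(n, beta, seed, event_fraction=0.6):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, max(len(beta), 1))), columns=list(beta) or ["x"])
    surv = simulate_survival(X, CohortSpec(beta=beta, event_fraction=event_fraction, seed=seed + 1))
    return X, surv["time_days"].to_numpy(), surv["event"].to_numpy()


class TestConcordance:
    def test_all_tied_scores_give_half(self):
        time = np.arange(1.0, 11.0)
        assert concordance_index(np.ones(10), (time, np.ones(10, int))) == 0.5

    def test_perfect_ranking_gives_one(self):
        time = np.arange(1.0, 21.0)
        assert concordance_index(-time, (time, np.ones(20, int))) == 1.0

    def test_five_subject_worked_example(self):
        # {(t,e,s)} = {(1,1,5),(2,1,4),(3,0,3),(4,1,1),(5,0,2)}: 8 comparable
        # pairs, 7 concordant -> C = 0.875
        time = np.array([1.0, 2, 3, 4, 5])
        event = np.array([1, 1, 0, 1, 0])
        score = np.array([5.0, 4, 3, 1, 2])
        assert concordance_index(score, (time, event)) == 7.0 / 8.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        time = np.round(rng.exponential(100, n), 1)  # induce some ties
        event = rng.integers(0, 2, n)
        scores = np.round(rng.normal(size=n), 1)
        if not ((time[:, None] > time[None, :]) & (event[None, :] == 1)).any():
            event[np.argmin(time)] = 1
        assert concordance_index(scores, (time, event)) == brute_force_c_index(
            scores, time, event
        )

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(np.ones(3), (np.ones(3), np.zeros(3, int)))


class TestTimeDependentAuc:
    def test_equals_binary_auc_without_censoring(self):
        X, time, event = _cohort(300, {"x": 1.0}, seed=1, event_fraction=None)
        scores = X["x"].to_numpy()
        horizon = float(np.median(time)) / 365.0
        got = time_dependent_auc(scores, (time, event), horizon)
        want = roc_auc_score(time <= horizon * 365.0, scores)
        assert got == pytest.approx(want, abs=1e-10)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        _, time, event = _cohort(2000, {"x": 0.8}, seed=3)
        got = time_dependent_auc(rng.normal(size=2000), (time, event), 2.0)
        assert got == pytest.approx(0.5, abs=0.03)

    def test_power_monotone_in_effect_size(self):
        aucs = []
        for i, b in enumerate((0.5, 1.0, 2.0)):
            X, time, event = _cohort(1500, {"x": b}, seed=40 + i)
            aucs.append(time_dependent_auc(X["x"].to_numpy(), (time, event), 2.0))
        assert aucs[0] > 0.5
        assert aucs[0] < aucs[1] < aucs[2]

    def test_horizon_outside_followup_rejected(self):
        _, time, event = _cohort(100, {"x": 0.5}, seed=5)
        with pytest.raises(ValueError, match="horizon"):
            time_dependent_auc(np.zeros(100), (time, event), 50.0)


class TestAic:
    def test_null_model_closed_form(self):
        # with lp = 0 and distinct times, logPL = -sum over events of
        # log(size of risk set): independent closed form
        time = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        event = np.array([1, 1, 0, 1, 0])
        at_risk = {1.0: 5, 2.0: 4, 3.0: 3}
        expect = -2.0 * -sum(np.log(at_risk[t]) for t in (1.0, 2.0, 3.0))
        got = aic(pd.DataFrame(index=range(5)), (time, event), feature_names=[])
        assert got == pytest.approx(expect, rel=1e-12)

    def test_noise_feature_raises_aic_in_expectation(self):
        diffs = []
        for seed in range(60):
            X, time, event = _cohort(80, {"x": 1.0}, seed=200 + seed)
            X = X.assign(noise=np.random.default_rng(seed).normal(size=80))
            a1 = aic(X, (time, event), ["x"])
            a2 = aic(X, (time, event), ["x", "noise"])
            diffs.append(a2 - a1)
        assert np.mean(diffs) > 0

    def test_identical_inputs_identical_aic(self):
        X, time, event = _cohort(120, {"x": 0.7}, seed=6)
        assert aic(X, (time, event), ["x"]) == aic(X, (time, event), ["x"])


class TestKaplanMeier:
    def test_identical_outcome_groups_indistinguishable(self):
        time = np.tile(np.arange(1.0, 41.0), 2)
        event = np.tile(np.r_[np.ones(30, int), np.zeros(10, int)], 2)
        scores = np.r_[np.zeros(40), np.ones(40)]
        out = km_stratify(scores, (time, event))
        assert out["logrank_p"] > 0.9
        assert out["group_hr"]["hr"] == pytest.approx(1.0, abs=0.05)

    def test_uncensored_km_equals_empirical_survival(self):
        rng = np.random.default_rng(7)
        time = rng.exponential(100, 200)
        event = np.ones(200, int)
        scores = rng.normal(size=200)
        out = km_stratify(scores, (time, event))
        for name, mask in (("high", scores > np.median(scores)), ("low", scores <= np.median(scores))):
            curve = out["curves"][name]
            tg = np.sort(time[mask])
            emp = 1.0 - np.searchsorted(tg, curve["time"], side="right") / mask.sum()
            np.testing.assert_allclose(curve["survival"], emp, atol=1e-12)
            assert (np.diff(curve["survival"]) <= 1e-12).all()
            assert curve["survival"].iloc[0] <= 1.0
        assert out["curves"]["high"]["survival"].iloc[-1] == pytest.approx(0.0)

    def test_group_hr_recovery(self):
        # emulated strong stratification: true group hazard ratio 2.4 at
        # n=400 with ~56% events lands in a wide interval around 2.4
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            X = pd.DataFrame({"g": rng.integers(0, 2, 400)})
            sd = X["g"].std()
            surv = simulate_survival(
                X, CohortSpec(beta={"g": np.log(2.4) * sd}, event_fraction=0.56, seed=301 + seed)
            )
            out = km_stratify(
                X["g"].to_numpy() + rng.normal(scale=1e-6, size=400),
                (surv["time_days"].to_numpy(), surv["event"].to_numpy()),
            )
            if 1.8 <= out["group_hr"]["hr"] <= 3.2:
                hits += 1
        assert hits >= 9

    def test_all_tied_at_median_rejected(self):
        with pytest.raises(ValueError, match="median"):
            km_stratify(np.ones(10), (np.arange(1.0, 11.0), np.ones(10, int)))


class TestBootstrap:
    def test_seeded_runs_reproduce_exactly(self):
        X, time, event = _cohort(120, {"x": 1.0}, seed=8)
        kw = dict(iterations=5, seed=42, folds=3, n_alphas=10)
        b1 = bootstrap_validate(X, (time, event), ["x"], **kw)
        b2 = bootstrap_validate(X, (time, event), ["x"], **kw)
        assert b1 == b2

    def test_null_feature_interval_covers_half(self):
        X, time, event = _cohort(200, {"x": 1.0}, seed=9)
        X = X.assign(noise=np.random.default_rng(999).normal(size=200))
        out = bootstrap_validate(X, (time, event), ["noise"], iterations=100, seed=1, folds=3,
                                 n_alphas=10)
        assert out["c_index"]["ci_lower"] <= 0.5 <= out["c_index"]["ci_upper"]

    def test_strong_feature_bootstrap_consistent_with_full_fit(self):
        X, time, event = _cohort(250, {"x": 1.5}, seed=10)
        out = bootstrap_validate(X, (time, event), ["x"], iterations=60, seed=2, folds=3,
                                 n_alphas=10)
        full = concordance_index(X["x"].to_numpy(), (time, event))
        assert out["c_index"]["ci_lower"] - 0.05 <= full <= out["c_index"]["ci_upper"] + 0.05


class TestCategoricalNri:
    def test_identical_scores_give_zero(self):
        _, time, event = _cohort(200, {"x": 1.0}, seed=11)
        s = np.random.default_rng(11).normal(size=200)
        out = categorical_nri(s, s, (time, event), 2.0)
        assert out == {"overall": 0.0, "event": 0.0, "nonevent": 0.0}

    def test_swapping_models_negates_overall(self):
        rng = np.random.default_rng(12)
        X, time, event = _cohort(300, {"x": 1.0}, seed=12)
        s_new = X["x"].to_numpy()
        s_ref = rng.normal(size=300)
        a = categorical_nri(s_new, s_ref, (time, event), 2.0)
        b = categorical_nri(s_ref, s_new, (time, event), 2.0)
        assert a["overall"] == pytest.approx(-b["overall"], abs=1e-12)

    def test_true_risk_beats_noise_directionally(self):
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(500 + seed)
            X, time, event = _cohort(400, {"x": 1.2}, seed=600 + seed)
            out = categorical_nri(
                X["x"].to_numpy(), rng.normal(size=400), (time, event), 2.0
            )
            if out["overall"] > 0:
                wins += 1
        assert wins >= 38

    def test_horizon_beyond_followup_rejected(self):
        _, time, event = _cohort(100, {"x": 0.5}, seed=13)
        with pytest.raises(ValueError, match="horizon"):
            categorical_nri(np.zeros(100), np.ones(100), (time, event), 100.0)
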