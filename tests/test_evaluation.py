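"""Multi-class AUC (Hand & Till's M), leave-one-out leakage guarantees,
cohort transfer, and the coefficient-recovery harness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reguframe.cohort import GeneratorConfig, simulate_cohort, shift_cohort
from reguframe.elicit import backbone_from_sem
from reguframe.errors import DataError
from reguframe.evaluation import (
    PredictionSet,
    in_out_analysis,
    kfold_protocol,
    loo_protocol,
    multiclass_auc,
    one_vs_rest_auc,
    recovery_experiment,
)
from reguframe.sem import build_theory_model


def brute_force_m(probs: np.ndarray, labels: np.ndarray) -> float:
    """Independent oracle: average over ordered class pairs of explicit
    pair counting."""
    classes = [k for k in range(probs.shape[1]) if (labels == k).any()]
    vals = []
    for i, j in itertools.permutations(classes, 2):
        wins = ties = total = 0
        for a in np.flatnonzero(labels == i):
            for b in np.flatnonzero(labels == j):
                total += 1
                if probs[a, i] > probs[b, i]:
                    wins += 1
                elif probs[a, i] == probs[b, i]:
                    ties += 1
        vals.append((wins + 0.5 * ties) / total)
    return float(np.mean(vals))


def _random_predictions(seed: int, n: int = 24, k: int = 3) -> PredictionSet:
    rng = np.random.default_rng(seed)
    probs = rng.random((n, k)) + 0.05
    probs /= probs.sum(axis=1, keepdims=True)
    labels = rng.integers(0, k, n)
    return PredictionSet(probs, labels, [f"s{i}" for i in range(k)])


class TestMulticlassAuc:
    def test_perfect_separation_is_one(self):
        probs = np.eye(3)[[0, 0, 1, 1, 2, 2]] * 0.94 + 0.02
        preds = PredictionSet(probs, np.array([0, 0, 1, 1, 2, 2]), ["a", "b", "c"])
        assert multiclass_auc(preds) == 1.0

    def test_identical_scores_give_half(self):
        probs = np.full((9, 3), 1 / 3)
        preds = PredictionSet(probs, np.arange(9) % 3, ["a", "b", "c"])
        assert multiclass_auc(preds) == 0.5

    def test_hand_worked_three_class_table(self):
        """Six-row table checked by exhaustive pair enumeration."""
        probs = np.array(
            [
                [0.6, 0.3, 0.1],
                [0.2, 0.5, 0.3],
                [0.3, 0.4, 0.3],
                [0.1, 0.2, 0.7],
                [0.5, 0.25, 0.25],
                [0.2, 0.2, 0.6],
            ]
        )
        labels = np.array([0, 1, 1, 2, 0, 2])
        preds = PredictionSet(probs, labels, ["low", "medium", "high"])
        assert multiclass_auc(preds) == pytest.approx(brute_force_m(probs, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_sets(self, seed):
        preds = _random_predictions(seed)
        assert multiclass_auc(preds) == pytest.approx(
            brute_force_m(preds.probs, preds.labels), abs=1e-12
        )

    def test_matches_sklearn_ovo(self):
        from sklearn.metrics import roc_auc_score

        preds = _random_predictions(99, n=60)
        assert multiclass_auc(preds) == pytest.approx(
            roc_auc_score(preds.labels, preds.probs, multi_class="ovo"), abs=1e-10
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.01, 5.0))
    def test_invariant_to_monotone_score_transform(self, seed, c):
        """The M measure only uses score ranks: a monotone row-stochastic
        reparameterization p -> (p + c) / (1 + k c) leaves it unchanged."""
        preds = _random_predictions(seed)
        k = preds.probs.shape[1]
        transformed = PredictionSet(
            (preds.probs + c) / (1 + k * c), preds.labels, preds.states
        )
        assert multiclass_auc(transformed) == pytest.approx(multiclass_auc(preds), abs=1e-9)

    def test_absent_class_skipped_with_warning(self, caplog):
        probs = np.full((6, 3), 1 / 3)
        preds = PredictionSet(probs, np.array([0, 0, 0, 1, 1, 1]), ["a", "b", "c"])
        with caplog.at_level("WARNING"):
            val = multiclass_auc(preds)
        assert val == 0.5 and "absent" in caplog.text

    def test_single_class_undefined(self):
        probs = np.full((5, 3), 1 / 3)
        assert np.isnan(multiclass_auc(PredictionSet(probs, np.zeros(5, int), ["a", "b", "c"])))

    def test_one_vs_rest_alternative_close_to_m_on_balanced_data(self):
        preds = _random_predictions(7, n=90)
        assert abs(one_vs_rest_auc(preds) - multiclass_auc(preds)) < 0.15


DAG = {
    "intention_pre": [],
    "frame": [],
    "intention_post": ["intention_pre", "frame"],
}


def _small_cohort(n=40, seed=0):
    rng = np.random.default_rng(seed)
    pre = rng.normal(size=n)
    return pd.DataFrame(
        {
            "intention_pre": pre,
            "frame": rng.choice(["gain", "non_loss", "non_gain", "loss"], n),
            "intention_post": 0.6 * pre + 0.8 * rng.normal(size=n),
        }
    )


class TestLooProtocol:
    def test_n_in_n_out_and_determinism(self):
        tab = _small_cohort()
        p1 = loo_protocol(DAG, tab)
        p2 = loo_protocol(DAG, tab)
        assert len(p1.probs) == len(tab)
        np.testing.assert_array_equal(p1.probs, p2.probs)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_needs_ten_rows(self):
        with pytest.raises(DataError):
            loo_protocol(DAG, _small_cohort(8))

    def test_held_out_row_cannot_poison_its_own_fold(self):
        """Leakage guard: corrupting row i's target changes other rows'
        training folds, but row i's own posterior — fit without it — must
        be identical."""
        tab = _small_cohort(30, 3)
        clean = loo_protocol(DAG, tab)
        poisoned = tab.copy()
        poisoned.loc[4, "intention_post"] = 1e6
        dirty = loo_protocol(DAG, poisoned)
        np.testing.assert_allclose(dirty.probs[4], clean.probs[4])

    def test_fold_model_matches_manual_refit(self):
        """One fold recomputed by hand: cut-offs and CPTs from the other
        n-1 rows only."""
        from reguframe.bayesnet import fit_cpts, infer_posterior
        from reguframe.discretize import DiscretizationMap

        tab = _small_cohort(12, 1)
        preds = loo_protocol(DAG, tab)
        i = 0
        rest = tab.drop(index=i)
        dmap = DiscretizationMap.fit(rest, ["intention_pre", "intention_post"], ["frame"])
        net = fit_cpts(DAG, dmap.apply(rest), dmap.states(), smoothing=1.0)
        held = dmap.apply(tab.iloc[[i]])
        ev = {v: held.iloc[0][v] for v in ("intention_pre", "frame")}
        np.testing.assert_allclose(
            preds.probs[i], infer_posterior(net, ev, "intention_post")
        )

    def test_kfold_close_to_loo(self):
        tab = _small_cohort(60, 2)
        auc_loo = multiclass_auc(loo_protocol(DAG, tab))
        auc_kf = multiclass_auc(kfold_protocol(DAG, tab, k=10, seed=0))
        assert abs(auc_loo - auc_kf) < 0.15


def _strong_cohort(n: int, seed: int, pre_shift: float = 0.0) -> pd.DataFrame:
    """Strong pre -> post signal; a nonzero ``pre_shift`` emulates a second
    population whose pre-intervention level differs while the generating
    relation is preserved (training cut-offs then miscalibrate)."""
    rng = np.random.default_rng(seed)
    pre = rng.normal(size=n)
    return pd.DataFrame(
        {
            "intention_pre": pre + pre_shift,
            "frame": rng.choice(["gain", "non_loss", "non_gain", "loss"], n),
            "intention_post": 0.8 * pre + 0.6 * rng.normal(size=n),
        }
    )


@pytest.fixture(scope="module")
def cohorts():
    return DAG, _strong_cohort(400, 31), _strong_cohort(200, 32, pre_shift=1.0)


class TestInOutAnalysis:
    def test_transfer_degrades_but_beats_chance(self, cohorts):
        """A shifted cohort with preserved generating signal: the transfer
        AUC degrades relative to the in-cohort LOO AUC but stays above
        chance (the in/out degradation pattern)."""
        dag, healthy, patients = cohorts
        res = in_out_analysis(dag, healthy, patients)
        assert res["train_loo_auc"] > 0.6
        assert 0.5 < res["transfer_auc"] < res["train_loo_auc"]

    def test_label_permuted_test_is_chance(self, cohorts):
        dag, healthy, patients = cohorts
        permuted = patients.copy()
        permuted["intention_post"] = (
            permuted["intention_post"].sample(frac=1.0, random_state=1).to_numpy()
        )
        res = in_out_analysis(dag, healthy, permuted)
        assert abs(res["transfer_auc"] - 0.5) < 0.1

    def test_identical_test_table_reproduces_in_sample_auc(self):
        """Scoring the training table itself must reproduce the in-sample
        (resubstitution) AUC of the training-fitted network."""
        from reguframe.bayesnet import fit_cpts
        from reguframe.discretize import DiscretizationMap
        from reguframe.evaluation import PredictionSet, multiclass_auc, predict_rows

        tab = _strong_cohort(120, 33)
        res = in_out_analysis(DAG, tab, tab)
        dmap = DiscretizationMap.fit(tab, ["intention_pre", "intention_post"], ["frame"])
        disc = dmap.apply(tab)
        net = fit_cpts(DAG, disc, dmap.states(), smoothing=1.0)
        probs = predict_rows(net, disc, ["intention_pre", "frame"], "intention_post")
        labels = np.array(
            [net.state_index("intention_post", s) for s in disc["intention_post"]]
        )
        expected = multiclass_auc(
            PredictionSet(probs, labels, net.states["intention_post"])
        )
        assert res["transfer_auc"] == pytest.approx(expected, abs=1e-12)


class TestRecoveryExperiment:
    def test_zero_path_config_recovers_zero(self):
        paths = dict(GeneratorConfig().structural_paths)
        paths[("prevention", "calm")] = 0.0
        report = recovery_experiment(
            GeneratorConfig(structural_paths=paths), replicates=8, seed=5, n=564
        )
        assert report.valid
        assert abs(report.row("prevention->calm")["mean"]) < 0.05

    def test_report_shape_and_truths(self):
        report = recovery_experiment(replicates=3, seed=9, n=400)
        assert report.n_converged >= 2
        assert report.row("hope->involvement")["true"] == 0.87
        assert report.row("promotion*hope->involvement")["true"] == pytest.approx(0.4437)
        assert {"true", "mean", "empirical_se", "bias"} <= set(report.table.columns)
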