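"""Scoring and experiment harness: multi-class AUC (Hand & Till's M),
leave-one-out and k-fold protocols, cohort-transfer analysis, and the
parameter-recovery experiment for the structural model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from reguframe import sem
from reguframe.bayesnet import DiscreteNet, encode_table, fit_cpts, infer_posterior
from reguframe.cohort import GeneratorConfig, simulate_cohort
from reguframe.discretize import DiscretizationMap
from reguframe.errors import DataError, InvalidConfigError, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class PredictionSet:
    """Per-row predicted probability vectors over the target states plus the
    true state labels (as indices into ``states``)."""

    probs: np.ndarray
    labels: np.ndarray
    states: list[str]

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.probs.ndim != 2 or len(self.probs) != len(self.labels):
            raise InvalidConfigError("probs must be (n, n_states) aligned with labels")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise InvalidConfigError("probability rows must sum to 1")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.probs.shape[1]:
            raise InvalidConfigError("labels outside the state space")


def _pairwise_auc(scores_i: np.ndarray, scores_j: np.ndarray) -> float:
    """P(random class-i case scores higher than random class-j case) with
    half credit for ties (Mann-Whitney on the class-i score)."""
    ni, nj = len(scores_i), len(scores_j)
    diff = scores_i[:, None] - scores_j[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (ni * nj))


def multiclass_auc(preds: PredictionSet) -> float:
    """Hand & Till's M: the average over ordered class pairs (i, j) of the
    probability that a random class-i case receives a higher class-i score
    than a random class-j case (ties get half credit).

    Pairs involving a class absent from the labels are skipped with a
    warning; if fewer than two classes are present the measure is undefined
    and NaN is returned.
    """
    present = [k for k in range(preds.probs.shape[1]) if (preds.labels == k).any()]
    if len(present) < 2:
        logger.warning("multi-class AUC undefined: fewer than 2 classes present")
        return float("nan")
    if len(present) < preds.probs.shape[1]:
        logger.warning(
            "classes absent from labels; skipping their pairs: %s",
            sorted(set(range(preds.probs.shape[1])) - set(present)),
        )
    vals = []
    for i in present:
        for j in present:
            if i == j:
                continue
            vals.append(
                _pairwise_auc(
                    preds.probs[preds.labels == i, i], preds.probs[preds.labels == j, i]
                )
            )
    return float(np.mean(vals))


def one_vs_rest_auc(preds: PredictionSet) -> float:
    """Macro one-vs-rest AUC, reported alongside M as a secondary view."""
    vals = []
    for k in range(preds.probs.shape[1]):
        pos = preds.labels == k
        if pos.any() and (~pos).any():
            vals.append(_pairwise_auc(preds.probs[pos, k], preds.probs[~pos, k]))
    return float(np.mean(vals)) if vals else float("nan")


# ----------------------------------------------------------------------
# network evaluation protocols
# ----------------------------------------------------------------------
def _split_vars(dag: dict[str, list[str]], table: pd.DataFrame):
    numeric = [v for v in dag if v in table.columns and pd.api.types.is_numeric_dtype(table[v])]
    categorical = [v for v in dag if v in table.columns and v not in numeric]
    missing = [v for v in dag if v not in table.columns]
    if missing:
        raise SchemaError(f"table is missing network variables: {missing}")
    return numeric, categorical


def _net_from_rows(dag, table, rows, target, evidence_vars, smoothing):
    sub = table.iloc[rows]
    dmap = DiscretizationMap.fit(sub, *_split_vars(dag, sub))
    disc = dmap.apply(sub)
    net = fit_cpts(dag, disc, dmap.states(), smoothing=smoothing,
                   target=target, evidence_vars=evidence_vars)
    return dmap, net


def default_evidence_vars(dag: dict[str, list[str]], target: str) -> list[str]:
    """Pre-intervention tier: everything that is not a post-intervention
    response (emotions, involvement, deep processing, post intention)."""
    post = {"anger", "anxiety", "fear", "calm", "hope", "involvement",
            "deep_processing", "intention_post"}
    return [v for v in dag if v != target and v not in post]


def predict_rows(net: DiscreteNet, disc: pd.DataFrame, evidence_vars: list[str],
                 target: str) -> np.ndarray:
    probs = np.empty((len(disc), net.card(target)))
    for r, (_, row) in enumerate(disc.iterrows()):
        ev = {v: row[v] for v in evidence_vars if v in net.states}
        probs[r] = infer_posterior(net, ev, target=target)
    return probs


def loo_protocol(
    dag: dict[str, list[str]],
    table: pd.DataFrame,
    target: str = "intention_post",
    smoothing: float = 1.0,
    evidence_vars: list[str] | None = None,
) -> PredictionSet:
    """Leave-one-out: for each row, tertile cut-offs and CPTs are refit on
    the other n-1 rows and the held-out row's target posterior is predicted
    from its pre-intervention evidence plus frame.  Deterministic.

    The held-out row never influences the fold's cut-offs or CPTs; its true
    label is its raw target value coded with the fold's training cut-offs.
    """
    n = len(table)
    if n < 10:
        raise DataError(f"leave-one-out needs n >= 10, got {n}")
    evidence_vars = evidence_vars or default_evidence_vars(dag, target)
    all_rows = np.arange(n)
    probs = np.empty((n, 3))
    labels = np.empty(n, dtype=np.intp)
    states = None
    for i in range(n):
        rows = all_rows[all_rows != i]
        dmap, net = _net_from_rows(dag, table, rows, target, evidence_vars, smoothing)
        held = dmap.apply(table.iloc[[i]])
        ev = {v: held.iloc[0][v] for v in evidence_vars if v in net.states}
        post = infer_posterior(net, ev, target=target)
        if states is None:
            states = net.states[target]
            probs = np.empty((n, len(states)))
        probs[i] = post
        labels[i] = net.state_index(target, held.iloc[0][target])
    return PredictionSet(probs=probs, labels=labels, states=states)


def kfold_protocol(
    dag, table, target: str = "intention_post", k: int = 10, smoothing: float = 1.0,
    evidence_vars: list[str] | None = None, seed: int = 0,
) -> PredictionSet:
    """k-fold variant of the out-of-sample protocol (faster than LOO; the
    acceptance-grade protocol is LOO)."""
    n = len(table)
    if n < k:
        raise DataError(f"k-fold needs n >= k, got n={n}, k={k}")
    evidence_vars = evidence_vars or default_evidence_vars(dag, target)
    rng = np.random.default_rng(seed)
    fold = rng.permutation(np.arange(n) % k)
    probs = None
    labels = np.empty(n, dtype=np.intp)
    states = None
    for f in range(k):
        rows = np.flatnonzero(fold != f)
        test = np.flatnonzero(fold == f)
        dmap, net = _net_from_rows(dag, table, rows, target, evidence_vars, smoothing)
        disc = dmap.apply(table.iloc[test])
        if states is None:
            states = net.states[target]
            probs = np.empty((n, len(states)))
        probs[test] = predict_rows(net, disc, evidence_vars, target)
        labels[test] = [net.state_index(target, s) for s in disc[target]]
    return PredictionSet(probs=probs, labels=labels, states=states)


def in_out_analysis(
    dag: dict[str, list[str]],
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    target: str = "intention_post",
    smoothing: float = 1.0,
    evidence_vars: list[str] | None = None,
) -> dict[str, float]:
    """Cohort-transfer check: LOO AUC on the training cohort versus AUC on a
    second cohort scored with the training discretization and CPTs (no
    refitting)."""
    missing = [v for v in dag if v not in test_table.columns]
    if missing:
        raise SchemaError(f"test table is missing network variables: {missing}")
    evidence_vars = evidence_vars or default_evidence_vars(dag, target)
    train_auc = multiclass_auc(
        loo_protocol(dag, train_table, target, smoothing, evidence_vars)
    )
    dmap, net = _net_from_rows(
        dag, train_table, np.arange(len(train_table)), target, evidence_vars, smoothing
    )
    disc = dmap.apply(test_table)
    probs = predict_rows(net, disc, evidence_vars, target)
    labels = np.array([net.state_index(target, s) for s in disc[target]])
    transfer_auc = multiclass_auc(
        PredictionSet(probs=probs, labels=labels, states=net.states[target])
    )
    return {"train_loo_auc": train_auc, "transfer_auc": transfer_auc}


# ----------------------------------------------------------------------
# parameter recovery
# ----------------------------------------------------------------------
INDIRECT_CHAINS = {
    "prevention*calm->involvement": ["prevention", "calm", "involvement"],
    "promotion*calm->involvement": ["promotion", "calm", "involvement"],
    "prevention*hope->involvement": ["prevention", "hope", "involvement"],
    "promotion*hope->involvement": ["promotion", "hope", "involvement"],
}


@dataclass
class RecoveryReport:
    """True vs. re-estimated standardized coefficients over replicates."""

    table: pd.DataFrame
    replicates: int
    n_converged: int
    seed: int
    valid: bool = True
    per_replicate: pd.DataFrame | None = None

    def row(self, param: str) -> pd.Series:
        return self.table.loc[param]


def recovery_experiment(
    config: GeneratorConfig | None = None,
    replicates: int = 50,
    seed: int = 1,
    n: int = 564,
    compute_coverage: bool = False,
) -> RecoveryReport:
    """Simulate ``replicates`` cohorts of size ``n`` from ``config``, fit
    the theory model to each, and aggregate the standardized structural
    estimates and the four product-of-paths indirect effects.

    Replicate r uses seed ``seed + r``.  Non-converged replicates are
    excluded and counted; if more than 10% fail the report is flagged
    invalid.  ``compute_coverage`` additionally records the coverage of the
    normal-theory 95% intervals (slower: needs per-replicate SEs).
    """
    base = config or GeneratorConfig()
    spec = sem.build_theory_model()
    truths = {f"{a}->{b}": v for (a, b), v in base.structural_paths.items()}
    for name, chain in INDIRECT_CHAINS.items():
        truths[name] = float(
            np.prod([base.structural_paths[(x, y)] for x, y in zip(chain[:-1], chain[1:])])
        )
    params = list(truths)
    records = []
    n_converged = 0
    for r in range(replicates):
        import dataclasses as _dc

        cfg = _dc.replace(base, n_participants=n, seed=seed + r)
        fit = sem.fit_sem(spec, simulate_cohort(cfg), se=compute_coverage)
        if not fit.converged:
            logger.warning("replicate %d did not converge; excluded", r)
            continue
        n_converged += 1
        rec = {}
        for p in params:
            if "*" in p:
                rec[p] = float(
                    np.prod([fit.estimates[f"{x}->{y}"]
                             for x, y in zip(INDIRECT_CHAINS[p][:-1], INDIRECT_CHAINS[p][1:])])
                )
            else:
                rec[p] = fit.estimates[p]
                if compute_coverage and p in fit.se:
                    half = 1.959964 * fit.se[p]
                    rec[p + "::covered"] = abs(rec[p] - truths[p]) <= half
        records.append(rec)
    per = pd.DataFrame(records)
    rows = []
    for p in params:
        est = per[p].to_numpy()
        row = {
            "true": truths[p],
            "mean": float(est.mean()),
            "empirical_se": float(est.std(ddof=1)) if len(est) > 1 else float("nan"),
            "bias": float(est.mean() - truths[p]),
        }
        if compute_coverage and p + "::covered" in per:
            row["coverage"] = float(per[p + "::covered"].mean())
        rows.append(row)
    table = pd.DataFrame(rows, index=params)
    return RecoveryReport(
        table=table,
        replicates=replicates,
        n_converged=n_converged,
        seed=seed,
        valid=(replicates - n_converged) <= 0.1 * replicates,
        per_replicate=per,
    )
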