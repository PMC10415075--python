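"""Structure elicitation for the predictive network.

The theory SEM supplies an immutable backbone (one node per latent
composite, every structural edge, the frame node pointing into the modelled
emotions, and the pre -> post intention slice that gives the network its
two-time-slice character).  Candidate variables (demographics and TPB
antecedents) are then admitted by a greedy forward search: each legal
single-edge addition from a candidate is scored by a combination of
in-sample and out-of-sample multi-class AUC for the target, and the best
strictly improving move is accepted until no move improves by at least
``eps``.  Backbone edges are never removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from reguframe.bayesnet import DiscreteNet, fit_cpts
from reguframe.discretize import DiscretizationMap
from reguframe.errors import InvalidConfigError, SchemaError
from reguframe.evaluation import (
    PredictionSet,
    default_evidence_vars,
    kfold_protocol,
    loo_protocol,
    multiclass_auc,
    predict_rows,
)
from reguframe.sem import SemSpec

logger = logging.getLogger(__name__)

TPB_VARS = ("attitude_cog", "attitude_aff", "norm", "pbc")
FOCI = ("promotion", "prevention")
DEFAULT_CANDIDATES = ("age", "gender", "education") + TPB_VARS


def backbone_from_sem(spec: SemSpec, frame_var: str = "frame") -> list[tuple[str, str]]:
    """Fixed backbone edge set over composite nodes: every structural edge
    of the SEM plus the frame node pointing into the modelled emotions (the
    intervention entry point)."""
    spec.validate()
    edges = list(spec.structural)
    for emotion in ("anger", "calm", "hope"):
        if emotion in spec.measurement:
            edges.append((frame_var, emotion))
    g = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise InvalidConfigError("backbone is not acyclic")
    return edges


def _edges_to_dag(nodes: list[str], edges: list[tuple[str, str]]) -> dict[str, list[str]]:
    dag: dict[str, list[str]] = {v: [] for v in nodes}
    for a, b in edges:
        dag[b].append(a)
    return dag


@dataclass
class SearchConfig:
    """Structure-search knobs: score weight w (combined score =
    w * in-sample AUC + (1 - w) * out-of-sample AUC), minimum improvement
    eps, parent cap, and the cross-validation protocol (``loo`` is the
    reference protocol; ``kfold`` trades exactness for speed).

    Moves are *ranked* by the combined score but *accepted* only when (a)
    both the combined score and its out-of-sample component improve by at
    least ``eps`` — the in-sample AUC of a CPT predictor is non-decreasing
    in added parents (resubstitution optimism), so an unconditional
    combined gate would admit pure-noise parents — and (b) a one-sided
    paired t-test on the per-row held-out log-scores shows the candidate
    model predicting better than the current one at level ``gate_alpha``
    (rows are independent, so the paired test is approximately exact and
    keeps chance fluctuations of the rank-based AUC from being mistaken
    for signal).  Set ``gate_alpha = 1`` to disable the significance
    gate."""

    weight: float = 0.5
    eps: float = 0.005
    parent_cap: int = 4
    cv: str = "loo"
    kfolds: int = 10
    smoothing: float = 1.0
    target: str = "intention_post"
    seed: int = 0
    gate_alpha: float = 0.005


@dataclass
class StructureSearchResult:
    net: DiscreteNet
    dag: dict[str, list[str]]
    dmap: DiscretizationMap
    trace: list[dict] = field(default_factory=list)
    backbone_edges: list[tuple[str, str]] = field(default_factory=list)
    backbone_score: float = float("nan")
    final_score: float = float("nan")


def _score_dag(dag, table, config: SearchConfig):
    evidence = default_evidence_vars(dag, config.target)
    numeric = [v for v in dag if pd.api.types.is_numeric_dtype(table[v])]
    categorical = [v for v in dag if v not in numeric]
    dmap = DiscretizationMap.fit(table, numeric, categorical)
    disc = dmap.apply(table)
    net = fit_cpts(dag, disc, dmap.states(), smoothing=config.smoothing,
                   target=config.target, evidence_vars=evidence)
    probs = predict_rows(net, disc, evidence, config.target)
    labels = np.array([net.state_index(config.target, s) for s in disc[config.target]])
    auc_in = multiclass_auc(PredictionSet(probs, labels, net.states[config.target]))
    if config.cv == "loo":
        out_preds = loo_protocol(dag, table, config.target, config.smoothing, evidence)
    elif config.cv == "kfold":
        out_preds = kfold_protocol(dag, table, config.target, config.kfolds,
                                   config.smoothing, evidence, config.seed)
    else:
        raise InvalidConfigError(f"unknown cv protocol {config.cv!r}")
    auc_out = multiclass_auc(out_preds)
    combined = config.weight * auc_in + (1.0 - config.weight) * auc_out
    return combined, auc_in, auc_out, out_preds


def _paired_logscore_p(base: PredictionSet, trial: PredictionSet) -> float:
    """One-sided p-value that the trial model's held-out log-score beats the
    base model's, from a paired t-test over rows (both prediction sets
    cover the same rows in the same order)."""
    from scipy import stats

    lp_base = np.log(base.probs[np.arange(len(base.labels)), base.labels] + 1e-12)
    lp_trial = np.log(trial.probs[np.arange(len(trial.labels)), trial.labels] + 1e-12)
    d = lp_trial - lp_base
    sd = d.std(ddof=1)
    if sd == 0.0:
        return 1.0 if d.mean() <= 0 else 0.0
    t = d.mean() / (sd / np.sqrt(len(d)))
    return float(stats.t.sf(t, df=len(d) - 1))


def structure_search(
    backbone_edges: list[tuple[str, str]],
    candidate_vars: list[str],
    table: pd.DataFrame,
    config: SearchConfig | None = None,
) -> StructureSearchResult:
    """Greedy forward elicitation over candidate-variable edges.

    At each step every legal single-edge addition *from* a candidate
    variable (into a backbone node, an already-admitted candidate, or —
    candidate-to-candidate — another candidate) is scored; the best move is
    accepted if it improves the combined score by at least ``eps``.
    Edges into the exogenous foci from TPB variables are excluded to keep
    the theory backbone's causal reading.  An empty candidate set returns
    the backbone network unchanged.
    """
    config = config or SearchConfig()
    backbone_nodes = sorted({v for e in backbone_edges for v in e})
    overlap = set(candidate_vars) & set(backbone_nodes)
    if overlap:
        raise InvalidConfigError(f"candidates overlap the backbone: {sorted(overlap)}")
    missing = [v for v in backbone_nodes + list(candidate_vars) if v not in table.columns]
    if missing:
        raise SchemaError(f"table is missing variables: {missing}")

    nodes = list(backbone_nodes)
    edges = list(backbone_edges)
    current, auc_in, current_out, current_preds = _score_dag(
        _edges_to_dag(nodes, edges), table, config
    )
    backbone_score = current
    trace: list[dict] = []
    logger.info("backbone combined score %.4f (in %.4f / out %.4f)", current, auc_in, current_out)

    remaining = list(candidate_vars)
    max_steps = max(1, len(candidate_vars) * config.parent_cap)
    for _ in range(max_steps):
        moves = []
        in_net = set(nodes)
        for c in candidate_vars:
            heads = [v for v in nodes if v != c]
            for v in heads:
                if v in FOCI and c in TPB_VARS:
                    continue  # preserve the backbone's causal reading
                if (c, v) in edges:
                    continue
                dag_nodes = nodes if c in in_net else nodes + [c]
                if len(_edges_to_dag(dag_nodes, edges)[v]) >= config.parent_cap:
                    continue
                g = nx.DiGraph(edges + [(c, v)])
                g.add_nodes_from(dag_nodes)
                if not nx.is_directed_acyclic_graph(g):
                    continue
                moves.append((c, v))
        if not moves:
            break
        best = None
        for c, v in moves:
            trial_nodes = nodes if c in in_net else nodes + [c]
            trial = _edges_to_dag(trial_nodes, edges + [(c, v)])
            score, s_in, s_out, preds = _score_dag(trial, table, config)
            trace.append(
                {"edge": (c, v), "score_in": s_in, "score_out": s_out,
                 "combined": score, "accepted": False}
            )
            passes = (score - current >= config.eps
                      and s_out - current_out >= config.eps)
            if passes and (best is None or score > best[0]):
                best = (score, s_out, preds, c, v, len(trace) - 1)
        if best is None:
            logger.info("no move improves by >= %.3g; stopping", config.eps)
            break
        score, s_out, preds, c, v, t_idx = best
        if config.gate_alpha < 1.0:
            p = _paired_logscore_p(current_preds, preds)
            trace[t_idx]["gate_p"] = p
            if p > config.gate_alpha:
                logger.info(
                    "best move %s -> %s fails the paired log-score gate "
                    "(p = %.4f > %.3g); stopping", c, v, p, config.gate_alpha,
                )
                break
        trace[t_idx]["accepted"] = True
        edges.append((c, v))
        if c not in nodes:
            nodes.append(c)
        current, current_out, current_preds = score, s_out, preds
        logger.info("accepted %s -> %s (combined %.4f, out %.4f)", c, v, score, s_out)

    dag = _edges_to_dag(nodes, edges)
    evidence = default_evidence_vars(dag, config.target)
    numeric = [v for v in dag if pd.api.types.is_numeric_dtype(table[v])]
    categorical = [v for v in dag if v not in numeric]
    dmap = DiscretizationMap.fit(table, numeric, categorical)
    net = fit_cpts(dag, dmap.apply(table), dmap.states(), smoothing=config.smoothing,
                   target=config.target, evidence_vars=evidence)
    return StructureSearchResult(
        net=net, dag=dag, dmap=dmap, trace=trace,
        backbone_edges=list(backbone_edges),
        backbone_score=backbone_score, final_score=current,
    )
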