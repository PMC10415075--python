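"""Discrete Bayesian network over tertile-coded composites: CPT estimation
with Laplace smoothing, exact inference by variable elimination, and seeded
forward/conditional sampling.

Networks are small (one node per questionnaire composite plus the frame and
demographics), so exact inference is cheap; the implementation favours
clarity and numpy-speed counting, which the leave-one-out protocols rely
on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from reguframe.errors import (
    ComplexityError,
    ImpossibleEvidenceError,
    InvalidConfigError,
    SchemaError,
)

MAX_PARENTS = 6


@dataclass
class DiscreteNet:
    """A DAG with one conditional probability table per node.

    ``states[v]`` is the ordered label list of node v; ``cpts[v]`` has shape
    ``(card(v), card(p1), ..., card(pk))`` for parents ``parents[v]`` and
    every slice over the first axis sums to one.
    """

    states: dict[str, list[str]]
    parents: dict[str, list[str]]
    cpts: dict[str, np.ndarray]
    target: str = "intention_post"
    frame_var: str = "frame"
    evidence_vars: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.states)

    def card(self, v: str) -> int:
        return len(self.states[v])

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        for v, ps in self.parents.items():
            g.add_edges_from((p, v) for p in ps)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.graph()))

    def validate(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidConfigError("network graph is not acyclic")
        for v in self.nodes:
            shape = (self.card(v),) + tuple(self.card(p) for p in self.parents.get(v, []))
            if self.cpts[v].shape != shape:
                raise InvalidConfigError(f"CPT of {v} has shape {self.cpts[v].shape}, expected {shape}")
            sums = self.cpts[v].sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise InvalidConfigError(f"CPT rows of {v} do not sum to 1")
            if (self.cpts[v] < 0).any():
                raise InvalidConfigError(f"CPT of {v} has negative entries")

    def state_index(self, v: str, label: str) -> int:
        try:
            return self.states[v].index(label)
        except ValueError as exc:
            raise SchemaError(f"{label!r} is not a state of {v}") from exc

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "states": self.states,
                "parents": self.parents,
                "cpts": {v: self.cpts[v].tolist() for v in self.nodes},
                "target": self.target,
                "frame_var": self.frame_var,
                "evidence_vars": self.evidence_vars,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscreteNet":
        d = json.loads(text)
        net = cls(
            states=d["states"],
            parents=d["parents"],
            cpts={v: np.asarray(t, dtype=float) for v, t in d["cpts"].items()},
            target=d.get("target", "intention_post"),
            frame_var=d.get("frame_var", "frame"),
            evidence_vars=d.get("evidence_vars", []),
        )
        net.validate()
        return net

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "DiscreteNet":
        return cls.from_json(Path(path).read_text())


# ----------------------------------------------------------------------
# CPT estimation
# ----------------------------------------------------------------------
def encode_table(table: pd.DataFrame, states: dict[str, list[str]]) -> dict[str, np.ndarray]:
    """Map a label table to integer codes according to ``states``."""
    codes = {}
    for v, labels in states.items():
        if v not in table.columns:
            raise SchemaError(f"table is missing column {v!r}")
        cat = pd.Categorical(table[v], categories=labels)
        arr = cat.codes.to_numpy() if hasattr(cat.codes, "to_numpy") else np.asarray(cat.codes)
        if (arr < 0).any():
            bad = sorted(set(table[v]) - set(labels))
            raise SchemaError(f"column {v} has values outside its state space: {bad}")
        codes[v] = arr.astype(np.intp)
    return codes


def fit_cpts(
    dag: dict[str, list[str]],
    table: pd.DataFrame,
    states: dict[str, list[str]],
    smoothing: float = 1.0,
    target: str = "intention_post",
    frame_var: str = "frame",
    evidence_vars: list[str] | None = None,
    codes: dict[str, np.ndarray] | None = None,
) -> DiscreteNet:
    """Estimate all CPTs by smoothed counting:
    (count + s) / (sum counts + s * n_states).

    ``dag`` maps node -> parent list.  ``codes`` allows passing
    pre-encoded integer columns (the LOO protocol re-counts hundreds of
    times on the same encoding).
    """
    for v, ps in dag.items():
        if len(ps) > MAX_PARENTS:
            raise ComplexityError(
                f"node {v} has {len(ps)} parents (> {MAX_PARENTS}); "
                "constrain the structure search"
            )
    if codes is None:
        codes = encode_table(table, {v: states[v] for v in dag})
    cpts = {}
    for v, ps in dag.items():
        card_v = len(states[v])
        pcards = [len(states[p]) for p in ps]
        flat = codes[v].copy()
        mult = card_v
        for p, cp in zip(ps, pcards):
            flat = flat + mult * codes[p]
            mult *= cp
        counts = np.bincount(flat, minlength=mult).astype(float)
        counts = counts.reshape(tuple(reversed(pcards)) + (card_v,))
        # axes currently (pk, ..., p1, v) -> (v, p1, ..., pk)
        counts = np.moveaxis(counts, -1, 0)
        counts = np.transpose(counts, axes=(0,) + tuple(range(len(ps), 0, -1)))
        counts += smoothing
        denom = counts.sum(axis=0, keepdims=True)
        if smoothing == 0.0:
            denom = np.where(denom == 0.0, 1.0, denom)
        cpts[v] = counts / denom
    net = DiscreteNet(
        states={v: list(states[v]) for v in dag},
        parents={v: list(ps) for v, ps in dag.items()},
        cpts=cpts,
        target=target,
        frame_var=frame_var,
        evidence_vars=evidence_vars or [],
    )
    net.validate()
    return net


# ----------------------------------------------------------------------
# exact inference: variable elimination
# ----------------------------------------------------------------------
class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars_: tuple[str, ...], table: np.ndarray):
        self.vars = vars_
        self.table = table

    def reduce(self, var: str, idx: int) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1 :], np.take(self.table, idx, axis=ax)
        )


def _multiply(f1: _Factor, f2: _Factor) -> _Factor:
    """Broadcasted factor product over the union of the two scopes."""
    vars_ = f1.vars + tuple(v for v in f2.vars if v not in f1.vars)
    t1 = f1.table.reshape(f1.table.shape + (1,) * (len(vars_) - len(f1.vars)))
    present = [v for v in vars_ if v in f2.vars]
    t2 = np.transpose(f2.table, [f2.vars.index(v) for v in present])
    shape = [t2.shape[present.index(v)] if v in f2.vars else 1 for v in vars_]
    return _Factor(vars_, t1 * t2.reshape(shape))


def _marginalize(f: _Factor, var: str) -> _Factor:
    ax = f.vars.index(var)
    return _Factor(f.vars[:ax] + f.vars[ax + 1 :], f.table.sum(axis=ax))


def infer_posterior(
    net: DiscreteNet, evidence: dict[str, str], target: str | None = None
) -> np.ndarray:
    """Exact posterior P(target | evidence) by variable elimination.

    ``evidence`` maps node -> state label.  Returns a probability vector
    over the target's states (sums to one).  Evidence with zero probability
    raises ``ImpossibleEvidenceError``.
    """
    target = target or net.target
    if target not in net.states:
        raise SchemaError(f"unknown target {target!r}")
    ev_idx = {v: net.state_index(v, s) for v, s in evidence.items()}
    if target in ev_idx:
        out = np.zeros(net.card(target))
        out[ev_idx[target]] = 1.0
        return out

    factors = []
    for v in net.nodes:
        f = _Factor((v,) + tuple(net.parents[v]), net.cpts[v])
        for ev, idx in ev_idx.items():
            if ev in f.vars:
                f = f.reduce(ev, idx)
        factors.append(f)

    elim = [v for v in net.nodes if v != target and v not in ev_idx]
    # min-degree-ish: eliminate variables appearing in the fewest factors first
    while elim:
        elim.sort(key=lambda v: sum(v in f.vars for f in factors))
        v = elim.pop(0)
        related = [f for f in factors if v in f.vars]
        factors = [f for f in factors if v not in f.vars]
        if not related:
            continue
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        factors.append(_marginalize(prod, v))

    result = factors[0]
    for f in factors[1:]:
        result = _multiply(result, f)
    table = result.table
    if result.vars != (target,):
        ax = result.vars.index(target)
        table = np.moveaxis(table, ax, 0).reshape(net.card(target), -1).sum(axis=1)
    z = table.sum()
    if z <= 0.0:
        raise ImpossibleEvidenceError(f"evidence {evidence} has zero probability")
    return table / z


def sample_forward(net: DiscreteNet, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` joint samples by ancestral sampling (label table)."""
    order = net.topological_order()
    cols: dict[str, np.ndarray] = {}
    code: dict[str, np.ndarray] = {}
    for v in order:
        ps = net.parents[v]
        cpt = net.cpts[v]
        if not ps:
            probs = np.broadcast_to(cpt[:, None], (net.card(v), n)).T
        else:
            idx = tuple(code[p] for p in ps)
            probs = np.moveaxis(cpt, 0, -1)[idx]
        u = rng.random(n)[:, None]
        code[v] = (probs.cumsum(axis=1) < u).sum(axis=1).astype(np.intp)
        code[v] = np.minimum(code[v], net.card(v) - 1)
        cols[v] = np.asarray(net.states[v], dtype=object)[code[v]]
    return pd.DataFrame(cols)


def sample_conditional(
    net: DiscreteNet, evidence: dict[str, str], variable: str, rng: np.random.Generator
) -> str:
    """Draw one state of ``variable`` from its exact posterior given
    ``evidence``."""
    if variable in evidence:
        raise SchemaError(f"{variable} is already observed")
    post = infer_posterior(net, evidence, target=variable)
    idx = int(rng.choice(len(post), p=post))
    return net.states[variable][idx]
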