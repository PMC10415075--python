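import itertools

import numpy as np
import pandas as pd
import pytest

from reguframe.bayesnet import DiscreteNet
from reguframe.cohort import GeneratorConfig, simulate_cohort
from reguframe.sem import build_theory_model

FRAMES = ["gain", "non_loss", "non_gain", "loss"]


@pytest.fixture(scope="session")
def cohort_564():
    return simulate_cohort(GeneratorConfig(n_participants=564, seed=7))


@pytest.fixture(scope="session")
def cohort_5000():
    return simulate_cohort(GeneratorConfig(n_participants=5000, seed=11))


@pytest.fixture(scope="session")
def theory_spec():
    return build_theory_model()


def random_cpt(rng, card, pcards):
    t = rng.random((card,) + tuple(pcards)) + 0.05
    return t / t.sum(axis=0, keepdims=True)


def random_net(seed: int, max_nodes: int = 6) -> DiscreteNet:
    """Random small DAG with random CPTs (for inference-oracle checks)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"v{i}" for i in range(n)]
    cards = rng.integers(2, 4, n)
    states = {v: [f"{v}s{k}" for k in range(cards[i])] for i, v in enumerate(names)}
    parents = {}
    for i, v in enumerate(names):
        pool = names[:i]
        k = int(rng.integers(0, min(len(pool), 3) + 1))
        parents[v] = list(rng.choice(pool, size=k, replace=False)) if k else []
    cpts = {
        v: random_cpt(rng, len(states[v]), [len(states[p]) for p in parents[v]])
        for v in names
    }
    return DiscreteNet(states, parents, cpts, target=names[-1])


def joint_enumeration(net: DiscreteNet) -> tuple[list[str], np.ndarray]:
    """Independent full-joint oracle: multiply CPT entries over every joint
    assignment (no factor algebra shared with the implementation)."""
    order = net.topological_order()
    cards = [net.card(v) for v in order]
    joint = np.zeros(cards)
    for assign in itertools.product(*(range(c) for c in cards)):
        st = dict(zip(order, assign))
        p = 1.0
        for v in order:
            idx = (st[v],) + tuple(st[p_] for p_ in net.parents[v])
            p *= net.cpts[v][idx]
        joint[assign] = p
    return order, joint


def posterior_by_enumeration(net, evidence, target):
    order, joint = joint_enumeration(net)
    axes = {v: i for i, v in enumerate(order)}
    sl = [slice(None)] * len(order)
    for v, s in evidence.items():
        sl[axes[v]] = net.state_index(v, s)
    sub = joint[tuple(sl)]
    remaining = [v for v in order if v not in evidence]
    t_ax = remaining.index(target)
    sub = np.moveaxis(sub, t_ax, 0).reshape(net.card(target), -1).sum(axis=1)
    return sub / sub.sum()


def matching_toy_net(
    n_traits: int = 1,
    relevant: int = 1,
    p_match: float = 0.8,
    p_mismatch: float = 0.2,
    seed: int = 0,
) -> DiscreteNet:
    """Toy respondent network: ternary traits, 4 frames, ternary target.

    The first ``relevant`` traits interact with the frame: the target's
    top-state probability is ``p_match`` when the frame index matches the
    (sum of relevant trait indices mod 4), else ``p_mismatch``.  Remaining
    traits are pure noise.
    """
    rng = np.random.default_rng(seed)
    traits = [f"trait{i}" for i in range(n_traits)]
    states = {t: ["low", "medium", "high"] for t in traits}
    states["frame"] = list(FRAMES)
    states["intention_post"] = ["low", "medium", "high"]
    parents = {t: [] for t in traits}
    parents["frame"] = []
    parents["intention_post"] = traits[:relevant] + ["frame"]
    shape = (3,) + (3,) * relevant + (4,)
    cpt = np.zeros(shape)
    for combo in itertools.product(*(range(3) for _ in range(relevant))):
        for f in range(4):
            ph = p_match if (sum(combo) % 4) == f else p_mismatch
            cpt[(slice(None),) + combo + (f,)] = [(1 - ph) / 2, (1 - ph) / 2, ph]
    cpts = {t: np.full(3, 1 / 3) for t in traits}
    cpts["frame"] = np.full(4, 0.25)
    cpts["intention_post"] = cpt
    net = DiscreteNet(
        states, parents, cpts, target="intention_post", evidence_vars=traits
    )
    net.validate()
    return net


def dominant_frame_net() -> DiscreteNet:
    """One frame strictly dominates (top-state probability 0.9 vs 0.1) and
    no trait carries information."""
    states = {
        "trait0": ["low", "medium", "high"],
        "frame": list(FRAMES),
        "intention_post": ["low", "medium", "high"],
    }
    parents = {"trait0": [], "frame": [], "intention_post": ["frame"]}
    cpt = np.zeros((3, 4))
    for f in range(4):
        ph = 0.9 if f == 0 else 0.1
        cpt[:, f] = [(1 - ph) / 2, (1 - ph) / 2, ph]
    net = DiscreteNet(
        states,
        parents,
        {"trait0": np.full(3, 1 / 3), "frame": np.full(4, 0.25), "intention_post": cpt},
        target="intention_post",
        evidence_vars=["trait0"],
    )
    net.validate()
    return net
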