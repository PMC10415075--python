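"""Fast-profiling policy: which trait question to ask next, and which
message frame to send, learned against the discrete network used as a
respondent simulator.

The interaction is a finite-horizon decision problem.  A state is the
partial evidence over askable (pre-intervention) variables; a move either
queries an unobserved variable (the simulated respondent answers by a draw
from the network posterior) or commits to one of the four frames, ending
the episode with reward = posterior probability that the target
(post-intervention intention) is in its top tertile given the collected
evidence and the chosen frame.  Search is PUCT-style MCTS guided by a
trainable move/value network; the deployable artifact is a deterministic
bounded-depth decision tree extracted from the search, validated against an
exact dynamic-programming oracle on small networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from reguframe.bayesnet import DiscreteNet, infer_posterior
from reguframe.errors import ComplexityError, ContractError, InvalidConfigError
from reguframe.guidance import GuidanceFunction

Move = tuple[str, str]  # ("ask", variable) or ("send", frame)


@dataclass(frozen=True)
class InteractionState:
    """Partial evidence collected so far; terminal iff a frame was sent."""

    evidence: tuple[tuple[str, str], ...] = ()
    questions_asked: int = 0
    chosen_frame: str | None = None

    @property
    def terminal(self) -> bool:
        return self.chosen_frame is not None

    def evidence_dict(self) -> dict[str, str]:
        return dict(self.evidence)

    def with_answer(self, var: str, answer: str) -> "InteractionState":
        ev = dict(self.evidence)
        if var in ev:
            raise ContractError(f"{var} was already queried")
        ev[var] = answer
        return InteractionState(
            evidence=tuple(sorted(ev.items())),
            questions_asked=self.questions_asked + 1,
        )

    def with_frame(self, frame: str) -> "InteractionState":
        return replace(self, chosen_frame=frame)


@dataclass
class PolicyConfig:
    """Interaction budget and search knobs.

    ``askable`` is the queryable tier (pre-intervention traits and
    demographics; post-intervention responses are outcomes, never
    queryable).  ``min_questions`` is a reporting bound for extracted
    trees — sending is always a legal move — while ``max_questions`` is a
    hard budget.
    """

    askable: list[str]
    frames: list[str]
    target: str = "intention_post"
    reward_state: str = "high"
    max_questions: int = 6
    min_questions: int = 3
    c_puct: float = 1.5
    n_sim_train: int = 200
    n_sim_extract: int = 800
    episodes: int = 300
    train_every: int = 50
    epochs_per_fit: int = 10
    hidden: int = 64

    @classmethod
    def from_net(cls, net: DiscreteNet, **overrides) -> "PolicyConfig":
        askable = overrides.pop(
            "askable",
            [v for v in (net.evidence_vars or net.nodes)
             if v != net.frame_var and v != net.target],
        )
        frames = overrides.pop("frames", list(net.states[net.frame_var]))
        return cls(askable=askable, frames=frames, target=net.target, **overrides)


class NetOracle:
    """Memoized exact queries against the respondent network: terminal
    rewards and answer distributions."""

    def __init__(self, net: DiscreteNet, config: PolicyConfig):
        self.net = net
        self.config = config
        self._reward: dict = {}
        self._answers: dict = {}
        self._high = net.state_index(config.target, config.reward_state)

    def reward(self, evidence: tuple, frame: str) -> float:
        key = (evidence, frame)
        if key not in self._reward:
            ev = dict(evidence)
            ev[self.net.frame_var] = frame
            post = infer_posterior(self.net, ev, target=self.config.target)
            self._reward[key] = float(post[self._high])
        return self._reward[key]

    def answer_dist(self, evidence: tuple, var: str) -> np.ndarray:
        key = (evidence, var)
        if key not in self._answers:
            self._answers[key] = infer_posterior(self.net, dict(evidence), target=var)
        return self._answers[key]


def legal_moves(state: InteractionState, net: DiscreteNet, config: PolicyConfig) -> list[Move]:
    """All send moves, plus a query move per unobserved askable variable
    while the question budget lasts."""
    if state.terminal:
        raise ContractError("no legal moves in a terminal state")
    moves: list[Move] = []
    if state.questions_asked < config.max_questions:
        observed = {v for v, _ in state.evidence}
        moves += [("ask", v) for v in config.askable if v not in observed]
    moves += [("send", f) for f in config.frames]
    return moves


def simulate_step(
    net: DiscreteNet,
    state: InteractionState,
    move: Move,
    rng: np.random.Generator,
    config: PolicyConfig,
    oracle: NetOracle | None = None,
) -> tuple[InteractionState, float | None]:
    """Apply one move against the respondent simulator.

    A query samples the answer from the network posterior conditional on
    the evidence so far; a send terminates with the exact posterior reward.
    """
    if move not in legal_moves(state, net, config):
        raise ContractError(f"illegal move {move} in state {state}")
    oracle = oracle or NetOracle(net, config)
    kind, arg = move
    if kind == "ask":
        dist = oracle.answer_dist(state.evidence, arg)
        idx = int(rng.choice(len(dist), p=dist))
        return state.with_answer(arg, net.states[arg][idx]), None
    reward = oracle.reward(state.evidence, arg)
    return state.with_frame(arg), reward


# ----------------------------------------------------------------------
# MCTS (PUCT)
# ----------------------------------------------------------------------
class _NodeStats:
    __slots__ = ("moves", "P", "N", "W", "children")

    def __init__(self, moves: list[Move], priors: np.ndarray):
        self.moves = moves
        self.P = priors
        self.N = np.zeros(len(moves))
        self.W = np.zeros(len(moves))
        self.children: dict[tuple[int, str], InteractionState] = {}


def mcts_search(
    state: InteractionState,
    net: DiscreteNet,
    guidance: GuidanceFunction | None,
    n_sim: int,
    c_puct: float,
    rng: np.random.Generator,
    config: PolicyConfig,
    oracle: NetOracle | None = None,
) -> dict[Move, float]:
    """PUCT tree search from ``state``; returns the normalized root visit
    distribution over legal moves.

    Selection maximizes Q + c_puct * prior * sqrt(N_parent) / (1 + N_child).
    Send moves are terminal and evaluated by the exact posterior reward;
    question answers are chance events, sampled per traversal from the
    network posterior (their values average over visits).  Unexpanded
    decision nodes are evaluated by the guidance value head (uniform priors
    and a neutral value when no guidance is given).
    """
    if n_sim < 1:
        raise InvalidConfigError("n_sim must be >= 1")
    if state.terminal:
        raise ContractError("cannot search from a terminal state")
    oracle = oracle or NetOracle(net, config)
    tree: dict[tuple, _NodeStats] = {}

    def get_node(s: InteractionState) -> _NodeStats:
        key = (s.evidence, s.questions_asked)
        if key not in tree:
            moves = legal_moves(s, net, config)
            if guidance is not None:
                priors, value = guidance.evaluate(s, moves)
                p = np.array([priors[m] for m in moves])
            else:
                p = np.full(len(moves), 1.0 / len(moves))
                value = 0.5
            node = _NodeStats(moves, p)
            tree[key] = (node, value)
        return tree[key]

    root_key = (state.evidence, state.questions_asked)
    get_node(state)

    for _ in range(n_sim):
        s = state
        path: list[tuple[_NodeStats, int]] = []
        value = None
        while True:
            key = (s.evidence, s.questions_asked)
            if key not in tree:
                _, value = get_node(s)  # expand leaf, back up its value
                break
            node, _ = tree[key]
            total = node.N.sum()
            q = np.where(node.N > 0, node.W / np.maximum(node.N, 1), 0.0)
            u = c_puct * node.P * np.sqrt(total + 1e-8) / (1.0 + node.N)
            idx = int(np.argmax(q + u))
            move = node.moves[idx]
            path.append((node, idx))
            if move[0] == "send":
                value = oracle.reward(s.evidence, move[1])
                break
            dist = oracle.answer_dist(s.evidence, move[1])
            ans_idx = int(rng.choice(len(dist), p=dist))
            s = s.with_answer(move[1], net.states[move[1]][ans_idx])
        for node, idx in path:
            node.N[idx] += 1
            node.W[idx] += value

    root, _ = tree[root_key]
    total = root.N.sum()
    if total == 0:
        # n_sim == 1 only expanded the root; fall back to priors
        return {m: float(p) for m, p in zip(root.moves, root.P)}
    return {m: float(n / total) for m, n in zip(root.moves, root.N)}


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------
def train_guidance(
    net: DiscreteNet,
    config: PolicyConfig | None = None,
    seed: int = 0,
) -> tuple[GuidanceFunction, list[dict]]:
    """Self-play training loop.

    Episodes start from empty evidence; at each state the MCTS visit
    distribution is recorded as the policy target; moves are sampled from
    the visits with temperature 1 for the first half of the question budget
    and greedily after; the realized terminal reward becomes the value
    target for every state of the episode.  The guidance network is
    refit every ``train_every`` episodes; the log records self-play rewards
    and held-out losses.  Fully seeded and deterministic.
    """
    config = config or PolicyConfig.from_net(net)
    rng = np.random.default_rng(seed)
    guidance = GuidanceFunction(
        config.askable,
        {v: net.states[v] for v in config.askable},
        config.frames,
        config.max_questions,
        hidden=config.hidden,
        seed=seed,
    )
    oracle = NetOracle(net, config)
    X_buf, Pi_buf, Mask_buf, Z_buf = [], [], [], []
    log: list[dict] = []
    rewards: list[float] = []
    for ep in range(config.episodes):
        state = InteractionState()
        episode: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        reward = None
        while reward is None:
            visits = mcts_search(
                state, net, guidance, config.n_sim_train, config.c_puct, rng, config, oracle
            )
            moves = list(visits)
            probs = np.array([visits[m] for m in moves])
            pi = np.zeros(guidance.n_moves)
            for m, p in visits.items():
                pi[guidance.move_index[m]] = p
            episode.append((guidance.encode(state), pi, guidance.move_mask(moves)))
            if state.questions_asked < config.max_questions / 2:
                move = moves[int(rng.choice(len(moves), p=probs / probs.sum()))]
            else:
                move = moves[int(np.argmax(probs))]
            state, reward = simulate_step(net, state, move, rng, config, oracle)
        rewards.append(reward)
        for x, pi, mask in episode:
            X_buf.append(x); Pi_buf.append(pi); Mask_buf.append(mask); Z_buf.append(reward)
        if (ep + 1) % config.train_every == 0 or ep + 1 == config.episodes:
            fit_log = guidance.fit(
                np.array(X_buf), np.array(Pi_buf), np.array(Mask_buf), np.array(Z_buf),
                epochs=config.epochs_per_fit, rng=rng,
            )
            log.append(
                {
                    "episode": ep + 1,
                    "buffer": len(X_buf),
                    "mean_reward": float(np.mean(rewards[-config.train_every:])),
                    "first_holdout_policy_ce": fit_log[0].get("holdout_policy_ce"),
                    "last_holdout_policy_ce": fit_log[-1].get("holdout_policy_ce"),
                    "first_holdout_value_mse": fit_log[0].get("holdout_value_mse"),
                    "last_holdout_value_mse": fit_log[-1].get("holdout_value_mse"),
                    "train_loss": fit_log[-1]["train_loss"],
                }
            )
    return guidance, log


# ----------------------------------------------------------------------
# policy trees
# ----------------------------------------------------------------------
@dataclass
class PolicyTree:
    """Rooted ask/send tree: internal nodes query a variable (one child per
    answer state), leaves commit to a frame."""

    kind: str  # "ask" | "send"
    label: str  # variable or frame
    children: dict[str, "PolicyTree"] = field(default_factory=dict)

    def depth_profile(self) -> list[int]:
        if self.kind == "send":
            return [0]
        return [1 + d for child in self.children.values() for d in child.depth_profile()]

    def max_depth(self) -> int:
        return max(self.depth_profile())

    def validate(self, max_questions: int, _seen: frozenset = frozenset()) -> None:
        if self.kind == "send":
            return
        if self.label in _seen:
            raise InvalidConfigError(f"variable {self.label} queried twice on a path")
        if len(_seen) >= max_questions:
            raise InvalidConfigError("tree exceeds the question budget")
        for child in self.children.values():
            child.validate(max_questions, _seen | {self.label})

    def to_dict(self) -> dict:
        if self.kind == "send":
            return {"send": self.label}
        return {"ask": self.label,
                "children": {s: c.to_dict() for s, c in self.children.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "PolicyTree":
        if "send" in d:
            return cls("send", d["send"])
        return cls("ask", d["ask"],
                   {s: cls.from_dict(c) for s, c in d["children"].items()})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PolicyTree":
        return cls.from_dict(json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PolicyTree":
        return cls.from_json(Path(path).read_text())


def brute_force_policy(
    net: DiscreteNet,
    max_questions: int,
    config: PolicyConfig | None = None,
    max_states: int = 100_000,
) -> tuple[float, PolicyTree]:
    """Exact dynamic program over the evidence lattice:

        V(e, b) = max( max_f E[reward | e, f],
                       max_v sum_a P(a | e) V(e + {v: a}, b - 1) )

    Ties prefer sending (shallower trees) and then the first option in
    deterministic order.  Raises ``ComplexityError`` when the evidence
    lattice is too large to enumerate.
    """
    config = config or PolicyConfig.from_net(net)
    size = 1
    for v in config.askable:
        size *= net.card(v) + 1
    if size > max_states:
        raise ComplexityError(
            f"evidence lattice has ~{size} configurations (> {max_states}); "
            "restrict the askable set or the budget"
        )
    oracle = NetOracle(net, config)
    memo: dict[tuple, tuple[float, PolicyTree]] = {}

    def V(evidence: tuple, budget: int) -> tuple[float, PolicyTree]:
        key = (evidence, budget)
        if key in memo:
            return memo[key]
        best_val, best_tree = max(
            ((oracle.reward(evidence, f), PolicyTree("send", f)) for f in config.frames),
            key=lambda t: t[0],
        )
        if budget > 0:
            observed = dict(evidence)
            for v in config.askable:
                if v in observed:
                    continue
                dist = oracle.answer_dist(evidence, v)
                children = {}
                ev = 0.0
                for a_idx, a in enumerate(net.states[v]):
                    if dist[a_idx] <= 0.0:
                        children[a] = PolicyTree("send", config.frames[0])
                        continue
                    child_ev = tuple(sorted(observed.items() | {(v, a)}))
                    val, sub = V(child_ev, budget - 1)
                    children[a] = sub
                    ev += dist[a_idx] * val
                if ev > best_val + 1e-12:
                    best_val, best_tree = ev, PolicyTree("ask", v, children)
        memo[key] = (best_val, best_tree)
        return memo[key]

    return V((), max_questions)


def extract_policy_tree(
    guidance: GuidanceFunction | None,
    net: DiscreteNet,
    config: PolicyConfig | None = None,
    seed: int = 0,
) -> PolicyTree:
    """Deterministic tree extraction: at each node run a high-simulation
    MCTS, take the most-visited move, and — if it is a question — branch on
    every possible answer and recurse.  Depth is clamped by the question
    budget (at the budget only send moves are legal)."""
    config = config or PolicyConfig.from_net(net)
    oracle = NetOracle(net, config)
    rng = np.random.default_rng(seed)

    def build(state: InteractionState) -> PolicyTree:
        visits = mcts_search(
            state, net, guidance, config.n_sim_extract, config.c_puct, rng, config, oracle
        )
        moves = list(visits)
        counts = np.array([visits[m] for m in moves])
        move = moves[int(np.argmax(counts))]
        if move[0] == "send":
            return PolicyTree("send", move[1])
        var = move[1]
        children = {
            a: build(state.with_answer(var, a)) for a in net.states[var]
        }
        return PolicyTree("ask", var, children)

    tree = build(InteractionState())
    tree.validate(config.max_questions)
    if tree.max_depth() < config.min_questions:
        import logging

        logging.getLogger(__name__).warning(
            "extracted tree depth %d is below the reporting bound %d",
            tree.max_depth(), config.min_questions,
        )
    return tree


def tree_expected_reward(
    tree: PolicyTree, net: DiscreteNet, config: PolicyConfig | None = None
) -> float:
    """Exact expected reward of a policy tree by enumeration over answer
    distributions."""
    config = config or PolicyConfig.from_net(net)
    oracle = NetOracle(net, config)

    def rec(node: PolicyTree, evidence: tuple) -> float:
        if node.kind == "send":
            return oracle.reward(evidence, node.label)
        dist = oracle.answer_dist(evidence, node.label)
        total = 0.0
        observed = dict(evidence)
        for a_idx, a in enumerate(net.states[node.label]):
            if dist[a_idx] <= 0.0:
                continue
            child_ev = tuple(sorted(observed.items() | {(node.label, a)}))
            total += dist[a_idx] * rec(node.children[a], child_ev)
        return float(total)

    return float(rec(tree, ()))


def evaluate_policy(
    tree: PolicyTree,
    net: DiscreteNet,
    n_rollouts: int = 2000,
    rng: np.random.Generator | None = None,
    config: PolicyConfig | None = None,
) -> dict[str, float]:
    """Monte-Carlo rollouts of simulated respondents through the tree
    (answers drawn from the network posterior at each internal node), plus
    the exact enumeration value."""
    config = config or PolicyConfig.from_net(net)
    rng = rng or np.random.default_rng(0)
    oracle = NetOracle(net, config)
    rewards = np.empty(n_rollouts)
    for r in range(n_rollouts):
        node = tree
        evidence: tuple = ()
        while node.kind == "ask":
            dist = oracle.answer_dist(evidence, node.label)
            a_idx = int(rng.choice(len(dist), p=dist))
            a = net.states[node.label][a_idx]
            evidence = tuple(sorted(dict(evidence).items() | {(node.label, a)}))
            node = node.children[a]
        rewards[r] = oracle.reward(evidence, node.label)
    return {
        "mean_reward": float(rewards.mean()),
        "mc_error": float(rewards.std(ddof=1) / np.sqrt(n_rollouts)),
        "exact": tree_expected_reward(tree, net, config),
        "n_rollouts": n_rollouts,
    }
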