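"""Profiling policy: legal moves, simulated interaction steps, MCTS,
self-play training, the exact dynamic-programming oracle, tree extraction
and evaluation."""

import itertools

import numpy as np
import pytest

from conftest import FRAMES, dominant_frame_net, matching_toy_net
from reguframe.bayesnet import infer_posterior
from reguframe.errors import ComplexityError, ContractError, InvalidConfigError
from reguframe.policy import (
    InteractionState,
    PolicyConfig,
    PolicyTree,
    brute_force_policy,
    evaluate_policy,
    extract_policy_tree,
    legal_moves,
    mcts_search,
    simulate_step,
    train_guidance,
    tree_expected_reward,
)


@pytest.fixture(scope="module")
def match_net():
    return matching_toy_net(n_traits=1, relevant=1)


@pytest.fixture(scope="module")
def match_cfg(match_net):
    return PolicyConfig.from_net(match_net, max_questions=2, min_questions=0)


class TestLegalMoves:
    def test_fresh_state_offers_all_queries_and_sends(self, match_net):
        cfg = PolicyConfig(askable=[f"t{i}" for i in range(7)], frames=list(FRAMES))
        moves = legal_moves(InteractionState(), match_net, cfg)
        assert len(moves) == 7 + 4

    def test_exhausted_budget_leaves_only_sends(self, match_net):
        cfg = PolicyConfig(askable=["a", "b"], frames=list(FRAMES), max_questions=1)
        state = InteractionState(evidence=(("a", "low"),), questions_asked=1)
        assert legal_moves(state, match_net, cfg) == [("send", f) for f in FRAMES]

    def test_all_observed_leaves_only_sends(self, match_net, match_cfg):
        state = InteractionState(evidence=(("trait0", "low"),), questions_asked=1)
        moves = legal_moves(state, match_net, match_cfg)
        assert moves == [("send", f) for f in FRAMES]

    def test_terminal_state_is_contract_error(self, match_net, match_cfg):
        with pytest.raises(ContractError):
            legal_moves(InteractionState(chosen_frame="gain"), match_net, match_cfg)


class TestSimulateStep:
    def test_send_on_empty_evidence_gives_prior_reward(self, match_net, match_cfg):
        rng = np.random.default_rng(0)
        state, reward = simulate_step(match_net, InteractionState(), ("send", "gain"), rng, match_cfg)
        assert state.terminal and state.chosen_frame == "gain"
        prior = infer_posterior(match_net, {"frame": "gain"}, "intention_post")
        assert reward == pytest.approx(float(prior[2]))

    def test_requery_is_contract_error(self, match_net, match_cfg):
        rng = np.random.default_rng(0)
        state, _ = simulate_step(match_net, InteractionState(), ("ask", "trait0"), rng, match_cfg)
        with pytest.raises(ContractError):
            simulate_step(match_net, state, ("ask", "trait0"), rng, match_cfg)

    def test_reward_matches_hand_enumeration(self, match_net, match_cfg):
        """On the matching net, P(high | trait, frame) is 0.8 on a match and
        0.2 otherwise, directly from the construction."""
        rng = np.random.default_rng(1)
        state = InteractionState(evidence=(("trait0", "medium"),), questions_asked=1)
        _, reward = simulate_step(match_net, state, ("send", "non_loss"), rng, match_cfg)
        assert reward == pytest.approx(0.8)  # trait index 1 matches frame index 1
        _, reward = simulate_step(match_net, state, ("send", "gain"), rng, match_cfg)
        assert reward == pytest.approx(0.2)

    def test_query_answers_follow_posterior(self, match_net, match_cfg):
        rng = np.random.default_rng(2)
        answers = [
            simulate_step(match_net, InteractionState(), ("ask", "trait0"), rng, match_cfg)[0]
            .evidence_dict()["trait0"]
            for _ in range(300)
        ]
        freq = np.array([answers.count(s) for s in ("low", "medium", "high")]) / 300
        np.testing.assert_allclose(freq, [1 / 3] * 3, atol=0.1)


class TestMcts:
    def test_single_legal_move_gets_probability_one(self, match_net):
        cfg = PolicyConfig(askable=["trait0"], frames=["gain"], max_questions=0)
        vis = mcts_search(InteractionState(), match_net, None, 50, 1.5,
                          np.random.default_rng(0), cfg)
        assert vis == {("send", "gain"): 1.0}

    def test_dominant_frame_attracts_most_visits(self):
        net = dominant_frame_net()
        cfg = PolicyConfig.from_net(net, max_questions=1, min_questions=0)
        vis = mcts_search(InteractionState(), net, None, 200, 1.5,
                          np.random.default_rng(0), cfg)
        assert max(vis, key=vis.get) == ("send", "gain")

    def test_visit_distribution_normalized(self, match_net, match_cfg):
        vis = mcts_search(InteractionState(), match_net, None, 300, 1.5,
                          np.random.default_rng(3), match_cfg)
        assert sum(vis.values()) == pytest.approx(1.0)

    def test_zero_simulations_rejected(self, match_net, match_cfg):
        with pytest.raises(InvalidConfigError):
            mcts_search(InteractionState(), match_net, None, 0, 1.5,
                        np.random.default_rng(0), match_cfg)


class TestBruteForce:
    def test_ask_then_match_beats_fixed_frame(self):
        """Matching net: asking the trait then matching yields 0.8; the best
        zero-question policy only 0.2 + 0.6 * P(trait matches) = analytically
        forced values."""
        net = matching_toy_net(n_traits=1, relevant=1)
        cfg = PolicyConfig.from_net(net, max_questions=1, min_questions=0)
        v1, tree1 = brute_force_policy(net, 1, cfg)
        v0, tree0 = brute_force_policy(net, 0, cfg)
        assert v1 == pytest.approx(0.8)
        assert tree1.kind == "ask" and tree1.label == "trait0"
        # no questions: every frame matches exactly one of three equiprobable
        # trait states (frame 'loss' matches none)
        assert v0 == pytest.approx(0.2 + (0.8 - 0.2) / 3)
        assert tree0.kind == "send"

    def test_budget_zero_returns_best_fixed_frame(self):
        net = dominant_frame_net()
        cfg = PolicyConfig.from_net(net, min_questions=0)
        val, tree = brute_force_policy(net, 0, cfg)
        assert tree.kind == "send" and tree.label == "gain"
        assert val == pytest.approx(0.9)

    def test_matches_exhaustive_policy_enumeration(self):
        """Budget-1 policies on a two-trait net can be enumerated outright:
        either send a fixed frame, or ask one trait and map each answer to a
        frame.  The DP optimum must equal the enumeration optimum."""
        net = matching_toy_net(n_traits=2, relevant=2, seed=4)
        cfg = PolicyConfig.from_net(net, max_questions=1, min_questions=0)
        from reguframe.policy import NetOracle

        oracle = NetOracle(net, cfg)
        best = max(oracle.reward((), f) for f in cfg.frames)
        for trait in cfg.askable:
            dist = oracle.answer_dist((), trait)
            for mapping in itertools.product(cfg.frames, repeat=3):
                val = sum(
                    dist[i] * oracle.reward(((trait, s),), mapping[i])
                    for i, s in enumerate(net.states[trait])
                )
                best = max(best, val)
        dp_val, _ = brute_force_policy(net, 1, cfg)
        assert dp_val == pytest.approx(best, abs=1e-12)

    def test_monotone_in_question_budget(self):
        net = matching_toy_net(n_traits=2, relevant=2, seed=1)
        cfg = PolicyConfig.from_net(net, min_questions=0)
        vals = [brute_force_policy(net, b, cfg)[0] for b in (0, 1, 2)]
        assert vals[0] <= vals[1] + 1e-12 <= vals[2] + 2e-12

    def test_state_space_guard(self):
        net = matching_toy_net(n_traits=2, relevant=1)
        cfg = PolicyConfig.from_net(net, min_questions=0)
        with pytest.raises(ComplexityError):
            brute_force_policy(net, 2, cfg, max_states=3)


@pytest.fixture(scope="module")
def trained_dominant():
    net = dominant_frame_net()
    cfg = PolicyConfig.from_net(
        net, max_questions=1, min_questions=0,
        episodes=120, n_sim_train=60, train_every=40,
    )
    guidance, log = train_guidance(net, cfg, seed=0)
    return net, cfg, guidance, log


class TestTrainingAndExtraction:
    def test_heldout_loss_decreases(self, trained_dominant):
        _, _, _, log = trained_dominant
        assert log[-1]["last_holdout_policy_ce"] < log[0]["first_holdout_policy_ce"]

    def test_training_is_deterministic(self):
        net = dominant_frame_net()
        cfg = PolicyConfig.from_net(net, max_questions=1, min_questions=0,
                                    episodes=30, n_sim_train=40, train_every=30)
        _, log1 = train_guidance(net, cfg, seed=7)
        _, log2 = train_guidance(net, cfg, seed=7)
        assert log1 == log2

    def test_dominant_net_extracts_single_leaf_equal_to_oracle(self, trained_dominant):
        net, cfg, guidance, _ = trained_dominant
        tree = extract_policy_tree(guidance, net, cfg, seed=1)
        assert tree.kind == "send" and tree.label == "gain"
        opt, _ = brute_force_policy(net, cfg.max_questions, cfg)
        assert tree_expected_reward(tree, net, cfg) == pytest.approx(opt, abs=1e-12)

    def test_value_head_learns_terminal_adjacent_values(self, trained_dominant):
        net, cfg, guidance, _ = trained_dominant
        state = InteractionState()
        _, value = guidance.evaluate(state, legal_moves(state, net, cfg))
        assert value == pytest.approx(0.9, abs=0.05)

    def test_matching_net_extracts_ask_then_match(self, match_net, match_cfg):
        tree = extract_policy_tree(None, match_net, match_cfg, seed=0)
        assert tree.kind == "ask" and tree.label == "trait0"
        assert tree_expected_reward(tree, match_net, match_cfg) == pytest.approx(0.8)

    def test_no_variable_repeats_on_any_path(self):
        net = matching_toy_net(n_traits=3, relevant=2, seed=2)
        cfg = PolicyConfig.from_net(net, max_questions=3, min_questions=0,
                                    n_sim_extract=300)
        tree = extract_policy_tree(None, net, cfg, seed=0)
        tree.validate(cfg.max_questions)  # raises on a repeat or budget breach


class TestPolicyTree:
    def test_json_round_trip(self, match_net, match_cfg):
        _, tree = brute_force_policy(match_net, 1, match_cfg)
        again = PolicyTree.from_json(tree.to_json())
        assert again.to_dict() == tree.to_dict()

    def test_single_leaf_evaluation_matches_prior(self, match_net, match_cfg):
        tree = PolicyTree("send", "gain")
        res = evaluate_policy(tree, match_net, 500, np.random.default_rng(0), match_cfg)
        prior = infer_posterior(match_net, {"frame": "gain"}, "intention_post")
        assert res["exact"] == pytest.approx(float(prior[2]))
        assert res["mean_reward"] == pytest.approx(res["exact"], abs=1e-9)

    def test_mc_estimate_within_two_standard_errors_of_exact(self, match_net, match_cfg):
        _, tree = brute_force_policy(match_net, 1, match_cfg)
        res = evaluate_policy(tree, match_net, 4000, np.random.default_rng(1), match_cfg)
        assert abs(res["mean_reward"] - res["exact"]) <= max(2 * res["mc_error"], 1e-9)

    def test_optimal_tree_beats_every_fixed_frame(self, match_net, match_cfg):
        from reguframe.policy import NetOracle

        _, tree = brute_force_policy(match_net, 1, match_cfg)
        opt = tree_expected_reward(tree, match_net, match_cfg)
        oracle = NetOracle(match_net, match_cfg)
        assert opt >= max(oracle.reward((), f) for f in match_cfg.frames)

    def test_dot_export_single_leaf(self, tmp_path):
        from reguframe.serialize import export_dot, tree_to_dot

        tree = PolicyTree("send", "gain")
        text = tree_to_dot(tree)
        assert text.count("->") == 0 and "send gain" in text
        export_dot(tree, tmp_path / "tree.dot")
        assert (tmp_path / "tree.dot").exists()

    def test_guidance_checkpoint_round_trip(self, tmp_path, match_net, match_cfg):
        from reguframe.guidance import GuidanceFunction

        g = GuidanceFunction(
            match_cfg.askable,
            {v: match_net.states[v] for v in match_cfg.askable},
            match_cfg.frames, match_cfg.max_questions, seed=3,
        )
        state = InteractionState()
        moves = legal_moves(state, match_net, match_cfg)
        before = g.evaluate(state, moves)
        g.save(tmp_path / "g.npz")
        loaded = GuidanceFunction.load(tmp_path / "g.npz")
        after = loaded.evaluate(state, moves)
        assert after[1] == pytest.approx(before[1])
        for m in moves:
            assert after[0][m] == pytest.approx(before[0][m])
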