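"""End-to-end pipeline: simulate -> fit SEM -> elicit network -> train
policy -> extract tree -> evaluate, with a run manifest, per-stage derived
seeds and output-existence skipping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import reguframe
from reguframe import cohort as cohort_mod
from reguframe import sem as sem_mod
from reguframe.elicit import DEFAULT_CANDIDATES, SearchConfig, backbone_from_sem, structure_search
from reguframe.errors import ReguframeError
from reguframe.evaluation import multiclass_auc, loo_protocol
from reguframe.bayesnet import DiscreteNet
from reguframe.policy import PolicyConfig, PolicyTree, evaluate_policy, extract_policy_tree, train_guidance
from reguframe.guidance import GuidanceFunction
from reguframe.serialize import export_dot

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit_sem", "elicit", "train_policy", "extract_tree", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2^31) derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    out_dir: Path = Path("results/pipeline")
    seed: int = 0
    n_participants: int = 564
    generator: dict = field(default_factory=dict)
    search: dict = field(default_factory=dict)
    policy: dict = field(default_factory=dict)
    candidates: list[str] | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        d["out_dir"] = Path(d.get("out_dir", "results/pipeline"))
        return cls(**d)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute all stages in order, skipping stages whose outputs already
    exist unless ``force``.  Returns the manifest (also written to
    ``manifest.json``); a stage failure is recorded in the manifest and
    re-raised."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": reguframe.__version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    paths = {
        "cohort": out / "cohort.csv",
        "sem": out / "sem_fits.json",
        "net": out / "net.json",
        "net_dot": out / "net.dot",
        "guidance": out / "guidance.npz",
        "training_log": out / "training_log.json",
        "tree": out / "tree.json",
        "tree_dot": out / "tree.dot",
        "evaluation": out / "evaluation.json",
    }

    def done(stage: str, *outputs: Path):
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {str(p): _hash_file(p) for p in outputs},
        }

    def skip(stage: str):
        logger.info("stage %s: outputs exist, skipping (use --force to rerun)", stage)
        manifest["stages"][stage] = {"status": "skipped"}

    try:
        # -- simulate ---------------------------------------------------
        if paths["cohort"].exists() and not force:
            skip("simulate")
        else:
            gen = cohort_mod.config_from_dict(config.generator) if config.generator else cohort_mod.GeneratorConfig()
            gen = dataclasses.replace(
                gen, n_participants=config.n_participants,
                seed=stage_seed(config.seed, "simulate"),
            )
            table = cohort_mod.simulate_cohort(gen)
            cohort_mod.write_cohort(
                table, paths["cohort"],
                metadata={"seed": gen.seed, "config": cohort_mod.config_to_dict(gen)},
            )
            done("simulate", paths["cohort"])
        table = cohort_mod.read_cohort(paths["cohort"])

        # -- SEM --------------------------------------------------------
        if paths["sem"].exists() and not force:
            skip("fit_sem")
        else:
            spec = sem_mod.build_theory_model()
            alt1, alt2 = sem_mod.build_alternative_models()
            fits = [sem_mod.fit_sem(s, table) for s in (spec, alt1, alt2)]
            comparison = sem_mod.compare_models(fits)
            indirect = {
                name: sem_mod.indirect_effect(fits[0], chain)
                for name, chain in (
                    ("prevention->calm->involvement", ["prevention", "calm", "involvement"]),
                    ("promotion->calm->involvement", ["promotion", "calm", "involvement"]),
                    ("prevention->hope->involvement", ["prevention", "hope", "involvement"]),
                    ("promotion->hope->involvement", ["promotion", "hope", "involvement"]),
                )
            }
            paths["sem"].write_text(json.dumps({
                "fits": [
                    {"model": f.spec.name, "chi_square": f.chi_square, "df": f.df,
                     "converged": f.converged, "indices": f.indices,
                     "estimates": f.estimates} for f in fits
                ],
                "comparison": comparison.to_dict(orient="records"),
                "indirect_effects": indirect,
            }, indent=2))
            if not all(f.converged for f in fits):
                logger.warning("at least one SEM fit did not converge")
            done("fit_sem", paths["sem"])

        # -- elicit -----------------------------------------------------
        if paths["net"].exists() and not force:
            skip("elicit")
        else:
            spec = sem_mod.build_theory_model()
            backbone = backbone_from_sem(spec)
            sc = SearchConfig(seed=stage_seed(config.seed, "elicit"), **config.search)
            candidates = config.candidates if config.candidates is not None else list(DEFAULT_CANDIDATES)
            result = structure_search(backbone, candidates, table, sc)
            result.net.save(paths["net"])
            export_dot(result.net, paths["net_dot"])
            (out / "search_trace.json").write_text(json.dumps({
                "backbone_score": result.backbone_score,
                "final_score": result.final_score,
                "trace": [
                    {**t, "edge": list(t["edge"])} for t in result.trace
                ],
            }, indent=2))
            done("elicit", paths["net"], paths["net_dot"])
        net = DiscreteNet.load(paths["net"])

        # -- train policy -------------------------------------------------
        if paths["guidance"].exists() and not force:
            skip("train_policy")
        else:
            pc = PolicyConfig.from_net(net, **config.policy)
            guidance, tlog = train_guidance(net, pc, seed=stage_seed(config.seed, "train_policy"))
            guidance.save(paths["guidance"])
            paths["training_log"].write_text(json.dumps(tlog, indent=2))
            done("train_policy", paths["training_log"])

        # -- extract tree -------------------------------------------------
        if paths["tree"].exists() and not force:
            skip("extract_tree")
        else:
            pc = PolicyConfig.from_net(net, **config.policy)
            guidance = GuidanceFunction.load(paths["guidance"])
            tree = extract_policy_tree(guidance, net, pc,
                                       seed=stage_seed(config.seed, "extract_tree"))
            tree.save(paths["tree"])
            export_dot(tree, paths["tree_dot"])
            done("extract_tree", paths["tree"], paths["tree_dot"])

        # -- evaluate -----------------------------------------------------
        if paths["evaluation"].exists() and not force:
            skip("evaluate")
        else:
            pc = PolicyConfig.from_net(net, **config.policy)
            tree = PolicyTree.load(paths["tree"])
            rng = np.random.default_rng(stage_seed(config.seed, "evaluate"))
            policy_eval = evaluate_policy(tree, net, n_rollouts=2000, rng=rng, config=pc)
            dag = {v: list(net.parents[v]) for v in net.nodes}
            loo_auc = multiclass_auc(loo_protocol(dag, table, net.target))
            paths["evaluation"].write_text(json.dumps({
                "policy": policy_eval,
                "tree_depths": tree.depth_profile(),
                "loo_multiclass_auc": loo_auc,
            }, indent=2))
            done("evaluate", paths["evaluation"])
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
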