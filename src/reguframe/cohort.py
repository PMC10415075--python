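"""Synthetic participant cohorts for message-framing intervention studies.

The generator emulates the measurement and structural properties the
downstream analyses assume: multi-item 7-point Likert scales with target
Cronbach alphas, a standardized linear structural system over the latent
traits (regulatory foci, TPB antecedents, message-induced emotions,
involvement, deep processing, pre/post intention), balanced randomization
over four message frames (gain, non-loss, non-gain, loss) and configurable
frame main effects and frame x focus "matching" interactions on the
emotions.

Every latent is standardized (variance one), so configured path
coefficients are the standardized generating truths.  Frame effects are
centered across the four balanced arms, which keeps the configured paths
exact in the presence of matching interactions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from reguframe.errors import InvalidConfigError, SchemaError

logger = logging.getLogger(__name__)

FRAMES = ("gain", "non_loss", "non_gain", "loss")

#: scale name -> (number of items, Cronbach alpha); reliabilities follow the
#: questionnaire the cohort emulates (foci 6 items each; emotions,
#: involvement and intention 3 items; deep processing and PBC 5 items).
DEFAULT_SCALES: dict[str, tuple[int, float]] = {
    "prevention": (6, 0.83),
    "promotion": (6, 0.82),
    "attitude_cog": (3, 0.87),
    "attitude_aff": (3, 0.87),
    "norm": (3, 0.83),
    "pbc": (5, 0.90),
    "intention_pre": (3, 0.97),
    "anger": (3, 0.91),
    "anxiety": (3, 0.80),
    "fear": (3, 0.82),
    "calm": (3, 0.86),
    "hope": (3, 0.86),
    "involvement": (3, 0.88),
    "deep_processing": (5, 0.88),
    "intention_post": (3, 0.96),
}

EXOGENOUS = ("promotion", "prevention", "attitude_cog", "attitude_aff", "norm", "pbc")
EMOTIONS = ("anger", "anxiety", "fear", "calm", "hope")

#: standardized structural paths of the theory model (foci -> emotions,
#: emotions -> involvement, the ELM chain, and the pre/post intention slice).
DEFAULT_STRUCTURAL_PATHS: dict[tuple[str, str], float] = {
    ("promotion", "calm"): 0.35,
    ("promotion", "hope"): 0.51,
    ("prevention", "calm"): -0.23,
    ("prevention", "hope"): -0.13,
    ("calm", "involvement"): -0.33,
    ("hope", "involvement"): 0.87,
    ("anger", "involvement"): -0.55,
    ("involvement", "deep_processing"): 0.50,
    ("deep_processing", "intention_post"): 0.40,
    ("intention_pre", "intention_post"): 0.40,
}

DEFAULT_TPB_EFFECTS: dict[str, float] = {
    "attitude_cog": 0.25,
    "attitude_aff": 0.25,
    "norm": 0.15,
    "pbc": 0.30,
}

# Negative-valence frames raise anger/anxiety/fear a little; matching frames
# raise hope for the matching focus.  Raw values; centering happens inside
# the generator.
DEFAULT_FRAME_EFFECTS: dict[str, tuple[float, float, float, float]] = {
    "anger": (0.0, 0.0, 0.15, 0.15),
    "anxiety": (0.0, 0.0, 0.15, 0.15),
    "fear": (0.0, 0.0, 0.15, 0.15),
}

DEFAULT_FRAME_FOCUS_INTERACTIONS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "hope": {
        "promotion": (0.2, 0.0, 0.0, 0.0),
        "prevention": (0.0, 0.2, 0.0, 0.0),
    },
}

# The printed involvement paths (calm -0.33, hope 0.87, anger -0.55) are
# only jointly feasible under unit variances when calm and hope correlate
# well beyond their focus-induced covariance; a residual covariance of 0.20
# (total latent r ~ 0.41) keeps the involvement R^2 at ~0.93.
DEFAULT_EMOTION_RESIDUAL_COV: dict[tuple[str, str], float] = {
    ("calm", "hope"): 0.20,
}

REQUIRED_COLUMNS = ("participant_id", "cohort", "frame", "age", "gender", "education")


def loading_from_alpha(alpha: float, k: int) -> float:
    """Common standardized loading of ``k`` parallel items with reliability
    ``alpha``.

    For parallel items with inter-item correlation r = lambda^2 the
    Spearman-Brown/Cronbach identity is alpha = k r / (1 + (k-1) r); this
    inverts it: r = alpha / (k - alpha (k-1)), lambda = sqrt(r).
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidConfigError(f"alpha must lie in (0, 1), got {alpha}")
    if k < 2:
        raise InvalidConfigError(f"need at least 2 items per scale, got {k}")
    r = alpha / (k - alpha * (k - 1))
    return math.sqrt(r)


@dataclass
class GeneratorConfig:
    """Study conditions for :func:`simulate_cohort`.

    All paths are standardized; every latent has variance one.  Scales are
    given either a target Cronbach alpha (converted to a common loading via
    :func:`loading_from_alpha`) or an explicit loading in ``loadings``.
    """

    n_participants: int = 564
    seed: int = 0
    scales: dict[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALES)
    )
    loadings: dict[str, float] = field(default_factory=dict)
    structural_paths: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURAL_PATHS)
    )
    tpb_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TPB_EFFECTS)
    )
    foci_correlation: float = 0.0
    frame_effects: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FRAME_EFFECTS)
    )
    frame_focus_interactions: dict[str, dict[str, tuple[float, float, float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_FRAME_FOCUS_INTERACTIONS.items()
        }
    )
    emotion_residual_cov: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EMOTION_RESIDUAL_COV)
    )
    age_mean: float = 30.0
    age_sd: float = 9.44
    age_range: tuple[int, int] = (18, 65)
    gender_probs: dict[str, float] = field(
        default_factory=lambda: {"female": 0.5, "male": 0.5}
    )
    education_probs: dict[str, float] = field(
        default_factory=lambda: {"primary": 0.1, "secondary": 0.5, "tertiary": 0.4}
    )
    likert_bounds: tuple[int, int] = (1, 7)
    likert_center: float = 4.0
    likert_scale: float = 1.5
    cohort_label: str = "healthy"

    # ------------------------------------------------------------------
    def scale_loading(self, scale: str) -> float:
        if scale in self.loadings:
            lam = self.loadings[scale]
            if not 0.0 < lam < 1.0:
                raise InvalidConfigError(f"loading for {scale} must lie in (0,1)")
            return lam
        k, alpha = self.scales[scale]
        return loading_from_alpha(alpha, k)

    def all_edges(self) -> dict[tuple[str, str], float]:
        """Structural paths plus TPB -> pre-intention paths, as one map."""
        edges = dict(self.structural_paths)
        for var, b in self.tpb_effects.items():
            edges[(var, "intention_pre")] = b
        return edges

    def endogenous_order(self) -> list[str]:
        """Topological order of endogenous latents under ``all_edges``."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.scales)
        g.add_edges_from(self.all_edges())
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidConfigError("structural paths contain a cycle")
        order = [v for v in nx.topological_sort(g) if v not in EXOGENOUS]
        return order

    def validate(self) -> None:
        for (a, b), v in self.all_edges().items():
            if abs(v) >= 1.0:
                raise InvalidConfigError(f"|path {a}->{b}| = {abs(v)} must be < 1")
            for node in (a, b):
                if node not in self.scales:
                    raise InvalidConfigError(f"path references unknown scale {node!r}")
        for name, (k, alpha) in self.scales.items():
            if k < 2:
                raise InvalidConfigError(f"scale {name} has {k} < 2 items")
            if not 0.0 < alpha < 1.0:
                raise InvalidConfigError(f"scale {name} alpha {alpha} outside (0,1)")
        for probs, what in ((self.gender_probs, "gender"), (self.education_probs, "education")):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise InvalidConfigError(f"{what} probabilities must sum to 1")
        if not -1.0 < self.foci_correlation < 1.0:
            raise InvalidConfigError("foci correlation must lie in (-1, 1)")
        if self.n_participants < 1:
            raise InvalidConfigError("n_participants must be positive")
        # raises if any implied residual variance is non-positive
        self.implied_latent_cov()

    # ------------------------------------------------------------------
    def _centered_frame_terms(self, emotion: str):
        """Centered frame main effects and interaction coefficients.

        Returns (main: (4,), inter: dict focus -> (4,)); both centered to
        zero mean over the balanced arms so they are orthogonal to the
        latent traits.
        """
        main = np.asarray(self.frame_effects.get(emotion, (0.0,) * 4), dtype=float)
        main = main - main.mean()
        inter = {}
        for focus, row in self.frame_focus_interactions.get(emotion, {}).items():
            r = np.asarray(row, dtype=float)
            inter[focus] = r - r.mean()
        return main, inter

    def implied_latent_cov(self) -> pd.DataFrame:
        """Model-implied covariance matrix of the latent scores.

        Propagates covariances through the standardized linear system in
        topological order.  Residual variances are set so every latent has
        unit variance; an implied R^2 >= 1 raises ``InvalidConfigError``.
        Frame-effect contributions are orthogonal to the traits (they are
        centered over balanced arms) but covary between emotions that share
        frame coefficients.
        """
        names = list(self.scales)
        idx = {v: i for i, v in enumerate(names)}
        cov = np.zeros((len(names), len(names)))
        for v in EXOGENOUS:
            cov[idx[v], idx[v]] = 1.0
        c = self.foci_correlation
        cov[idx["promotion"], idx["prevention"]] = c
        cov[idx["prevention"], idx["promotion"]] = c

        edges = self.all_edges()
        parents: dict[str, dict[str, float]] = {}
        for (a, b), v in edges.items():
            parents.setdefault(b, {})[a] = v

        resid_cov = {}
        for (a, b), v in self.emotion_residual_cov.items():
            resid_cov[frozenset((a, b))] = v

        frame_terms = {e: self._centered_frame_terms(e) for e in EMOTIONS}

        def frame_cov(e1: str, e2: str) -> float:
            if e1 not in frame_terms or e2 not in frame_terms:
                return 0.0
            m1, i1 = frame_terms[e1]
            m2, i2 = frame_terms[e2]
            total = float(np.mean(m1 * m2))
            for focus in set(i1) & set(i2):
                total += float(np.mean(i1[focus] * i2[focus]))
            return total

        order = self.endogenous_order()
        done = list(EXOGENOUS)
        for y in order:
            py = parents.get(y, {})
            iy = idx[y]
            # covariance with everything generated so far
            for z in done:
                s = sum(b * cov[idx[x], idx[z]] for x, b in py.items())
                s += frame_cov(y, z)
                s += resid_cov.get(frozenset((y, z)), 0.0)
                cov[iy, idx[z]] = cov[idx[z], iy] = s
            explained = sum(
                b1 * b2 * cov[idx[x1], idx[x2]]
                for x1, b1 in py.items()
                for x2, b2 in py.items()
            )
            explained += frame_cov(y, y)
            # residual covariance with other latents' residuals does not add
            # to the variance; only the own residual does.
            resid = 1.0 - explained
            if resid <= 1e-9:
                raise InvalidConfigError(
                    f"implied R^2 for {y} is {explained:.3f} >= 1; "
                    "standardization leaves no residual variance"
                )
            cov[iy, iy] = 1.0
            done.append(y)
        return pd.DataFrame(cov, index=names, columns=names)


def _frame_assignment(n: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced randomization: arm sizes differ by at most one."""
    reps = np.tile(np.arange(4), n // 4 + 1)[:n]
    return rng.permutation(reps)


def simulate_cohort(config: GeneratorConfig, return_latents: bool = False):
    """Generate a participant table under ``config``.

    Latents are drawn as a standardized linear system; indicators are
    lambda * latent + sqrt(1 - lambda^2) * noise, mapped affinely onto the
    Likert range (center + scale * score), clamped and rounded.  Composites
    are item means.  Deterministic under a fixed seed.

    With ``return_latents`` the (normally hidden) latent score matrix is
    returned alongside the table, which lets tests check the structural
    system directly, before Likert discretization.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    names = list(config.scales)

    scores: dict[str, np.ndarray] = {}
    # exogenous traits, foci possibly correlated
    c = config.foci_correlation
    chol = np.linalg.cholesky(np.array([[1.0, c], [c, 1.0]]))
    z = rng.standard_normal((n, 2)) @ chol.T
    scores["promotion"], scores["prevention"] = z[:, 0], z[:, 1]
    for v in EXOGENOUS[2:]:
        scores[v] = rng.standard_normal(n)

    frame_idx = _frame_assignment(n, rng)

    edges = config.all_edges()
    parents: dict[str, dict[str, float]] = {}
    for (a, b), v in edges.items():
        parents.setdefault(b, {})[a] = v

    order = config.endogenous_order()
    # joint residual draw honouring configured residual covariances
    implied = config.implied_latent_cov()
    resid_var = {}
    for y in order:
        py = parents.get(y, {})
        explained = sum(
            b1 * b2 * implied.loc[x1, x2]
            for x1, b1 in py.items()
            for x2, b2 in py.items()
        )
        m, inter = config._centered_frame_terms(y) if y in EMOTIONS else (np.zeros(4), {})
        explained += float(np.mean(m**2)) + sum(float(np.mean(r**2)) for r in inter.values())
        resid_var[y] = 1.0 - explained
    rc = np.diag([resid_var[y] for y in order])
    pos = {y: i for i, y in enumerate(order)}
    for (a, b), v in config.emotion_residual_cov.items():
        rc[pos[a], pos[b]] = rc[pos[b], pos[a]] = v
    try:
        resid_chol = np.linalg.cholesky(rc)
    except np.linalg.LinAlgError as exc:
        raise InvalidConfigError("residual covariance matrix not positive definite") from exc
    resid = rng.standard_normal((n, len(order))) @ resid_chol.T

    for j, y in enumerate(order):
        val = resid[:, j].copy()
        for x, b in parents.get(y, {}).items():
            val += b * scores[x]
        if y in EMOTIONS:
            main, inter = config._centered_frame_terms(y)
            val += main[frame_idx]
            for focus, row in inter.items():
                val += row[frame_idx] * scores[focus]
        scores[y] = val

    lo, hi = config.likert_bounds
    data: dict[str, np.ndarray] = {}
    data["participant_id"] = np.arange(1, n + 1)
    data["cohort"] = np.full(n, config.cohort_label, dtype=object)
    data["frame"] = np.array([FRAMES[i] for i in frame_idx], dtype=object)
    age = rng.normal(config.age_mean, config.age_sd, n)
    data["age"] = np.clip(np.rint(age), *config.age_range).astype(int)
    data["gender"] = rng.choice(
        list(config.gender_probs), n, p=list(config.gender_probs.values())
    )
    data["education"] = rng.choice(
        list(config.education_probs), n, p=list(config.education_probs.values())
    )

    for scale in names:
        k, _ = config.scales[scale]
        lam = config.scale_loading(scale)
        noise = rng.standard_normal((n, k))
        items = lam * scores[scale][:, None] + math.sqrt(1.0 - lam * lam) * noise
        likert = np.clip(
            np.rint(config.likert_center + config.likert_scale * items), lo, hi
        ).astype(int)
        for i in range(k):
            data[f"{scale}_{i + 1}"] = likert[:, i]
        data[scale] = likert.mean(axis=1)

    table = pd.DataFrame(data)
    if return_latents:
        return table, pd.DataFrame({v: scores[v] for v in names})
    return table


def shift_cohort(
    table: pd.DataFrame,
    shifts: dict[str, float] | None = None,
    new_label: str = "patients",
    n_subsample: int | None = None,
    seed: int = 0,
    scales: dict[str, tuple[int, float]] | None = None,
) -> pd.DataFrame:
    """Distributionally shifted copy of a cohort (e.g. an older patient
    sample with lower perceived control), used for cohort-transfer tests.

    ``shifts`` maps ``age`` or a scale name to a mean offset; scale offsets
    are applied on the Likert metric to every item of the scale, clamped
    back to the item range, and the composite is recomputed.
    """
    shifts = shifts or {}
    scales = scales or DEFAULT_SCALES
    out = table.copy()
    rng = np.random.default_rng(seed)
    if n_subsample is not None:
        if n_subsample > len(out):
            raise InvalidConfigError("subsample larger than the table")
        out = out.iloc[np.sort(rng.choice(len(out), n_subsample, replace=False))]
        out = out.reset_index(drop=True)
    for var, off in shifts.items():
        if var == "age":
            out["age"] = (out["age"] + off).round().astype(int)
            continue
        if var not in scales:
            raise SchemaError(f"unknown variable in shifts: {var!r}")
        k, _ = scales[var]
        cols = [f"{var}_{i + 1}" for i in range(k)]
        missing = [c for c in cols if c not in out.columns]
        if missing:
            raise SchemaError(f"missing item columns: {missing}")
        shifted = out[cols].to_numpy(dtype=float) + off
        clamped = np.clip(np.rint(shifted), 1, 7).astype(int)
        if (np.rint(shifted) != clamped).any():
            logger.warning("shift on %s clamped some items to the Likert range", var)
        out[cols] = clamped
        out[var] = clamped.mean(axis=1)
    out["cohort"] = new_label
    return out


def write_cohort(table: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a cohort as UTF-8 CSV, with an optional JSON metadata sidecar
    (seed, config hash...) at ``<path>.meta.json``."""
    path = Path(path)
    table.to_csv(path, index=False)
    if metadata is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(metadata, indent=2, default=str))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, validating the required schema."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed CSV at {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing required columns: {missing}")
    bad = set(table["frame"].dropna()) - set(FRAMES)
    if bad:
        raise SchemaError(f"unknown frame values: {sorted(bad)}")
    return table


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON/YAML-serializable form of a config (tuple keys joined by '->')."""
    d = dataclasses.asdict(config)
    d["structural_paths"] = {f"{a}->{b}": v for (a, b), v in config.structural_paths.items()}
    d["emotion_residual_cov"] = {
        f"{a}->{b}": v for (a, b), v in config.emotion_residual_cov.items()
    }
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    for key in ("structural_paths", "emotion_residual_cov"):
        if key in d:
            d[key] = {tuple(k.split("->")): v for k, v in d[key].items()}
    if "scales" in d:
        d["scales"] = {k: tuple(v) for k, v in d["scales"].items()}
    for key in ("age_range", "likert_bounds"):
        if key in d:
            d[key] = tuple(d[key])
    if "frame_effects" in d:
        d["frame_effects"] = {k: tuple(v) for k, v in d["frame_effects"].items()}
    if "frame_focus_interactions" in d:
        d["frame_focus_interactions"] = {
            e: {f: tuple(r) for f, r in m.items()}
            for e, m in d["frame_focus_interactions"].items()
        }
    return GeneratorConfig(**d)
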