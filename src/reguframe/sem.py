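"""Structural equation modelling: specification, maximum-likelihood fitting,
fit indices, model comparison and product-of-paths mediation.

The fitter minimizes the ML discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over the model-implied covariance Sigma(theta), built from a RAM
parameterization: a directed-coefficient matrix A (factor loadings and
structural paths) and a symmetric matrix Psi (variances, residual variances
and free covariances), with

    Sigma = G Psi G',   G = selector of observed rows of (I - A)^-1.

Latent scales are identified by fixing each latent's first loading to one;
the standardized solution is derived post hoc from the model-implied
variances.  chi^2 = (n - 1) F_min.  Gradients are analytic (trace
identities on the RAM derivatives), which keeps a ~75-parameter fit well
under a second.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from reguframe.errors import DataError, InvalidConfigError, SchemaError

#: indicator counts used by the theory model (matches the questionnaire:
#: 6 items per focus, 3 per emotion, 3 involvement, 5 deep processing,
#: 3 intention pre/post).
THEORY_ITEM_COUNTS = {
    "prevention": 6,
    "promotion": 6,
    "anger": 3,
    "calm": 3,
    "hope": 3,
    "involvement": 3,
    "deep_processing": 5,
    "intention_pre": 3,
    "intention_post": 3,
}


# ----------------------------------------------------------------------
# specification
# ----------------------------------------------------------------------
@dataclass
class SemSpec:
    """Measurement + structural model definition.

    ``measurement`` maps each latent to its ordered indicator names;
    ``structural`` lists directed latent-to-latent edges; ``covariances``
    lists free covariances (between exogenous latents, or between the
    residuals of endogenous latents).
    """

    measurement: dict[str, list[str]]
    structural: list[tuple[str, str]]
    covariances: list[tuple[str, str]] = field(default_factory=list)
    name: str = "model"
    saturated: bool = False

    def latents(self) -> list[str]:
        return list(self.measurement)

    def indicators(self) -> list[str]:
        return [ind for inds in self.measurement.values() for ind in inds]

    def validate(self) -> None:
        g = nx.DiGraph(self.structural)
        g.add_nodes_from(self.measurement)
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidConfigError("structural graph has a cycle")
        seen: set[str] = set()
        for lat, inds in self.measurement.items():
            if len(inds) < 2:
                raise InvalidConfigError(f"latent {lat} has fewer than 2 indicators")
            dup = seen & set(inds)
            if dup:
                raise InvalidConfigError(f"indicators assigned twice: {sorted(dup)}")
            seen |= set(inds)
        for a, b in self.structural + self.covariances:
            for v in (a, b):
                if v not in self.measurement:
                    raise InvalidConfigError(f"edge references unknown latent {v!r}")

    def exogenous(self) -> set[str]:
        children = {b for _, b in self.structural}
        return set(self.measurement) - children

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "measurement": self.measurement,
                "structural": [list(e) for e in self.structural],
                "covariances": [list(e) for e in self.covariances],
                "saturated": self.saturated,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SemSpec":
        d = json.loads(text)
        return cls(
            measurement=d["measurement"],
            structural=[tuple(e) for e in d["structural"]],
            covariances=[tuple(e) for e in d.get("covariances", [])],
            name=d.get("name", "model"),
            saturated=d.get("saturated", False),
        )


def _items(latent: str, counts: dict[str, int]) -> list[str]:
    return [f"{latent}_{i + 1}" for i in range(counts[latent])]


def build_theory_model(item_counts: dict[str, int] | None = None) -> SemSpec:
    """The theory-driven model: foci -> emotions -> involvement -> deep
    processing -> post intention, with pre-intervention intention as a
    second predictor of post intention.

    Foci covary; emotion residuals covary (parallel mediators sharing
    unmodelled message-response variance).
    """
    counts = item_counts or THEORY_ITEM_COUNTS
    latents = [
        "prevention",
        "promotion",
        "anger",
        "calm",
        "hope",
        "involvement",
        "deep_processing",
        "intention_pre",
        "intention_post",
    ]
    measurement = {lat: _items(lat, counts) for lat in latents}
    structural = [
        ("promotion", "anger"),
        ("promotion", "calm"),
        ("promotion", "hope"),
        ("prevention", "anger"),
        ("prevention", "calm"),
        ("prevention", "hope"),
        ("anger", "involvement"),
        ("calm", "involvement"),
        ("hope", "involvement"),
        ("involvement", "deep_processing"),
        ("deep_processing", "intention_post"),
        ("intention_pre", "intention_post"),
    ]
    covariances = [
        ("prevention", "promotion"),
        ("prevention", "intention_pre"),
        ("promotion", "intention_pre"),
        ("anger", "calm"),
        ("anger", "hope"),
        ("calm", "hope"),
    ]
    spec = SemSpec(measurement, structural, covariances, name="theory")
    spec.validate()
    return spec


def build_alternative_models(item_counts: dict[str, int] | None = None) -> tuple[SemSpec, SemSpec]:
    """Two comparison models: (1) involvement additionally affects post
    intention directly; (2) pre-intervention intention removed."""
    base = build_theory_model(item_counts)
    alt1 = SemSpec(
        measurement=dict(base.measurement),
        structural=base.structural + [("involvement", "intention_post")],
        covariances=list(base.covariances),
        name="alt1_direct_involvement",
    )
    meas2 = {k: v for k, v in base.measurement.items() if k != "intention_pre"}
    alt2 = SemSpec(
        measurement=meas2,
        structural=[e for e in base.structural if "intention_pre" not in e],
        covariances=[e for e in base.covariances if "intention_pre" not in e],
        name="alt2_no_pre_intention",
    )
    alt1.validate()
    alt2.validate()
    return alt1, alt2


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
@dataclass
class SemFit:
    """Result of a maximum-likelihood fit.

    ``estimates`` holds the standardized solution keyed ``"a->b"`` for
    loadings/paths and ``"a~~b"`` for covariances; ``estimates_unstd`` the
    raw solution on the identification metric.  ``indices`` carries RMSEA,
    CFI, TLI (raw and truncated) and SRMR.
    """

    spec: SemSpec
    estimates: dict[str, float]
    estimates_unstd: dict[str, float]
    se: dict[str, float]
    chi_square: float
    df: int
    n: int
    baseline_chi_square: float
    baseline_df: int
    indices: dict[str, float]
    converged: bool
    n_free: int
    latent_sd: dict[str, float]
    data_hash: str
    param_names: list[str] = field(default_factory=list)
    param_cov_std: np.ndarray | None = None

    def path(self, a: str, b: str) -> float:
        return self.estimates[f"{a}->{b}"]


class _RamModel:
    """Index bookkeeping for the RAM parameterization of one SemSpec."""

    def __init__(self, spec: SemSpec):
        spec.validate()
        self.spec = spec
        self.latents = spec.latents()
        self.obs = spec.indicators()
        self.m = len(self.latents) + len(self.obs)
        self.p = len(self.obs)
        self.lat_idx = {v: i for i, v in enumerate(self.latents)}
        self.obs_idx = {v: len(self.latents) + i for i, v in enumerate(self.obs)}
        self.obs_rows = np.arange(len(self.latents), self.m)

        self.fixed_A: list[tuple[int, int]] = []
        self.free_A: list[tuple[int, int]] = []
        self.names_A: list[str] = []
        for lat, inds in spec.measurement.items():
            j = self.lat_idx[lat]
            self.fixed_A.append((self.obs_idx[inds[0]], j))
            for ind in inds[1:]:
                self.free_A.append((self.obs_idx[ind], j))
                self.names_A.append(f"{lat}->{ind}")
        for a, b in spec.structural:
            self.free_A.append((self.lat_idx[b], self.lat_idx[a]))
            self.names_A.append(f"{a}->{b}")

        # variances: all observed errors + all latent (residual) variances,
        # log-parameterized; free covariances linear.
        self.var_rows = list(range(self.m))
        self.free_cov: list[tuple[int, int]] = []
        self.names_cov: list[str] = []
        for a, b in spec.covariances:
            self.free_cov.append((self.lat_idx[a], self.lat_idx[b]))
            self.names_cov.append(f"{a}~~{b}")

        self.n_free = len(self.free_A) + self.m + len(self.free_cov)
        self.param_names = (
            self.names_A
            + [f"var({v})" for v in self.latents + self.obs]
            + self.names_cov
        )
        self._fa = np.array(self.free_A, dtype=int).reshape(-1, 2)
        self._fc = np.array(self.free_cov, dtype=int).reshape(-1, 2)

    def start(self) -> np.ndarray:
        theta = np.zeros(self.n_free)
        na = len(self.free_A)
        # loadings start at 1 (parallel items), structural paths at 0
        n_load = sum(len(v) - 1 for v in self.spec.measurement.values())
        theta[:n_load] = 1.0
        # log-variances: latents ~0.45, observed errors ~0.5 (items are
        # standardized before fitting)
        theta[na : na + len(self.latents)] = math.log(0.45)
        theta[na + len(self.latents) : na + self.m] = math.log(0.5)
        return theta

    def matrices(self, theta: np.ndarray):
        A = np.zeros((self.m, self.m))
        for i, j in self.fixed_A:
            A[i, j] = 1.0
        na = len(self.free_A)
        if na:
            A[self._fa[:, 0], self._fa[:, 1]] = theta[:na]
        Psi = np.zeros((self.m, self.m))
        v = np.exp(theta[na : na + self.m])
        Psi[self.var_rows, self.var_rows] = v
        nc = len(self.free_cov)
        if nc:
            c = theta[na + self.m :]
            Psi[self._fc[:, 0], self._fc[:, 1]] += c
            Psi[self._fc[:, 1], self._fc[:, 0]] += c
        return A, Psi

    def implied(self, theta: np.ndarray):
        A, Psi = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.m) - A)
        V = B @ Psi @ B.T  # covariance over all variables
        G = B[self.obs_rows, :]
        Sigma = V[np.ix_(self.obs_rows, self.obs_rows)]
        return A, Psi, B, G, V, Sigma

    def objective(self, theta: np.ndarray, C: np.ndarray, logdet_C: float):
        """F_ML and its analytic gradient; returns a large penalty when the
        implied covariance leaves the positive-definite cone."""
        A, Psi, B, G, V, Sigma = self.implied(theta)
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            w = np.linalg.eigvalsh(Sigma)
            return 1e8 * (1.0 - min(w[0], 0.0)), np.zeros_like(theta)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        Sig_inv = np.linalg.inv(Sigma)
        F = logdet + float((Sig_inv * C).sum()) - logdet_C - self.p
        W = Sig_inv - Sig_inv @ C @ Sig_inv

        grad = np.zeros_like(theta)
        WG = W @ G
        # d/dA: 2 [ (B Psi B') K ]_{j,i}, K = F' W G on observed rows
        K = np.zeros((self.m, self.m))
        K[self.obs_rows, :] = WG
        HK = V @ K
        na = len(self.free_A)
        if na:
            grad[:na] = 2.0 * HK[self._fa[:, 1], self._fa[:, 0]]
        # d/dPsi: (2 - delta_ij) [G' W G]_{ij}; chain through log for diag
        M = G.T @ WG
        diag = np.diag(Psi)[self.var_rows]
        grad[na : na + self.m] = np.diag(M)[self.var_rows] * diag
        nc = len(self.free_cov)
        if nc:
            grad[na + self.m :] = 2.0 * M[self._fc[:, 0], self._fc[:, 1]]
        return F, grad


def _data_hash(data: pd.DataFrame) -> str:
    """Fingerprint of the source table (not of the modelled columns), so
    fits of different specs to the same table are recognized as
    comparable."""
    return hashlib.sha256(
        pd.util.hash_pandas_object(data, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


def _baseline(C: np.ndarray, n: int, logdet_C: float) -> tuple[float, int]:
    p = C.shape[0]
    # independence model: Sigma = diag(C)
    F_b = float(np.log(np.diag(C)).sum()) + p - logdet_C - p
    return (n - 1) * F_b, p * (p - 1) // 2


def fit_sem(
    spec: SemSpec,
    data: pd.DataFrame,
    se: bool = True,
    max_retries: int = 3,
) -> SemFit:
    """Fit ``spec`` to indicator data by maximum likelihood.

    Items are standardized before fitting (estimation on the Pearson
    correlation matrix of the Likert items), so the reported solution is
    directly comparable to standardized path diagrams.  Non-convergence is
    flagged on the result, never raised.
    """
    if spec.saturated:
        cols = [c for c in data.columns if data[c].dtype.kind in "if"]
        n = len(data.dropna(subset=cols))
        return SemFit(
            spec=spec, estimates={}, estimates_unstd={}, se={},
            chi_square=0.0, df=0, n=n, baseline_chi_square=0.0,
            baseline_df=0, indices={"rmsea": 0.0, "cfi": 1.0, "tli": 1.0, "srmr": 0.0},
            converged=True, n_free=0, latent_sd={}, data_hash=_data_hash(data),
        )

    model = _RamModel(spec)
    missing = [c for c in model.obs if c not in data.columns]
    if missing:
        raise SchemaError(f"data is missing indicator columns: {missing}")
    X = data[model.obs].dropna().to_numpy(dtype=float)
    n = X.shape[0]
    if n <= model.n_free:
        raise DataError(f"n = {n} does not exceed the {model.n_free} free parameters")
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    C = np.cov(X, rowvar=False, ddof=1)
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise DataError("sample covariance is not positive definite") from exc
    logdet_C = float(np.linalg.slogdet(C)[1])

    theta0 = model.start()
    rng = np.random.default_rng(0)
    best = None
    converged = False
    for attempt in range(max_retries):
        res = optimize.minimize(
            model.objective,
            theta0,
            args=(C, logdet_C),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 3000, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        gnorm = float(np.max(np.abs(res.jac)))
        if res.fun < 1e7 and gnorm < 5e-4:
            converged = True
            break
        theta0 = model.start() + rng.normal(0, 0.05, model.n_free)
    res = best
    theta = res.x

    A, Psi, B, G, V, Sigma = model.implied(theta)
    sd = np.sqrt(np.diag(V))
    all_names = model.latents + model.obs

    estimates_unstd: dict[str, float] = {}
    estimates: dict[str, float] = {}
    std_factor: dict[int, float] = {}
    na = len(model.free_A)
    for k, (i, j) in enumerate(model.free_A):
        name = model.names_A[k]
        estimates_unstd[name] = float(theta[k])
        f = sd[j] / sd[i]
        std_factor[k] = f
        estimates[name] = float(theta[k] * f)
    # fixed first loadings, standardized
    for lat, inds in spec.measurement.items():
        i, j = model.obs_idx[inds[0]], model.lat_idx[lat]
        estimates[f"{lat}->{inds[0]}"] = float(sd[j] / sd[i])
        estimates_unstd[f"{lat}->{inds[0]}"] = 1.0
    for k, (i, j) in enumerate(model.free_cov):
        name = model.names_cov[k]
        idx = na + model.m + k
        estimates_unstd[name] = float(theta[idx])
        f = 1.0 / (sd[i] * sd[j])
        std_factor[idx] = f
        estimates[name] = float(theta[idx] * f)
    for r in model.var_rows:
        estimates_unstd[f"var({all_names[r]})"] = float(Psi[r, r])

    chi2 = max(0.0, (n - 1) * float(res.fun))
    df = model.p * (model.p + 1) // 2 - model.n_free
    chi2_b, df_b = _baseline(C, n, logdet_C)

    D = np.sqrt(np.outer(np.diag(C), np.diag(C)))
    resid = (C - Sigma) / D
    srmr = float(np.sqrt(np.mean(resid[np.tril_indices(model.p)] ** 2)))

    ses: dict[str, float] = {}
    param_cov_std = None
    if se and converged:
        H = _numeric_hessian(model, theta, C, logdet_C)
        try:
            cov_unstd = 2.0 / (n - 1) * np.linalg.inv(H)
            dstd = np.ones(model.n_free)
            for k, f in std_factor.items():
                dstd[k] = f
            param_cov_std = cov_unstd * np.outer(dstd, dstd)
            sevec = np.sqrt(np.clip(np.diag(param_cov_std), 0.0, None))
            for k in range(na):
                ses[model.names_A[k]] = float(sevec[k])
            for k in range(len(model.free_cov)):
                ses[model.names_cov[k]] = float(sevec[na + model.m + k])
        except np.linalg.LinAlgError:
            pass

    fit = SemFit(
        spec=spec,
        estimates=estimates,
        estimates_unstd=estimates_unstd,
        se=ses,
        chi_square=chi2,
        df=df,
        n=n,
        baseline_chi_square=chi2_b,
        baseline_df=df_b,
        indices={"srmr": srmr},
        converged=converged,
        n_free=model.n_free,
        latent_sd={v: float(sd[model.lat_idx[v]]) for v in model.latents},
        data_hash=_data_hash(data),
        param_names=model.param_names,
        param_cov_std=param_cov_std,
    )
    fit.indices = fit_indices(fit)
    return fit


def _numeric_hessian(model: _RamModel, theta: np.ndarray, C, logdet_C, eps: float = 1e-5):
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        tp = theta.copy(); tp[i] += eps
        tm = theta.copy(); tm[i] -= eps
        _, gp = model.objective(tp, C, logdet_C)
        _, gm = model.objective(tm, C, logdet_C)
        H[i] = (gp - gm) / (2 * eps)
    return (H + H.T) / 2


# ----------------------------------------------------------------------
# fit indices
# ----------------------------------------------------------------------
def rmsea(chi_square: float, df: int, n: int) -> float:
    """Root mean square error of approximation,
    sqrt(max(chi2 - df, 0) / (df (n - 1)))."""
    if df == 0:
        if chi_square <= 1e-10:
            return 0.0
        return float("nan")
    return math.sqrt(max(chi_square - df, 0.0) / (df * (n - 1)))


def cfi(chi_square: float, df: int, baseline_chi_square: float, baseline_df: int) -> float:
    num = max(chi_square - df, 0.0)
    den = max(baseline_chi_square - baseline_df, chi_square - df, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def tli(chi_square: float, df: int, baseline_chi_square: float, baseline_df: int) -> float:
    """Tucker-Lewis index, untruncated (may exceed 1)."""
    if df == 0 or baseline_df == 0:
        return float("nan")
    rb = baseline_chi_square / baseline_df
    rm = chi_square / df
    if rb == 1.0:
        return float("nan")
    return (rb - rm) / (rb - 1.0)


def fit_indices(fit: SemFit) -> dict[str, float]:
    """RMSEA, CFI, TLI (raw and truncated at 1) and SRMR for a fit."""
    t = tli(fit.chi_square, fit.df, fit.baseline_chi_square, fit.baseline_df)
    out = {
        "rmsea": rmsea(fit.chi_square, fit.df, fit.n),
        "cfi": cfi(fit.chi_square, fit.df, fit.baseline_chi_square, fit.baseline_df),
        "tli_raw": t,
        "tli": min(t, 1.0) if not math.isnan(t) else t,
    }
    out["srmr"] = fit.indices.get("srmr", 0.0) if fit.indices else 0.0
    if fit.spec.saturated:
        out["srmr"] = 0.0
    return out


# ----------------------------------------------------------------------
# mediation
# ----------------------------------------------------------------------
def _chain_edges(chain) -> list[tuple[str, str]]:
    if all(isinstance(e, (tuple, list)) and len(e) == 2 for e in chain):
        return [tuple(e) for e in chain]
    if all(isinstance(v, str) for v in chain) and len(chain) >= 2:
        return list(zip(chain[:-1], chain[1:]))
    raise InvalidConfigError("chain must be a node list or an edge list")


def indirect_effect(fit: SemFit, chain) -> dict[str, float]:
    """Indirect (mediated) effect along ``chain``: the exact product of the
    standardized path estimates (a*b under the product-of-coefficients
    rule), with a multivariate delta-method standard error and two-sided
    normal-approximation p value.

    ``chain`` is either a node sequence ``[x, m, y]`` or an edge list.
    """
    edges = _chain_edges(chain)
    keys = [f"{a}->{b}" for a, b in edges]
    for k in keys:
        if k not in fit.estimates:
            raise InvalidConfigError(f"chain edge {k} is not a free parameter of the fit")
    b = np.array([fit.estimates[k] for k in keys])
    est = float(np.prod(b))

    se_val = float("nan")
    if fit.param_cov_std is not None:
        idx = [fit.param_names.index(k) for k in keys]
        grad = np.array([np.prod(np.delete(b, i)) for i in range(len(b))])
        sub = fit.param_cov_std[np.ix_(idx, idx)]
        var = float(grad @ sub @ grad)
        se_val = math.sqrt(max(var, 0.0))
    if se_val and not math.isnan(se_val) and se_val > 0:
        z = est / se_val
        p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    else:
        z, p = float("nan"), float("nan")
    return {"estimate": est, "se": se_val, "z": z, "p": p}


def bootstrap_indirect(
    spec: SemSpec,
    data: pd.DataFrame,
    chain,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict[str, float]:
    """Percentile bootstrap for an indirect effect: resample rows, refit,
    recompute the product of paths."""
    rng = np.random.default_rng(seed)
    edges = _chain_edges(chain)
    keys = [f"{a}->{b}" for a, b in edges]
    vals = []
    for _ in range(n_boot):
        boot = data.iloc[rng.integers(0, len(data), len(data))]
        f = fit_sem(spec, boot, se=False, max_retries=1)
        if f.converged:
            vals.append(np.prod([f.estimates[k] for k in keys]))
    vals = np.asarray(vals)
    alpha = 1.0 - ci
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return {
        "estimate": float(np.mean(vals)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_effective": int(len(vals)),
    }


# ----------------------------------------------------------------------
# model comparison & reliability
# ----------------------------------------------------------------------
def compare_models(fits: list[SemFit]) -> pd.DataFrame:
    """Side-by-side fit comparison, ordered by CFI (desc) then RMSEA (asc).

    The AIC-style column is chi^2 + 2 * n_free (same-data comparison only).
    """
    if len({(f.data_hash, f.n) for f in fits}) > 1:
        raise DataError("fits were computed on different data; comparison undefined")
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.spec.name,
                "chi_square": f.chi_square,
                "df": f.df,
                "rmsea": f.indices["rmsea"],
                "cfi": f.indices["cfi"],
                "tli": f.indices["tli"],
                "srmr": f.indices["srmr"],
                "aic_style": f.chi_square + 2 * f.n_free,
                "converged": f.converged,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(["cfi", "rmsea"], ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha, (k/(k-1)) (1 - sum of item variances / variance of
    the sum).  Returns NaN when the total score has zero variance."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise InvalidConfigError("need a 2-D array with >= 2 items and >= 2 rows")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return float("nan")
    item_var = X.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def save_fit(fit: SemFit, path: str | Path) -> None:
    """Fit report as JSON (estimates, SEs, chi-square, indices)."""
    Path(path).write_text(
        json.dumps(
            {
                "model": fit.spec.name,
                "n": fit.n,
                "converged": fit.converged,
                "chi_square": fit.chi_square,
                "df": fit.df,
                "baseline_chi_square": fit.baseline_chi_square,
                "baseline_df": fit.baseline_df,
                "indices": fit.indices,
                "estimates_standardized": fit.estimates,
                "se": fit.se,
            },
            indent=2,
        )
    )
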