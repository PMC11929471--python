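"""Bayesian linear path analysis (SEM) over standardized survey variables.

The model is a recursive (acyclic) system of linear Gaussian equations: each
endogenous variable is regressed on its declared parents, continuous
variables are z-scored so path coefficients are standardized effects, and
categorical spatial drivers (reef, site) enter as sum-to-zero contrasts.
Residuals are independent across equations except within declared
correlation blocks (e.g. the benthic-cover categories), which share a full
covariance matrix.

Inference is by Gibbs sampling: path coefficients receive N(0, 1) priors and
conjugate Gaussian updates given the residual (co)variances; residual
variances get inverse-gamma and block covariances inverse-Wishart updates.
Convergence is monitored with rank-normalized split R-hat and model adequacy
with a posterior-predictive p-value on a chi-square-type discrepancy (sum of
squared standardized residuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .counts import standardize_density

__all__ = [
    "PathModelSpec",
    "PreparedModel",
    "Equation",
    "PosteriorDraws",
    "SEMResult",
    "CyclicGraphError",
    "default_spec",
    "build_model",
    "sample_posterior",
    "rhat",
    "posterior_predictive_p",
    "path_summary",
    "fit_sem",
]


class CyclicGraphError(ValueError):
    """The declared edge set contains a directed cycle."""


@dataclass
class PathModelSpec:
    """Node/edge graph of the path model.

    ``nodes`` maps variable name to role (``"exogenous"`` or
    ``"endogenous"``); ``edges`` are (parent, child) pairs forming a DAG;
    ``categorical_drivers`` are exogenous factors expanded to sum-to-zero
    contrasts; ``residual_blocks`` are sets of endogenous nodes whose
    equation errors may be correlated.  All path coefficients share a
    Normal(prior_mean, prior_sd) prior.
    """

    nodes: dict
    edges: list
    categorical_drivers: list = field(default_factory=list)
    residual_blocks: list = field(default_factory=list)
    prior_mean: float = 0.0
    prior_sd: float = 1.0

    def __post_init__(self) -> None:
        for parent, child in self.edges:
            if parent not in self.nodes or child not in self.nodes:
                raise ValueError(f"edge ({parent!r}, {child!r}) uses undeclared node")
            if self.nodes[child] != "endogenous":
                raise ValueError(f"edge into non-endogenous node {child!r}")
        for block in self.residual_blocks:
            for name in block:
                if self.nodes.get(name) != "endogenous":
                    raise ValueError(f"residual block contains non-endogenous node {name!r}")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        self.topological_order()  # raises on cycles

    @property
    def endogenous(self) -> list:
        return [n for n, role in self.nodes.items() if role == "endogenous"]

    def parents(self, child: str) -> list:
        return [p for p, c in self.edges if c == child]

    def topological_order(self) -> list:
        """Kahn's algorithm; raises CyclicGraphError on a cycle."""
        indeg = {n: 0 for n in self.nodes}
        for _, child in self.edges:
            indeg[child] += 1
        frontier = [n for n, d in indeg.items() if d == 0]
        order = []
        while frontier:
            node = frontier.pop()
            order.append(node)
            for parent, child in self.edges:
                if parent == node:
                    indeg[child] -= 1
                    if indeg[child] == 0:
                        frontier.append(child)
        if len(order) != len(self.nodes):
            raise CyclicGraphError("edge list contains a directed cycle")
        return order


def default_spec() -> PathModelSpec:
    """Habitat -> microhabitat -> predator -> CoTS graph of the survey study.

    Spatial drivers (reef, site, depth) predict benthic cover; rubble cover
    drives bed thickness and sand drives rubble-piece metrics; thickness and
    hard substrate (dead-coral cover, the measured stand-in for hard
    substrate) drive *S. aspera*; piece metrics drive portunids; and both
    predators plus the spatial drivers feed the adult CoTS index.  Cover
    categories share a residual-correlation block because compositions are
    intrinsically dependent.
    """
    nodes = {
        "depth": "exogenous",
        "reef": "exogenous",
        "site": "exogenous",
        "rubble": "endogenous",
        "live_coral": "endogenous",
        "dead_coral": "endogenous",
        "sand": "endogenous",
        "rubble_thickness": "endogenous",
        "mean_piece_area": "endogenous",
        "n_pieces": "endogenous",
        "s_aspera": "endogenous",
        "portunidae": "endogenous",
        "cots": "endogenous",
    }
    covers = ["rubble", "live_coral", "dead_coral", "sand"]
    edges = []
    for cov in covers:
        edges += [("depth", cov), ("reef", cov), ("site", cov)]
    edges += [
        ("rubble", "rubble_thickness"),
        ("live_coral", "rubble_thickness"),
        ("sand", "mean_piece_area"),
        ("sand", "n_pieces"),
        ("rubble", "n_pieces"),
        ("rubble_thickness", "s_aspera"),
        ("dead_coral", "s_aspera"),
        ("live_coral", "s_aspera"),
        ("mean_piece_area", "portunidae"),
        ("n_pieces", "portunidae"),
        ("reef", "portunidae"),
        ("s_aspera", "cots"),
        ("portunidae", "cots"),
        ("reef", "cots"),
        ("site", "cots"),
    ]
    return PathModelSpec(
        nodes=nodes,
        edges=edges,
        categorical_drivers=["reef", "site"],
        residual_blocks=[frozenset(covers)],
    )


@dataclass
class Equation:
    """One endogenous equation: z-scored response and design matrix."""

    child: str
    y: np.ndarray
    X: np.ndarray
    colnames: list  # e.g. "s_aspera~rubble_thickness", "cots~reef[south_reef1]"


@dataclass
class PreparedModel:
    spec: PathModelSpec
    equations: dict  # child -> Equation
    blocks: list  # lists of children sharing a residual covariance
    n: int

    @property
    def param_names(self) -> list:
        names = []
        for eq in self.equations.values():
            names.extend(eq.colnames)
        for block in self.blocks:
            if len(block) == 1:
                names.append(f"sigma2[{block[0]}]")
            else:
                for j, a in enumerate(block):
                    names.append(f"sigma2[{a}]")
                    for b in block[j + 1 :]:
                        names.append(f"corr[{a},{b}]")
        return names


@dataclass
class PosteriorDraws:
    """MCMC draws indexed (chain, iteration, parameter)."""

    array: np.ndarray
    names: list
    burnin: int

    def retained(self) -> np.ndarray:
        return self.array[:, self.burnin :, :]

    def to_inference_data(self):
        post = {name: self.retained()[:, :, i] for i, name in enumerate(self.names)}
        return az.from_dict(posterior=post)


@dataclass
class SEMResult:
    """Per-edge posterior summaries with 95% CI sign classification."""

    table: pd.DataFrame
    posterior_predictive_p: float | None
    max_rhat: float


_COLUMN_MAP = {
    "depth": "depth_m",
    "rubble": "cover_rubble",
    "live_coral": "cover_live_coral",
    "dead_coral": "cover_dead_coral",
    "sand": "cover_sand",
    "macroalgae": "cover_macroalgae",
    "soft_coral": "cover_soft_coral",
    "rubble_thickness": "rubble_thickness_cm",
    "mean_piece_area": "mean_piece_area_cm2",
    "n_pieces": "n_pieces_inspected",
    "cots": "cots_index",
}


def _node_values(node: str, data: pd.DataFrame) -> np.ndarray:
    if node in data.columns:
        return data[node].to_numpy(dtype=float)
    col = _COLUMN_MAP.get(node)
    if col is not None and col in data.columns:
        return data[col].to_numpy(dtype=float)
    if f"count_{node}" in data.columns:
        return standardize_density(
            data[f"count_{node}"].to_numpy(dtype=float), data["area_m2"].to_numpy(dtype=float)
        )
    raise KeyError(f"node {node!r} not present or derivable from the data")


def _sum_to_zero(labels: pd.Series, prefix: str):
    levels = list(dict.fromkeys(labels.astype(str)))
    if len(levels) < 2:
        raise ValueError(f"categorical driver {prefix!r} needs >= 2 levels")
    arr = labels.astype(str).to_numpy()
    cols = np.zeros((len(arr), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(arr == lev, 1.0, np.where(arr == levels[-1], -1.0, 0.0))
    names = [f"{prefix}[{lev}]" for lev in levels[:-1]]
    return cols, names


def build_model(spec: PathModelSpec, data: pd.DataFrame) -> PreparedModel:
    """Z-score variables, expand categorical drivers, assemble per-equation
    design matrices.

    Raises a structured error for a missing column, a constant column
    (sd = 0), or a cyclic graph (checked at spec construction too).
    """
    n = len(data)
    zcache = {}

    def zscored(node):
        if node not in zcache:
            vals = _node_values(node, data)
            sd = np.std(vals)
            if sd == 0:
                raise ValueError(f"column for node {node!r} is constant (sd = 0)")
            zcache[node] = (vals - vals.mean()) / sd
        return zcache[node]

    equations = {}
    for child in spec.endogenous:
        y = zscored(child)
        cols, names = [], []
        for parent in spec.parents(child):
            if parent in spec.categorical_drivers:
                Xc, levnames = _sum_to_zero(data[parent], parent)
                cols.append(Xc)
                names.extend(f"{child}~{nm}" for nm in levnames)
            else:
                cols.append(zscored(parent)[:, None])
                names.append(f"{child}~{parent}")
        X = np.hstack(cols) if cols else np.empty((n, 0))
        if n > 0 and X.shape[1] >= n:
            raise ValueError(
                f"equation for {child!r} has {X.shape[1]} parameters but only {n} rows"
            )
        equations[child] = Equation(child=child, y=y, X=X, colnames=names)

    in_block = set()
    blocks = []
    for block in spec.residual_blocks:
        members = [c for c in spec.endogenous if c in block]
        blocks.append(members)
        in_block.update(members)
    for child in spec.endogenous:
        if child not in in_block:
            blocks.append([child])
    return PreparedModel(spec=spec, equations=equations, blocks=blocks, n=n)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _invwishart_draw(df: float, scale: np.ndarray, rng) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition of the Wishart."""
    m = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((m, m))
    for i in range(m):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    W = L @ A
    return np.linalg.inv(W @ W.T)


def _draw_coefficients(XtX, Xty, prior_prec, prior_mean_term, sigma2_scale, rng):
    """One conjugate Gaussian draw for a (stacked) coefficient vector."""
    A = XtX * sigma2_scale + prior_prec
    rhs = Xty * sigma2_scale + prior_mean_term
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, rhs)
    z = rng.standard_normal(len(rhs))
    return mean + np.linalg.solve(L.T, z)


def sample_posterior(
    model: PreparedModel,
    chains: int = 3,
    iterations: int = 11000,
    burnin: int = 1000,
    seed: int = 0,
    fixed_resid_var: dict | float | None = None,
) -> PosteriorDraws:
    """Gibbs sampling of all path coefficients and residual (co)variances.

    Defaults follow the study settings (3 chains, 11,000 iterations, first
    1,000 discarded); scale down for testing.  ``fixed_resid_var`` pins
    residual variances (scalar or per-equation dict), in which case only
    coefficients are updated — the conjugate closed-form regime.
    """
    if iterations <= burnin:
        raise ValueError("iterations must exceed burnin")
    if chains < 2:
        warnings.warn("fewer than 2 chains: R-hat will be unavailable", RuntimeWarning)
    spec = model.spec
    eqs = model.equations
    n = model.n
    names = model.param_names
    n_param = len(names)
    draws = np.empty((chains, iterations, n_param))

    # precomputations
    pre = {}
    for child, eq in eqs.items():
        pre[child] = {"XtX": eq.X.T @ eq.X, "Xty": eq.X.T @ eq.y, "p": eq.X.shape[1]}
    block_cross = {}
    block_xty = {}
    for bi, block in enumerate(model.blocks):
        if len(block) > 1:
            block_cross[bi] = {
                (a, b): eqs[a].X.T @ eqs[b].X for a in block for b in block
            }
            block_xty[bi] = {(a, b): eqs[a].X.T @ eqs[b].y for a in block for b in block}

    def fixed_var(child):
        if fixed_resid_var is None:
            return None
        if isinstance(fixed_resid_var, dict):
            return fixed_resid_var.get(child)
        return float(fixed_resid_var)

    prior_var = spec.prior_sd**2
    a0, b0 = 2.0, 1.0  # weakly informative inverse-gamma on residual variances
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)

    for ci in range(chains):
        rng = np.random.default_rng(chain_seeds[ci])
        beta = {child: np.zeros(pre[child]["p"]) for child in eqs}
        sigma2 = {child: fixed_var(child) or 1.0 for child in eqs}
        Sigma = {bi: np.eye(len(block)) for bi, block in enumerate(model.blocks) if len(block) > 1}

        for it in range(iterations):
            for bi, block in enumerate(model.blocks):
                if len(block) == 1:
                    child = block[0]
                    p = pre[child]["p"]
                    s2 = sigma2[child]
                    if p:
                        beta[child] = _draw_coefficients(
                            pre[child]["XtX"],
                            pre[child]["Xty"],
                            np.eye(p) / prior_var,
                            np.full(p, spec.prior_mean / prior_var),
                            1.0 / s2,
                            rng,
                        )
                    if fixed_var(child) is None and n > 0:
                        resid = eqs[child].y - eqs[child].X @ beta[child]
                        # inverse-gamma draw via 1/gamma
                        sigma2[child] = float(
                            (b0 + 0.5 * resid @ resid) / rng.gamma(a0 + n / 2.0)
                        )
                else:
                    m = len(block)
                    Sinv = np.linalg.inv(Sigma[bi])
                    sizes = [pre[c]["p"] for c in block]
                    offs = np.concatenate([[0], np.cumsum(sizes)])
                    P = offs[-1]
                    if P:
                        A = np.eye(P) / prior_var
                        rhs = np.full(P, spec.prior_mean / prior_var)
                        for j, cj in enumerate(block):
                            for k, ck in enumerate(block):
                                A[offs[j] : offs[j + 1], offs[k] : offs[k + 1]] += (
                                    Sinv[j, k] * block_cross[bi][(cj, ck)]
                                )
                            rhs[offs[j] : offs[j + 1]] += sum(
                                Sinv[j, k] * block_xty[bi][(cj, ck)]
                                for k, ck in enumerate(block)
                            )
                        L = np.linalg.cholesky(A)
                        mean = np.linalg.solve(A, rhs)
                        stacked = mean + np.linalg.solve(L.T, rng.standard_normal(P))
                        for j, cj in enumerate(block):
                            beta[cj] = stacked[offs[j] : offs[j + 1]]
                    if n > 0:
                        E = np.column_stack(
                            [eqs[c].y - eqs[c].X @ beta[c] for c in block]
                        )
                        scale = np.eye(m) + E.T @ E
                        Sigma[bi] = _invwishart_draw(m + 2 + n, scale, rng)
                        for j, cj in enumerate(block):
                            sigma2[cj] = float(Sigma[bi][j, j])

            # pack the draw
            vals = []
            for child in eqs:
                vals.append(beta[child])
            for bi, block in enumerate(model.blocks):
                if len(block) == 1:
                    vals.append([sigma2[block[0]]])
                else:
                    S = Sigma[bi]
                    sd = np.sqrt(np.diag(S))
                    for j, a in enumerate(block):
                        row = [S[j, j]]
                        row += [S[j, k] / (sd[j] * sd[k]) for k in range(j + 1, len(block))]
                        vals.append(row)
            draws[ci, it, :] = np.concatenate([np.atleast_1d(v) for v in vals])

    return PosteriorDraws(array=draws, names=names, burnin=burnin)


def rhat(draws: PosteriorDraws) -> dict:
    """Rank-normalized split-chain potential scale reduction per parameter."""
    if draws.array.shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if draws.array.shape[1] - draws.burnin < 100:
        raise ValueError("R-hat requires >= 100 post-burn-in iterations")
    ds = az.rhat(draws.to_inference_data(), method="rank")
    return {name: float(ds[name].values) for name in draws.names}


def posterior_predictive_p(
    model: PreparedModel,
    draws: PosteriorDraws,
    n_rep: int = 200,
    seed: int = 0,
    statistic: str = "chisq",
) -> float:
    """Posterior-predictive p-value comparing observed and replicated data.

    For each retained draw, replicated data are generated from the drawn
    parameters at the observed design matrices and a discrepancy is computed
    for both; the returned p is the fraction of draws with replicated >=
    observed.  ``statistic="chisq"`` (default) is the total squared
    standardized residual across equations (Mahalanobis within correlated
    blocks).  Because residual variances are free parameters, that statistic
    has essentially no power against symmetric tail misspecification;
    ``statistic="tails"`` (total fourth power of standardized residuals)
    targets exactly that.
    """
    if statistic not in ("chisq", "tails"):
        raise ValueError("statistic must be 'chisq' or 'tails'")
    rng = np.random.default_rng(seed)
    ret = draws.retained()
    flat = ret.reshape(-1, ret.shape[-1])
    idx = np.linspace(0, len(flat) - 1, min(n_rep, len(flat))).astype(int)
    name_pos = {name: i for i, name in enumerate(draws.names)}
    eqs = model.equations
    n = model.n
    exceed = 0
    for row in flat[idx]:
        t_obs = 0.0
        t_rep = 0.0
        for block in model.blocks:
            m = len(block)
            resid = np.column_stack(
                [
                    eqs[c].y
                    - (eqs[c].X @ row[[name_pos[nm] for nm in eqs[c].colnames]]
                       if eqs[c].colnames else np.zeros(n))
                    for c in block
                ]
            )
            if m == 1:
                s2 = row[name_pos[f"sigma2[{block[0]}]"]]
                e_rep = rng.normal(scale=np.sqrt(s2), size=(n, 1))
                if statistic == "chisq":
                    t_obs += float(np.sum(resid**2) / s2)
                    t_rep += float(np.sum(e_rep**2) / s2)
                else:
                    t_obs += float(np.sum((resid**2 / s2) ** 2))
                    t_rep += float(np.sum((e_rep**2 / s2) ** 2))
            else:
                S = np.eye(m)
                sd = np.sqrt([row[name_pos[f"sigma2[{c}]"]] for c in block])
                for j, a in enumerate(block):
                    S[j, j] = sd[j] ** 2
                    for k in range(j + 1, m):
                        r = row[name_pos[f"corr[{a},{block[k]}]"]]
                        S[j, k] = S[k, j] = r * sd[j] * sd[k]
                e_rep = rng.multivariate_normal(np.zeros(m), S, size=n)
                if statistic == "chisq":
                    Sinv = np.linalg.inv(S)
                    t_obs += float(np.einsum("ij,jk,ik->", resid, Sinv, resid))
                    t_rep += float(np.einsum("ij,jk,ik->", e_rep, Sinv, e_rep))
                else:
                    t_obs += float(np.sum((resid / sd) ** 4))
                    t_rep += float(np.sum((e_rep / sd) ** 4))
        if t_rep >= t_obs:
            exceed += 1
    return exceed / len(idx)


def path_summary(draws: PosteriorDraws, rhat_threshold: float = 1.05) -> SEMResult:
    """Posterior mean, sd, central 95% CI and sign class per coefficient.

    Sign classification: ``positive`` if the 95% CI lies above zero,
    ``negative`` if below, otherwise ``nonsignificant``.  R-hat above the
    threshold raises a warning and is recorded per parameter.
    """
    ret = draws.retained()
    try:
        rhats = rhat(draws)
    except ValueError:
        rhats = {name: np.nan for name in draws.names}
    rows = []
    for i, name in enumerate(draws.names):
        samp = ret[:, :, i].ravel()
        lo, hi = np.percentile(samp, [2.5, 97.5])
        sign = "positive" if lo > 0 else ("negative" if hi < 0 else "nonsignificant")
        rows.append(
            {
                "parameter": name,
                "mean": float(samp.mean()),
                "sd": float(samp.std(ddof=1)),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "sign": sign,
                "rhat": rhats[name],
            }
        )
    table = pd.DataFrame(rows)
    max_rhat = float(np.nanmax(table["rhat"].to_numpy())) if len(table) else np.nan
    if np.isfinite(max_rhat) and max_rhat > rhat_threshold:
        warnings.warn(f"max R-hat {max_rhat:.3f} exceeds {rhat_threshold}", RuntimeWarning)
    return SEMResult(table=table, posterior_predictive_p=None, max_rhat=max_rhat)


def fit_sem(
    spec: PathModelSpec,
    data: pd.DataFrame,
    chains: int = 3,
    iterations: int = 11000,
    burnin: int = 1000,
    seed: int = 0,
    ppp_reps: int = 200,
) -> tuple:
    """Convenience wrapper: build, sample, summarize, and check the model."""
    model = build_model(spec, data)
    draws = sample_posterior(model, chains=chains, iterations=iterations, burnin=burnin, seed=seed)
    result = path_summary(draws)
    result.posterior_predictive_p = posterior_predictive_p(
        model, draws, n_rep=ppp_reps, seed=seed + 1
    )
    return model, draws, result
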