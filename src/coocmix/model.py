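"""Bayesian mixed-effects co-occurrence model.

The observed co-occurrence count of each species pair follows Fisher's
non-central hypergeometric distribution with a log link on the odds ratio:

    theta_pair = X beta + u_set(pair) [+ v_dietpair(pair)]
    u_s ~ Normal(0, sigma_{group(s)})        v_d ~ Normal(0, sigma_v)

Fixed effects (treatment contrasts, reference levels: low guild overlap,
intact habitat) act on pair covariates; the random intercept on the
co-occurrence-set ID pools pairs that share covariate levels, which is what
makes theta estimable for rare species whose individual tables carry almost
no information. The random-effect standard deviation may be constant or
vary with dietary-guild overlap or habitat.

Inference is MCMC: an adaptive Metropolis-within-Gibbs sampler with
componentwise updates for the set intercepts (vectorised over sets, which
are conditionally independent given the fixed effects), componentwise
adaptive random-walk updates for the fixed effects, log-scale random-walk
updates for the variance components, and "compensated" moves that shift a
fixed-effect coefficient while counter-shifting the set intercepts so the
likelihood is unchanged — these decorrelate the intercept/contrast
directions from the random effects and are what make the chain mix well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .nhd import SupportTable

__all__ = [
    "ModelSpec",
    "Priors",
    "MCMCConfig",
    "PosteriorFit",
    "build_design",
    "linear_predictor",
    "model_loglik",
    "log_posterior",
    "fit_mcm",
    "posterior_summary",
    "gelman_rubin",
]

FIXED_TERM_VARS = ("std_phylo_distance", "guild_overlap", "habitat")
REFERENCE_LEVELS = {"guild_overlap": "low", "habitat": "intact"}
LEVELS = {"guild_overlap": ("low", "medium", "high"), "habitat": ("intact", "altered")}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model structure."""

    fixed_terms: tuple = ("std_phylo_distance", "guild_overlap", "habitat")
    set_defining_vars: tuple = (
        "occupancy_pairing",
        "phylo_bin",
        "diet_pairing",
        "habitat",
    )
    sigma_grouping: str = "constant"  # constant | guild_overlap | habitat
    include_diet_pairing_re: bool = False

    def __post_init__(self):
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "set_defining_vars", tuple(self.set_defining_vars))
        if "occupancy_pairing" not in self.set_defining_vars:
            raise ValueError("set_defining_vars must contain occupancy_pairing")
        if self.sigma_grouping not in ("constant", "guild_overlap", "habitat"):
            raise ValueError(f"unknown sigma_grouping {self.sigma_grouping!r}")
        for term in self.fixed_terms:
            for part in term.split(":"):
                if part not in FIXED_TERM_VARS:
                    raise ValueError(f"unknown fixed term component {part!r}")

    def label(self) -> str:
        fx = "+".join(self.fixed_terms) if self.fixed_terms else "1"
        re = ",".join(v for v in self.set_defining_vars)
        tag = f"fx[{fx}]|set[{re}]|sigma[{self.sigma_grouping}]"
        if self.include_diet_pairing_re:
            tag += "|diet_re"
        return tag


@dataclass(frozen=True)
class Priors:
    """Weakly-informative defaults: Normal(0, 5^2) fixed effects,
    half-Student-t(3, 0, 2.5) random-effect standard deviations."""

    beta_sd: float = 5.0
    sigma_df: float = 3.0
    sigma_scale: float = 2.5


@dataclass(frozen=True)
class MCMCConfig:
    """Chain geometry; the default mirrors the full-scale analysis
    (4 chains x 3000 steps, 1000 warm-up, thinning 2 -> 4000 draws)."""

    chains: int = 4
    steps: int = 3000
    warmup: int = 1000
    thin: int = 2
    store_loglik: bool = True
    rhat_warn: float = 1.05

    @property
    def n_keep_per_chain(self) -> int:
        return (self.steps - self.warmup) // self.thin


def _term_columns(records: pd.DataFrame, var: str) -> dict:
    """Treatment-coded columns for one variable."""
    if var == "std_phylo_distance":
        return {"std_phylo_distance": records["std_phylo_distance"].to_numpy(float)}
    levels = LEVELS[var]
    ref = REFERENCE_LEVELS[var]
    vals = records[var].astype(str)
    bad = set(vals.unique()) - set(levels)
    if bad:
        raise ValueError(f"unexpected {var} levels {sorted(bad)}")
    return {
        f"{var}[{lev}]": (vals == lev).to_numpy(float)
        for lev in levels
        if lev != ref
    }


class Design:
    """Numeric design assembled from pair records and a ModelSpec."""

    def __init__(self, records: pd.DataFrame, spec: ModelSpec):
        from .data import assign_cooc_sets

        self.spec = spec
        if all(c in records.columns for c in spec.set_defining_vars):
            # sets are (re)derived from the spec so candidate structures with
            # different set definitions really differ
            records = assign_cooc_sets(records, spec.set_defining_vars)
        elif "set_id" not in records.columns:
            raise ValueError(
                "records lack both set_id and the set-defining covariates"
            )
        self.records = records
        cols = {"(Intercept)": np.ones(len(records))}
        for term in spec.fixed_terms:
            parts = term.split(":")
            built = [_term_columns(records, p) for p in parts]
            cur = built[0]
            for nxt in built[1:]:
                cur = {
                    f"{na}:{nb}": va * vb
                    for na, va in cur.items()
                    for nb, vb in nxt.items()
                }
            cols.update(cur)
        self.beta_names = list(cols)
        self.X = np.column_stack([cols[c] for c in self.beta_names])

        set_cat = pd.Categorical(records["set_id"])
        self.set_labels = list(set_cat.categories)
        self.set_idx = np.asarray(set_cat.codes, dtype=np.int64)
        self.n_sets = len(self.set_labels)
        self.set_sizes = np.bincount(self.set_idx, minlength=self.n_sets)

        if spec.sigma_grouping == "constant":
            self.group_labels = ["all"]
            self.group_of_set = np.zeros(self.n_sets, dtype=np.int64)
        else:
            gcat = pd.Categorical(records[spec.sigma_grouping].astype(str))
            gcodes = np.asarray(gcat.codes, dtype=np.int64)
            mn = np.full(self.n_sets, np.iinfo(np.int64).max)
            mx = np.full(self.n_sets, -1, dtype=np.int64)
            np.minimum.at(mn, self.set_idx, gcodes)
            np.maximum.at(mx, self.set_idx, gcodes)
            if np.any(mn != mx):
                raise ValueError(
                    f"sigma grouping variable {spec.sigma_grouping!r} is not "
                    "constant within co-occurrence sets; include it among the "
                    "set-defining variables"
                )
            cats = list(gcat.categories)
            order = np.argsort(cats)
            self.group_labels = [cats[i] for i in order]
            remap = np.empty(len(cats), dtype=np.int64)
            remap[order] = np.arange(len(cats))
            self.group_of_set = remap[mn]
        self.n_groups = len(self.group_labels)
        self.sets_per_group = np.bincount(self.group_of_set, minlength=self.n_groups)

        if spec.include_diet_pairing_re:
            dcat = pd.Categorical(records["diet_pairing"])
            self.diet_labels = list(dcat.categories)
            self.diet_idx = np.asarray(dcat.codes, dtype=np.int64)
            self.n_diet = len(self.diet_labels)
        else:
            self.diet_labels, self.diet_idx, self.n_diet = None, None, 0

        self.table = SupportTable(
            records["n_a"].to_numpy(),
            records["n_nota"].to_numpy(),
            records["n_b"].to_numpy(),
            records["n_ab"].to_numpy(),
        )
        self.uninformative = self.table.size == 1  # single-point supports, flagged

        # columns eligible for compensated moves: constant within every set
        self.comp_cols = []
        for j in range(1, self.X.shape[1]):
            col = self.X[:, j]
            mn = np.full(self.n_sets, np.inf)
            mx = np.full(self.n_sets, -np.inf)
            np.minimum.at(mn, self.set_idx, col)
            np.maximum.at(mx, self.set_idx, col)
            if np.allclose(mn, mx):
                self.comp_cols.append((j, mn.copy()))
        self.comp_cols.insert(0, (0, np.ones(self.n_sets)))  # intercept always

    def theta(self, beta, u, v=None) -> np.ndarray:
        th = self.X @ beta + u[self.set_idx]
        if v is not None and self.diet_idx is not None:
            th = th + v[self.diet_idx]
        return th


def build_design(records: pd.DataFrame, spec: ModelSpec) -> Design:
    return Design(records, spec)


def linear_predictor(records: pd.DataFrame, spec: ModelSpec, beta, u=None, v=None):
    """theta for each pair record given coefficient values.

    ``beta`` maps design-column names (e.g. ``(Intercept)``,
    ``std_phylo_distance``, ``guild_overlap[medium]``) to values; ``u``
    maps set IDs to intercepts (0 when omitted) and ``v`` maps diet-pairing
    labels likewise.
    """
    design = Design(records, spec)
    bvec = np.zeros(len(design.beta_names))
    beta = dict(beta)
    for name, val in beta.items():
        if name not in design.beta_names:
            raise KeyError(f"unknown coefficient {name!r}; have {design.beta_names}")
        bvec[design.beta_names.index(name)] = val
    uvec = np.zeros(design.n_sets)
    if u:
        for sid, val in u.items():
            if sid not in design.set_labels:
                raise KeyError(f"unknown set_id {sid!r}")
            uvec[design.set_labels.index(sid)] = val
    th = design.X @ bvec + uvec[design.set_idx]
    if v:
        if design.diet_idx is None:
            raise ValueError("spec does not include a diet-pairing random effect")
        vvec = np.zeros(design.n_diet)
        for lab, val in v.items():
            if lab not in design.diet_labels:
                raise KeyError(f"unknown diet pairing {lab!r}")
            vvec[design.diet_labels.index(lab)] = val
        th = th + vvec[design.diet_idx]
    return th


def model_loglik(records: pd.DataFrame, theta) -> np.ndarray:
    """Pointwise NHD log-likelihood of each pair's observed count at its theta."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        bad = int(np.flatnonzero(~np.isfinite(theta))[0])
        raise ValueError(f"non-finite theta for pair index {bad}")
    table = SupportTable(
        records["n_a"].to_numpy(),
        records["n_nota"].to_numpy(),
        records["n_b"].to_numpy(),
        records["n_ab"].to_numpy(),
    )
    return table.loglik(theta)


def _half_t_logpdf(x, df, scale):
    """log density of a half-Student-t(df, 0, scale); array-friendly."""
    x = np.asarray(x, float)
    const = (
        np.log(2.0)
        + gammaln((df + 1) / 2)
        - gammaln(df / 2)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
    )
    out = const - (df + 1) / 2 * np.log1p((x / scale) ** 2 / df)
    out = np.where(x > 0, out, -np.inf)
    return float(out) if out.ndim == 0 else out


def log_posterior(records, spec, beta, u, sigma, priors=Priors(), v=None, sigma_v=None):
    """Joint log posterior density (up to a constant) at one parameter point."""
    design = records if isinstance(records, Design) else Design(records, spec)
    beta = np.asarray(beta, float)
    u = np.asarray(u, float)
    sigma = np.asarray(sigma, float)
    th = design.theta(beta, u, None if v is None else np.asarray(v, float))
    lp = float(design.table.loglik(th).sum())
    lp += float(-0.5 * np.sum(beta**2) / priors.beta_sd**2
                - len(beta) * np.log(priors.beta_sd))
    sg = sigma[design.group_of_set]
    lp += float(np.sum(-0.5 * (u / sg) ** 2 - np.log(sg)))
    lp += float(sum(_half_t_logpdf(s, priors.sigma_df, priors.sigma_scale) for s in sigma))
    if v is not None:
        v = np.asarray(v, float)
        lp += float(np.sum(-0.5 * (v / sigma_v) ** 2 - np.log(sigma_v)))
        lp += _half_t_logpdf(float(sigma_v), priors.sigma_df, priors.sigma_scale)
    return lp


@dataclass
class PosteriorFit:
    """Retained MCMC draws plus convergence diagnostics."""

    spec: ModelSpec
    beta_names: list
    set_labels: list
    group_labels: list
    beta: np.ndarray  # (chains, keep, p)
    u: np.ndarray  # (chains, keep, n_sets)
    sigma: np.ndarray  # (chains, keep, n_groups)
    v: np.ndarray | None
    sigma_v: np.ndarray | None
    diet_labels: list | None
    pointwise_loglik: np.ndarray | None  # (chains*keep, n_pairs)
    rhat: dict
    config: MCMCConfig
    priors: Priors
    seed: int
    accept_rates: dict
    n_uninformative_pairs: int = 0

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, arr.shape[-1])

    def param_table(self) -> dict:
        """Flattened draws per scalar parameter name."""
        out = {}
        for j, nm in enumerate(self.beta_names):
            out[f"beta[{nm}]"] = self.flat("beta")[:, j]
        for g, nm in enumerate(self.group_labels):
            out[f"sigma[{nm}]"] = self.flat("sigma")[:, g]
        if self.v is not None:
            out["sigma_diet"] = self.sigma_v.reshape(-1)
        return out


def gelman_rubin(chains: np.ndarray, *, split: bool = True, rank_normalize: bool = False):
    """Gelman-Rubin potential scale reduction R-hat for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws). By default each chain is split
    in half (split-R-hat), which also detects within-chain trends; set
    ``rank_normalize`` for the rank-normalized variant that is robust to
    heavy tails. Identical chains give R-hat ~= 1.
    """
    x = np.asarray(chains, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    if rank_normalize:
        from scipy.stats import norm, rankdata

        r = rankdata(x, axis=None).reshape(x.shape)
        x = norm.ppf((r - 0.375) / (x.size + 0.25))
    m, n = x.shape
    chain_means = x.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = x.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _robbins_monro(scale, accepted, target, it, c0=1.0, decay=0.6):
    return scale * np.exp(c0 / (it + 1) ** decay * (accepted - target))


def _run_chain(design: Design, priors: Priors, cfg: MCMCConfig, seed: int):
    rng = np.random.default_rng(seed)
    p = design.X.shape[1]
    n_sets, n_groups = design.n_sets, design.n_groups
    table = design.table
    group_of_pair = design.group_of_set[design.set_idx]

    beta = np.zeros(p)
    u = np.zeros(n_sets)
    log_sig = np.full(n_groups, np.log(0.5))
    has_v = design.diet_idx is not None
    v = np.zeros(design.n_diet) if has_v else None
    log_sig_v = np.log(0.5) if has_v else None

    s_beta = 0.1  # scalar scale on the adaptive joint proposal
    chol = np.eye(p)
    warm_hist = []
    s_u = np.full(n_sets, 0.5)
    s_sig = np.full(n_groups, 0.3)
    s_scale = np.full(n_groups, 0.3)
    s_comp = np.full(len(design.comp_cols), 0.3)
    s_v = np.full(design.n_diet, 0.5) if has_v else None
    s_sigv = 0.3

    theta = design.theta(beta, u, v)
    ll = table.loglik(theta)

    keep = cfg.n_keep_per_chain
    out_beta = np.empty((keep, p))
    out_u = np.empty((keep, n_sets))
    out_sig = np.empty((keep, n_groups))
    out_v = np.empty((keep, design.n_diet)) if has_v else None
    out_sigv = np.empty(keep) if has_v else None
    out_ll = np.empty((keep, table.n_pairs)) if cfg.store_loglik else None

    acc = {"beta": 0.0, "u": 0.0, "sigma": 0.0, "comp": 0.0, "scale": 0.0}
    n_after = 0
    bsd2 = priors.beta_sd**2
    k = 0
    for it in range(cfg.steps):
        warm = it < cfg.warmup
        sigma = np.exp(log_sig)
        sig_of_set = sigma[design.group_of_set]

        # --- joint fixed-effect update (adaptive covariance) ------------
        delta = s_beta * (chol @ rng.normal(size=p))
        th_new = theta + design.X @ delta
        ll_new = table.loglik(th_new)
        beta_new = beta + delta
        dlp = (ll_new.sum() - ll.sum()) - 0.5 * (
            np.sum(beta_new**2) - np.sum(beta**2)
        ) / bsd2
        a_b = np.log(rng.random()) < dlp
        if a_b:
            beta, theta, ll = beta_new, th_new, ll_new
        if warm:
            s_beta = float(_robbins_monro(s_beta, float(a_b), 0.3, it))
            warm_hist.append(beta.copy())
            if it >= cfg.warmup // 2 and it % 100 == 0 and len(warm_hist) > 50:
                cov = np.cov(np.asarray(warm_hist[-500:]).T) + 1e-8 * np.eye(p)
                chol = np.linalg.cholesky(cov) if p > 1 else np.sqrt(cov).reshape(1, 1)
        else:
            acc["beta"] += float(a_b)

        # --- compensated location moves (likelihood-invariant) ----------
        # theta = X beta + u[set] is exactly unchanged (the column equals
        # its per-set value), so neither theta nor ll needs recomputation.
        acc_c = np.zeros(len(design.comp_cols))
        for ci, (j, xs) in enumerate(design.comp_cols):
            delta = rng.normal(0.0, s_comp[ci])
            u_new = u - delta * xs
            dlp = (
                -0.5 * ((beta[j] + delta) ** 2 - beta[j] ** 2) / bsd2
                - 0.5 * np.sum((u_new**2 - u**2) / sig_of_set**2)
            )
            if np.log(rng.random()) < dlp:
                beta[j] += delta
                u = u_new
                acc_c[ci] = 1.0
        if warm:
            s_comp = _robbins_monro(s_comp, acc_c, 0.44, it)
        else:
            acc["comp"] += acc_c.mean()

        # --- set intercepts, vectorised componentwise -------------------
        delta = rng.normal(0.0, s_u)
        th_new = theta + delta[design.set_idx]
        ll_new = table.loglik(th_new)
        dll_set = np.bincount(design.set_idx, ll_new - ll, minlength=n_sets)
        u_new = u + delta
        dprior = -0.5 * (u_new**2 - u**2) / sig_of_set**2
        accept = np.log(rng.random(n_sets)) < dll_set + dprior
        u = np.where(accept, u_new, u)
        acc_pair = accept[design.set_idx]
        theta = np.where(acc_pair, th_new, theta)
        ll = np.where(acc_pair, ll_new, ll)
        if warm:
            s_u = _robbins_monro(s_u, accept.astype(float), 0.44, it)
        else:
            acc["u"] += accept.mean()

        # --- group scale moves: u_g -> u_g * e^d, log sigma_g += d ------
        # The Normal(u | 0, sigma) terms cancel against the proposal
        # Jacobian, so sigma is moved by the likelihood directly; this
        # breaks the slow coupling of the centered parameterization.
        d_g = rng.normal(0.0, s_scale)
        factor = np.exp(d_g)
        u_new = u * factor[design.group_of_set]
        th_new = theta + (u_new - u)[design.set_idx]
        ll_new = table.loglik(th_new)
        dll_grp = np.bincount(group_of_pair, ll_new - ll, minlength=n_groups)
        sig_new = sigma * factor
        dprior = (
            _half_t_logpdf(sig_new, priors.sigma_df, priors.sigma_scale)
            - _half_t_logpdf(sigma, priors.sigma_df, priors.sigma_scale)
            + d_g  # Jacobian of the log-sigma parameterization
        )
        accept = np.log(rng.random(n_groups)) < dll_grp + dprior
        if np.any(accept):
            acc_set = accept[design.group_of_set]
            u = np.where(acc_set, u_new, u)
            log_sig = np.where(accept, log_sig + d_g, log_sig)
            acc_pair = accept[group_of_pair]
            theta = np.where(acc_pair, th_new, theta)
            ll = np.where(acc_pair, ll_new, ll)
            sigma = np.exp(log_sig)
            sig_of_set = sigma[design.group_of_set]
        if warm:
            s_scale = _robbins_monro(s_scale, accept.astype(float), 0.44, it)
        else:
            acc["scale"] += accept.mean()

        # --- diet-pairing intercepts ------------------------------------
        if has_v:
            sv = np.exp(log_sig_v)
            delta = rng.normal(0.0, s_v)
            th_new = theta + delta[design.diet_idx]
            ll_new = table.loglik(th_new)
            dll_d = np.bincount(design.diet_idx, ll_new - ll, minlength=design.n_diet)
            v_new = v + delta
            dprior = -0.5 * (v_new**2 - v**2) / sv**2
            accept = np.log(rng.random(design.n_diet)) < dll_d + dprior
            v = np.where(accept, v_new, v)
            acc_pair = accept[design.diet_idx]
            theta = np.where(acc_pair, th_new, theta)
            ll = np.where(acc_pair, ll_new, ll)
            if warm:
                s_v = _robbins_monro(s_v, accept.astype(float), 0.44, it)
            # sigma_v random walk on log scale
            lsv_new = log_sig_v + rng.normal(0.0, s_sigv)
            sv_new = np.exp(lsv_new)
            dlp = (
                -0.5 * np.sum(v**2) * (1 / sv_new**2 - 1 / sv**2)
                - design.n_diet * (lsv_new - log_sig_v)
                + _half_t_logpdf(sv_new, priors.sigma_df, priors.sigma_scale)
                - _half_t_logpdf(sv, priors.sigma_df, priors.sigma_scale)
                + (lsv_new - log_sig_v)  # Jacobian of log parameterization
            )
            a = np.log(rng.random()) < dlp
            if a:
                log_sig_v = lsv_new
            if warm:
                s_sigv = float(_robbins_monro(s_sigv, float(a), 0.44, it))

        # --- group standard deviations, conditional on u ----------------
        u_sq_by_group = np.bincount(design.group_of_set, u**2, minlength=n_groups)
        ls_new = log_sig + rng.normal(0.0, s_sig)
        s_old, s_new = np.exp(log_sig), np.exp(ls_new)
        dls = ls_new - log_sig
        dlp = (
            -0.5 * u_sq_by_group * (1 / s_new**2 - 1 / s_old**2)
            - design.sets_per_group * dls
            + _half_t_logpdf(s_new, priors.sigma_df, priors.sigma_scale)
            - _half_t_logpdf(s_old, priors.sigma_df, priors.sigma_scale)
            + dls
        )
        acc_s = np.log(rng.random(n_groups)) < dlp
        log_sig = np.where(acc_s, ls_new, log_sig)
        if warm:
            s_sig = _robbins_monro(s_sig, acc_s.astype(float), 0.44, it)
        else:
            acc["sigma"] += acc_s.mean()
            n_after += 1

        if not warm and (it - cfg.warmup) % cfg.thin == 0 and k < keep:
            out_beta[k] = beta
            out_u[k] = u
            out_sig[k] = np.exp(log_sig)
            if has_v:
                out_v[k] = v
                out_sigv[k] = np.exp(log_sig_v)
            if cfg.store_loglik:
                out_ll[k] = ll
            k += 1

    for key in acc:
        acc[key] /= max(n_after, 1)
    return out_beta, out_u, out_sig, out_v, out_sigv, out_ll, acc


def fit_mcm(
    records: pd.DataFrame,
    spec: ModelSpec,
    *,
    mcmc: MCMCConfig = MCMCConfig(),
    priors: Priors = Priors(),
    seed: int = 0,
) -> PosteriorFit:
    """Fit the mixed-effects co-occurrence model by MCMC.

    Deterministic under a fixed seed: chain c uses a child seed spawned from
    ``(seed, c)``. Pairs whose support has a single point contribute zero
    log-likelihood (their count is forced by the margins); they are retained
    but counted in ``n_uninformative_pairs``.
    """
    if len(records) == 0:
        raise ValueError("no pair records to fit")
    design = Design(records, spec)
    chains = []
    for c in range(mcmc.chains):
        child = int(np.random.SeedSequence([int(seed), c]).generate_state(1)[0] % (2**31))
        chains.append(_run_chain(design, priors, mcmc, child))

    def stack(i):
        if chains[0][i] is None:
            return None
        return np.stack([ch[i] for ch in chains])

    beta, u, sig = stack(0), stack(1), stack(2)
    v, sigv = stack(3), stack(4)
    ll = None
    if mcmc.store_loglik:
        ll = np.concatenate([ch[5] for ch in chains], axis=0)

    rhat = {}
    if mcmc.chains >= 2:
        for j, nm in enumerate(design.beta_names):
            rhat[f"beta[{nm}]"] = gelman_rubin(beta[:, :, j])
        for g, nm in enumerate(design.group_labels):
            rhat[f"sigma[{nm}]"] = gelman_rubin(sig[:, :, g])
        if v is not None:
            rhat["sigma_diet"] = gelman_rubin(sigv)
        worst = max(rhat.values())
        if worst > mcmc.rhat_warn:
            warnings.warn(
                f"possible non-convergence: max R-hat {worst:.3f} > {mcmc.rhat_warn}",
                stacklevel=2,
            )

    acc = {
        key: float(np.mean([ch[6][key] for ch in chains])) for key in chains[0][6]
    }
    return PosteriorFit(
        spec=spec,
        beta_names=design.beta_names,
        set_labels=design.set_labels,
        group_labels=design.group_labels,
        beta=beta,
        u=u,
        sigma=sig,
        v=v,
        sigma_v=sigv,
        diet_labels=design.diet_labels,
        pointwise_loglik=ll,
        rhat=rhat,
        config=mcmc,
        priors=priors,
        seed=int(seed),
        accept_rates=acc,
        n_uninformative_pairs=int(design.uninformative.sum()),
    )


def posterior_summary(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior means and central 95% credible intervals per parameter."""
    rows = []
    for name, draws in fit.param_table().items():
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(draws.mean()),
                "sd": float(draws.std(ddof=1)) if len(draws) > 1 else 0.0,
                "q2.5": float(lo),
                "q97.5": float(hi),
                "rhat": fit.rhat.get(name, np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
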