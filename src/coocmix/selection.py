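"""ELPD model comparison and two-step structure selection.

The expected log pointwise predictive density (ELPD) measures out-of-sample
prediction accuracy and is estimated from the posterior pointwise
log-likelihood matrix by Pareto-smoothed importance sampling leave-one-out
cross-validation (PSIS-LOO). Model pairs are compared through the ELPD
difference ``delta_e`` and its standard error ``s_delta`` computed from the
pointwise differences; the ratio ``z_delta = delta_e / s_delta`` is an
informal evidence score, not a formal test (the pairwise co-occurrence data
reuse every species in many pairs, so independence assumptions fail).

Structure selection is two-step: first pick the random-effects structure
with the full fixed-effects structure in place, then pick the fixed-effects
structure with the chosen random structure held fixed, maximizing ELPD at
each step.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import MCMCConfig, ModelSpec, Priors, PosteriorFit, fit_mcm

__all__ = [
    "ElpdResult",
    "ElpdComparison",
    "elpd_psis_loo",
    "compare_models",
    "select_structure",
    "nested_term_zscores",
    "default_random_candidates",
    "default_fixed_candidates",
]


@dataclass
class ElpdResult:
    elpd: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray

    @property
    def n(self) -> int:
        return len(self.pointwise)


@dataclass
class ElpdComparison:
    elpd_a: float
    elpd_b: float
    se_a: float
    se_b: float
    delta_e: float  # ELPD_a - ELPD_b (full minus nested by convention)
    se_delta: float
    z_delta: float
    degenerate: bool = False
    pareto_k_a: np.ndarray | None = None
    pareto_k_b: np.ndarray | None = None


def elpd_psis_loo(pointwise_loglik: np.ndarray) -> ElpdResult:
    """PSIS-LOO ELPD from a (draws, pairs) pointwise log-likelihood matrix.

    Importance ratios are the reciprocal likelihoods; the largest ~20% of
    ratios per observation are smoothed by a generalized-Pareto tail fit
    (delegated to ``arviz.psislw``). Pareto shape values > 0.7 indicate an
    unreliable importance-sampling estimate for that observation. A
    degenerate posterior (identical draws) falls back to the plain
    pointwise log-likelihood with a warning.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be a (draws, pairs) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise_loglik contains non-finite entries")
    n_draws, n_obs = ll.shape
    if np.allclose(ll.max(axis=0), ll.min(axis=0)):
        warnings.warn("degenerate posterior draws; returning plain pointwise log-lik")
        pw = ll[0].copy()
        se = float(np.sqrt(n_obs * pw.var(ddof=0))) if n_obs > 1 else 0.0
        return ElpdResult(float(pw.sum()), se, pw, np.zeros(n_obs))

    from arviz.stats import psislw
    from scipy.special import logsumexp

    lw, k = psislw(-ll.T)  # arviz expects (n_obs, n_draws)
    lw, k = np.asarray(lw), np.asarray(k)
    pw = logsumexp(lw + ll.T, axis=1)
    se = float(np.sqrt(n_obs * pw.var(ddof=0)))
    n_bad = int((k > 0.7).sum())
    if n_bad:
        warnings.warn(f"{n_bad} observations with Pareto k > 0.7; LOO may be unreliable")
    return ElpdResult(float(pw.sum()), se, pw, k)


def loo_from_fit(fit: PosteriorFit) -> ElpdResult:
    if fit.pointwise_loglik is None:
        raise ValueError("fit was run without store_loglik")
    return elpd_psis_loo(fit.pointwise_loglik)


def compare_models(loo_a: ElpdResult, loo_b: ElpdResult) -> ElpdComparison:
    """ELPD comparison a (full) vs b (nested) from pointwise vectors.

    ``delta_e`` is the sum of pointwise differences; ``se_delta`` the
    standard error of that sum; ``z_delta`` their ratio (0 with a
    degeneracy flag when the two models are pointwise identical).
    """
    if loo_a.n != loo_b.n:
        raise ValueError(f"mismatched pair sets: {loo_a.n} vs {loo_b.n} observations")
    d = loo_a.pointwise - loo_b.pointwise
    delta = float(d.sum())
    se_delta = float(np.sqrt(len(d) * d.var(ddof=0)))
    if se_delta == 0.0:
        return ElpdComparison(
            loo_a.elpd, loo_b.elpd, loo_a.se, loo_b.se,
            delta, 0.0, 0.0, degenerate=True,
            pareto_k_a=loo_a.pareto_k, pareto_k_b=loo_b.pareto_k,
        )
    return ElpdComparison(
        loo_a.elpd, loo_b.elpd, loo_a.se, loo_b.se,
        delta, se_delta, delta / se_delta,
        pareto_k_a=loo_a.pareto_k, pareto_k_b=loo_b.pareto_k,
    )


FULL_FIXED = (
    "std_phylo_distance",
    "guild_overlap",
    "habitat",
    "std_phylo_distance:guild_overlap",
    "std_phylo_distance:habitat",
    "guild_overlap:habitat",
)


def default_random_candidates(
    base_set_vars=("occupancy_pairing", "phylo_bin", "diet_pairing", "habitat"),
    *,
    include_diet_re: bool = False,
) -> list[ModelSpec]:
    """Reconstruction of the named random-structure catalogue.

    Varies the random-effect SD grouping (constant / by guild overlap / by
    habitat) on a fixed set definition, with the full fixed structure; the
    full supplementary candidate lists are user-overridable.
    """
    specs = []
    for grouping in ("constant", "guild_overlap", "habitat"):
        set_vars = tuple(base_set_vars)
        if grouping != "constant" and grouping not in set_vars:
            set_vars = set_vars + (grouping,)
        specs.append(
            ModelSpec(
                fixed_terms=FULL_FIXED,
                set_defining_vars=set_vars,
                sigma_grouping=grouping,
            )
        )
        if include_diet_re:
            specs.append(replace(specs[-1], include_diet_pairing_re=True))
    return specs


def default_fixed_candidates(random_spec: ModelSpec) -> list[ModelSpec]:
    """All main-effect subsets plus hierarchy-respecting interaction add-ons."""
    mains = ("std_phylo_distance", "guild_overlap", "habitat")
    specs = []
    for r in range(len(mains) + 1):
        for combo in itertools.combinations(mains, r):
            specs.append(replace(random_spec, fixed_terms=combo))
    # interactions only on top of all three mains, pairwise
    for inter in (
        ("std_phylo_distance:guild_overlap",),
        ("std_phylo_distance:habitat",),
        ("guild_overlap:habitat",),
    ):
        specs.append(replace(random_spec, fixed_terms=mains + inter))
    return specs


@dataclass
class SelectionResult:
    best_spec: ModelSpec
    best_fit: PosteriorFit
    trace: pd.DataFrame
    loos: dict | None = None  # (step, model label) -> ElpdResult


def _complexity(spec: ModelSpec) -> int:
    """Crude parameter count used by the parsimony rule."""
    n_beta = 1
    sizes = {"std_phylo_distance": 1, "guild_overlap": 2, "habitat": 1}
    for term in spec.fixed_terms:
        k = 1
        for part in term.split(":"):
            k *= sizes[part]
        n_beta += k
    n_sigma = {"constant": 1, "guild_overlap": 3, "habitat": 2}[spec.sigma_grouping]
    return n_beta + n_sigma + (1 if spec.include_diet_pairing_re else 0)


def _pick(results, parsimony_se: float):
    """Highest-ELPD candidate, or with ``parsimony_se`` > 0 the simplest
    candidate whose ELPD is within that many pairwise standard errors of
    the best (the one-standard-error rule of cross-validation practice;
    plain ELPD maximization overfits nested comparisons, whose ELPD
    penalty for a superfluous term is comparable to its own SE)."""
    best = max(results, key=lambda r: r[2].elpd)
    if parsimony_se <= 0:
        return best
    eligible = []
    for r in results:
        if r is best:
            eligible.append(r)
            continue
        cmp_ = compare_models(best[2], r[2])
        if cmp_.delta_e <= parsimony_se * cmp_.se_delta:
            eligible.append(r)
    return min(eligible, key=lambda r: (_complexity(r[0]), -r[2].elpd))


def select_structure(
    records: pd.DataFrame,
    candidate_random_specs: list[ModelSpec],
    candidate_fixed_specs=None,
    *,
    mcmc: MCMCConfig = MCMCConfig(),
    priors: Priors = Priors(),
    seed: int = 0,
    parsimony_se: float = 1.0,
) -> SelectionResult:
    """Two-step ELPD structure selection.

    Step 1 fits every candidate random structure (each carrying the full
    fixed structure) and keeps the winner; step 2 varies the fixed
    structure on that random structure. ``candidate_fixed_specs`` may be a
    callable (random spec -> list of specs) or an explicit list; by default
    all main-effect subsets and pairwise interactions are tried. The winner
    at each step maximizes ELPD, moderated by the one-standard-error
    parsimony rule (``parsimony_se=0`` recovers plain maximization).
    Candidates whose fit fails are recorded, excluded and warned about.
    """
    if not candidate_random_specs:
        raise ValueError("candidate_random_specs is empty")
    if candidate_fixed_specs is None:
        candidate_fixed_specs = default_fixed_candidates

    rows = []
    loos = {}
    counter = itertools.count()

    def run(spec, step):
        i = next(counter)
        fit_seed = int(np.random.SeedSequence([int(seed), 7, i]).generate_state(1)[0] % (2**31))
        try:
            fit = fit_mcm(records, spec, mcmc=mcmc, priors=priors, seed=fit_seed)
            loo = loo_from_fit(fit)
        except Exception as exc:  # noqa: BLE001 - failures recorded, not fatal
            warnings.warn(f"candidate {spec.label()} failed: {exc}")
            rows.append(
                {"step": step, "model": spec.label(), "elpd": np.nan, "se": np.nan,
                 "seed": fit_seed, "status": f"failed: {exc}"}
            )
            return None
        rows.append(
            {"step": step, "model": spec.label(), "elpd": loo.elpd, "se": loo.se,
             "seed": fit_seed, "status": "ok"}
        )
        loos[(step, spec.label())] = loo
        return spec, fit, loo

    step1 = [r for r in (run(s, 1) for s in candidate_random_specs) if r is not None]
    if not step1:
        raise RuntimeError("all random-structure candidates failed")
    best_random = _pick(step1, parsimony_se)

    fixed_list = (
        candidate_fixed_specs(best_random[0])
        if callable(candidate_fixed_specs)
        else list(candidate_fixed_specs)
    )
    step2 = [r for r in (run(s, 2) for s in fixed_list) if r is not None]
    if not step2:
        raise RuntimeError("all fixed-structure candidates failed")
    best = _pick(step2, parsimony_se)

    trace = pd.DataFrame(rows)
    trace["delta_vs_best"] = trace["elpd"] - best[2].elpd
    return SelectionResult(best_spec=best[0], best_fit=best[1], trace=trace,
                           loos=loos)


def _droppable_terms(fixed_terms):
    """Fixed terms removable without breaking marginality (interactions first)."""
    terms = list(fixed_terms)
    out = []
    for t in terms:
        if ":" in t:
            out.append(t)
        else:
            in_interaction = any(
                ":" in other and t in other.split(":") for other in terms
            )
            if not in_interaction:
                out.append(t)
    return out


def nested_term_zscores(
    records: pd.DataFrame,
    best_spec: ModelSpec,
    best_fit: PosteriorFit,
    *,
    mcmc: MCMCConfig = MCMCConfig(),
    priors: Priors = Priors(),
    seed: int = 0,
) -> pd.DataFrame:
    """z(delta-ELPD) of the final model against each one-term-poorer model.

    One comparison per removable fixed term (interactions are removed
    before the main effects they contain) plus, when the random-effect SD
    varies among groups, one against the constant-SD model.
    """
    loo_full = loo_from_fit(best_fit)
    rows = []
    nested = [
        (f"- {t}", replace(best_spec, fixed_terms=tuple(x for x in best_spec.fixed_terms if x != t)))
        for t in _droppable_terms(best_spec.fixed_terms)
    ]
    if best_spec.sigma_grouping != "constant":
        rows_spec = replace(best_spec, sigma_grouping="constant")
        nested.append(("sigma -> constant", rows_spec))
    for i, (label, spec) in enumerate(nested):
        fit_seed = int(np.random.SeedSequence([int(seed), 11, i]).generate_state(1)[0] % (2**31))
        fit = fit_mcm(records, spec, mcmc=mcmc, priors=priors, seed=fit_seed)
        cmp_ = compare_models(loo_full, loo_from_fit(fit))
        rows.append(
            {"dropped": label, "delta_e": cmp_.delta_e, "se_delta": cmp_.se_delta,
             "z_delta": cmp_.z_delta}
        )
    return pd.DataFrame(rows)
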