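"""Mixed-model analyses of trial-level behavior and model accuracy, plus
the behavioral preprocessing rules.

Behavioral tables are trial-level: one row per participant x trial with a
binary ``correct`` score and a reaction time.  Preprocessing applies the
participant-level exclusion rules (a minimum-accuracy rule and a
20%-out-of-range reaction-time rule), drops individual out-of-range
trials, and caps learning-phase rows at the first 36 repetitions per
stimulus role so the doubled prototype frequency does not dominate the
fit.

Two fitters are provided:

* :func:`fit_behavioral_glme` — binomial logistic regression with a
  participant random intercept, estimated by maximum likelihood with
  adaptive-free Gauss–Hermite quadrature over the random effect (the
  per-participant likelihood factorizes, so a one-dimensional quadrature
  is exact up to the node count).  Wald standard errors come from the
  numerical Hessian of the marginal log-likelihood.
* :func:`fit_model_accuracy_lmm` — linear mixed model (batch random
  intercept) on the continuous Luce-choice accuracies of the network
  ensembles, via ``statsmodels`` ``MixedLM``.  Model accuracy lives on
  [0, 1] and the effects of interest are small mean shifts on that scale,
  so an identity-link Gaussian model is the default; a logit-transformed
  sensitivity fit is available behind a flag.

Reference levels are chosen so single coefficients answer the questions
of interest: the role reference is ``exception`` and the condition
reference ``early``, making the plain condition coefficient the
delayed-vs-early effect *for exceptions*; the exceptions-only contrast
set uses category reference ``B`` so the condition coefficient is the
category-B exception's condition effect and the interaction is the
A-minus-B difference of condition effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import optimize, special, stats as sps

__all__ = [
    "ExclusionReport",
    "FitResult",
    "SeparationWarning",
    "add_repetition",
    "preprocess_behavior",
    "fit_behavioral_glme",
    "fit_model_accuracy_lmm",
]

REQUIRED_COLUMNS = (
    "participant_id", "condition", "block", "trial_index", "stimulus_id",
    "role", "category", "correct", "rt",
)

RT_RANGE = (0.15, 2.0)
RT_VIOLATION_FRACTION = 0.20
ACCURACY_CRITERION = 0.75
LEARNING_REPETITION_CAP = 36


class SeparationWarning(UserWarning):
    """Signals (quasi-)complete separation in a logistic fit: some cell is
    perfectly predicted and the corresponding coefficient diverges."""


@dataclass(frozen=True)
class ExclusionReport:
    excluded_participants: tuple[tuple[str, str], ...]  # (participant_id, reason)
    n_trials_dropped_rt: int
    n_trials_dropped_repetition: int
    n_participants_in: int
    n_participants_out: int

    def __str__(self) -> str:  # human-readable summary
        lines = [f"participants: {self.n_participants_in} -> {self.n_participants_out}"]
        for pid, reason in self.excluded_participants:
            lines.append(f"  excluded {pid}: {reason}")
        lines.append(f"trials dropped (RT range): {self.n_trials_dropped_rt}")
        lines.append(f"learning trials dropped (repetition cap): {self.n_trials_dropped_repetition}")
        return "\n".join(lines)


@dataclass(frozen=True)
class FitResult:
    """Coefficient table and metadata of one mixed-model fit."""

    terms: tuple[str, ...]
    estimates: np.ndarray
    std_errors: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    random_effect_sd: float
    bic: float
    model_info: Mapping[str, str] = field(default_factory=dict)
    cov: np.ndarray | None = None

    def coef(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.std_errors[self.terms.index(term)])

    def contrast(self, weights: Mapping[str, float]) -> tuple[float, float]:
        """Estimate and SE of a linear combination of coefficients."""
        if self.cov is None:
            raise ValueError("fit carries no coefficient covariance")
        c = np.zeros(len(self.terms))
        for term, w in weights.items():
            c[self.terms.index(term)] = w
        return float(c @ self.estimates), float(np.sqrt(c @ self.cov @ c))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "estimate": self.estimates, "se": self.std_errors,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p_values,
        })

    def to_json(self) -> str:
        import json

        return json.dumps({
            "terms": list(self.terms),
            "estimates": self.estimates.tolist(),
            "std_errors": self.std_errors.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "p_values": self.p_values.tolist(),
            "random_effect_sd": self.random_effect_sd,
            "bic": self.bic,
            "model_info": dict(self.model_info),
        }, indent=2)


# ---------------------------------------------------------------------------
# preprocessing


def _validate_schema(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavioral table is missing columns {missing}")
    bad = table.index[~table["correct"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"non-binary 'correct' values at rows {bad[:5].tolist()}")
    bad = table.index[table["rt"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive reaction times at rows {bad[:5].tolist()}")


def add_repetition(table: pd.DataFrame) -> pd.DataFrame:
    """Add (or recompute) the ``repetition`` column: the 1-based count of
    appearances of each stimulus role within participant, in trial
    order (learning and test phases counted jointly)."""
    out = table.sort_values(["participant_id", "trial_index"], kind="stable").copy()
    out["repetition"] = out.groupby(["participant_id", "role"], observed=True).cumcount() + 1
    return out.sort_index() if table.index.is_monotonic_increasing else out


def preprocess_behavior(
    raw: pd.DataFrame,
    rt_range: tuple[float, float] = RT_RANGE,
    rt_violation_fraction: float = RT_VIOLATION_FRACTION,
    accuracy_criterion: float = ACCURACY_CRITERION,
    learning_repetition_cap: int | None = LEARNING_REPETITION_CAP,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the participant- and trial-level exclusion rules.

    A participant is excluded when (a) they never achieve accuracy above
    ``accuracy_criterion`` for any stimulus role in any learning or test
    block, or (b) more than ``rt_violation_fraction`` of their reaction
    times fall outside ``rt_range``.  Retained participants then lose
    individual out-of-range trials, and learning-phase rows beyond the
    first ``learning_repetition_cap`` repetitions of a role are dropped.
    The function is idempotent: re-applying it to its own output changes
    nothing.
    """
    _validate_schema(raw)
    table = raw if "repetition" in raw.columns else add_repetition(raw)

    lo, hi = rt_range
    excluded: list[tuple[str, str]] = []
    for pid, rows in table.groupby("participant_id", observed=True):
        block_acc = rows.groupby(["block", "role"], observed=True)["correct"].mean()
        if not (block_acc > accuracy_criterion).any():
            excluded.append((str(pid), f"accuracy never above {accuracy_criterion} "
                                       "for any stimulus type in any block"))
            continue
        out_of_range = ((rows["rt"] < lo) | (rows["rt"] > hi)).mean()
        if out_of_range > rt_violation_fraction:
            excluded.append((str(pid), f"{out_of_range:.0%} of reaction times outside "
                                       f"[{lo} s, {hi} s]"))
    bad_ids = {pid for pid, _ in excluded}
    kept = table[~table["participant_id"].astype(str).isin(bad_ids)]

    in_range = (kept["rt"] >= lo) & (kept["rt"] <= hi)
    n_rt_dropped = int((~in_range).sum())
    kept = kept[in_range]

    n_rep_dropped = 0
    if learning_repetition_cap is not None:
        over = (kept["phase"] == "learning") & (kept["repetition"] > learning_repetition_cap) \
            if "phase" in kept.columns else (kept["repetition"] > learning_repetition_cap)
        n_rep_dropped = int(over.sum())
        kept = kept[~over]

    report = ExclusionReport(
        excluded_participants=tuple(excluded),
        n_trials_dropped_rt=n_rt_dropped,
        n_trials_dropped_repetition=n_rep_dropped,
        n_participants_in=table["participant_id"].nunique(),
        n_participants_out=kept["participant_id"].nunique(),
    )
    return kept.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# binomial GLMM by Gauss-Hermite quadrature


def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    z, w = special.roots_hermite(n_nodes)
    return z * np.sqrt(2.0), w / np.sqrt(np.pi)


def _design(table: pd.DataFrame, formula_variant: str) -> tuple[np.ndarray, tuple[str, ...]]:
    if formula_variant == "base":
        f = "C(role, Treatment('exception')) * C(condition, Treatment('early'))"
    elif formula_variant == "with_repetition":
        f = ("C(role, Treatment('exception')) * C(condition, Treatment('early'))"
             " * centered_repetition")
        table = table.assign(centered_repetition=table["repetition"] - table["repetition"].mean())
    else:
        raise ValueError("formula_variant must be 'base' or 'with_repetition'")
    dm = dmatrix(f, table, return_type="dataframe")
    return np.asarray(dm), tuple(_clean_term(c) for c in dm.columns)


def _clean_term(name: str) -> str:
    return (name
            .replace("C(role, Treatment('exception'))", "role")
            .replace("C(condition, Treatment('early'))", "condition")
            .replace("C(category, Treatment('B'))", "category")
            .replace("[T.", "[").replace("]", "]"))


def fit_behavioral_glme(table: pd.DataFrame, formula_variant: str = "base",
                        n_quadrature: int = 25, ci: float = 0.95) -> FitResult:
    """Binomial logistic GLMM with a participant random intercept, by
    marginal maximum likelihood.

    The random intercept is integrated out per participant with
    ``n_quadrature``-node Gauss-Hermite quadrature; the fixed effects and
    the random-intercept SD are optimized jointly.  Returns Wald CIs and
    p-values plus the BIC computed from the marginal log-likelihood with
    the trial count as sample size.

    A :class:`SeparationWarning` is issued when a coefficient diverges,
    which happens with perfectly separated cells.
    """
    x, terms = _design(table, formula_variant)
    y = table["correct"].to_numpy(dtype=float)
    groups, group_idx = np.unique(table["participant_id"].to_numpy(), return_inverse=True)
    nodes, weights = _gh_nodes(n_quadrature)
    n_obs, q = x.shape
    n_groups = groups.size

    def neg_loglik_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta, log_sigma = theta[:q], theta[q]
        sigma = np.exp(log_sigma)
        eta0 = x @ beta  # (n_obs,)
        # (n_obs, K) linear predictors per node
        eta = eta0[:, None] + sigma * nodes[None, :]
        # log Bernoulli likelihood per obs/node, numerically safe
        ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
        ll_group = np.zeros((n_groups, nodes.size))
        np.add.at(ll_group, group_idx, ll_obs)
        m = ll_group.max(axis=1, keepdims=True)
        lik = np.exp(ll_group - m)  # (G, K)
        denom = lik @ weights
        loglik = float(np.sum(m[:, 0] + np.log(denom)))
        # gradient
        post = lik * weights[None, :] / denom[:, None]  # (G, K) posterior node weights
        resid = y[:, None] - special.expit(eta)  # (n_obs, K)
        w_obs = post[group_idx]  # (n_obs, K)
        g_beta = x.T @ (resid * w_obs).sum(axis=1)
        g_sigma = float(np.sum((resid * w_obs) * nodes[None, :]) * sigma)
        return -loglik, -np.concatenate([g_beta, [g_sigma]])

    theta0 = np.concatenate([np.zeros(q), [np.log(0.5)]])
    res = optimize.minimize(neg_loglik_and_grad, theta0, jac=True, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    if not res.success and np.linalg.norm(res.jac) > 1e-2:
        warnings.warn(f"GLME fit did not fully converge: {res.message} "
                      f"(|grad| = {np.linalg.norm(res.jac):.2e})", RuntimeWarning)

    theta = res.x
    hess = _numerical_hessian(lambda t: neg_loglik_and_grad(t)[1], theta)
    cov_all = _safe_inverse(hess)
    beta = theta[:q]
    cov = cov_all[:q, :q]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    if np.any(np.abs(beta) > 8.0) or np.any(~np.isfinite(se)) or np.any(se > 50.0):
        warnings.warn("coefficient estimates diverged; data are (quasi-)separable",
                      SeparationWarning)

    zcrit = sps.norm.ppf(0.5 + ci / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * sps.norm.sf(np.abs(zstat))
    loglik = -res.fun
    k_params = q + 1
    bic = -2.0 * loglik + k_params * np.log(n_obs)
    return FitResult(
        terms=terms, estimates=beta, std_errors=se,
        ci_low=beta - zcrit * se, ci_high=beta + zcrit * se, p_values=p,
        random_effect_sd=float(np.exp(theta[q])), bic=float(bic),
        model_info={"family": "binomial", "link": "logit",
                    "random_effects": "participant intercept",
                    "estimation": f"ML, {n_quadrature}-node Gauss-Hermite",
                    "formula_variant": formula_variant},
        cov=cov,
    )


def _numerical_hessian(grad, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = theta.size
    h = np.zeros((n, n))
    for i in range(n):
        step = np.zeros(n)
        step[i] = eps * max(1.0, abs(theta[i]))
        h[i] = (grad(theta + step) - grad(theta - step)) / (2 * step[i])
    return 0.5 * (h + h.T)


def _safe_inverse(h: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(h)


# ---------------------------------------------------------------------------
# model-accuracy mixed model


def fit_model_accuracy_lmm(table: pd.DataFrame, contrast_set: str = "overall",
                           logit_outcome: bool = False, ci: float = 0.95) -> FitResult:
    """Linear mixed model on end-of-learning network accuracies.

    ``contrast_set='overall'`` fits role x condition with exception/early
    references, so ``condition[delayed]`` is the condition effect for
    exceptions.  ``contrast_set='exceptions_by_category'`` restricts to
    the two exception stimuli and fits category x condition with the
    category-B reference, so ``condition[delayed]`` is the category-B
    exception's condition effect and the interaction the A-minus-B
    difference.  Batch is the random intercept in both cases.

    ``logit_outcome`` refits on logit-transformed accuracy (clipped away
    from 0/1) as a sensitivity check; coefficients are then on the
    log-odds scale.
    """
    import statsmodels.formula.api as smf

    data = table.copy()
    if contrast_set == "overall":
        formula = ("accuracy ~ C(role, Treatment('exception')) * "
                   "C(condition, Treatment('early'))")
    elif contrast_set == "exceptions_by_category":
        data = data[data["role"] == "exception"].copy()
        formula = ("accuracy ~ C(category, Treatment('B')) * "
                   "C(condition, Treatment('early'))")
    else:
        raise ValueError("contrast_set must be 'overall' or 'exceptions_by_category'")
    if logit_outcome:
        eps = 1e-6
        data["accuracy"] = np.log(data["accuracy"].clip(eps, 1 - eps)
                                  / (1 - data["accuracy"].clip(eps, 1 - eps)))

    # near-zero between-batch variance can make the default optimizer's
    # Hessian singular; fall back to derivative-free methods
    fit = None
    last_err: Exception | None = None
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data, groups=data["batch"])
                fit = model.fit(reml=False, method=method)
            break
        except np.linalg.LinAlgError as err:
            last_err = err
    if fit is None:
        raise RuntimeError(f"mixed-model fit failed with every optimizer: {last_err}")
    fe = fit.fe_params
    terms = tuple(_clean_term(t) for t in fe.index)
    est = fe.to_numpy()
    se = fit.bse_fe.to_numpy()
    zcrit = sps.norm.ppf(0.5 + ci / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    re_sd = float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0)))
    bic = float(-2 * fit.llf + (len(est) + 2) * np.log(len(data)))
    cov = np.asarray(fit.cov_params())[: len(est), : len(est)]
    return FitResult(
        terms=terms, estimates=est, std_errors=se,
        ci_low=est - zcrit * se, ci_high=est + zcrit * se, p_values=p,
        random_effect_sd=re_sd, bic=bic,
        model_info={"family": "gaussian", "link": "identity",
                    "random_effects": "batch intercept",
                    "contrast_set": contrast_set,
                    "outcome": "logit(accuracy)" if logit_outcome else "accuracy"},
        cov=cov,
    )
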