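"""Nested mixed-effects contrasts for per-focus / per-nucleus measurements.

Foci measurements are nested: foci within nuclei, nuclei within samples
(individual images), samples within experiments (batches).  Treatment
comparisons (e.g. si-circRNA vs si-linear vs si-NTC) must account for that
hierarchy, or pseudo-replication across hundreds of nuclei inflates
significance.  Two model families are provided:

* Gaussian linear mixed model (continuous responses: percent nuclear area,
  focus intensity), ``response ~ state + (1|experiment) +
  (1|experiment:sample)`` with an optional nucleus-level intercept, fitted
  by REML (statsmodels MixedLM).
* Negative-binomial mixed model (foci counts per nucleus), log link, same
  nested intercepts, fitted by Laplace approximation of the marginal
  likelihood (implemented here; no efficiency or quadrature refinements).

Both expose sklearn-style estimator classes and produce a common fit
object consumed by :func:`emmeans_tukey`, which computes estimated marginal
means per treatment with SEM and all pairwise contrasts adjusted by Tukey's
studentized-range method (containment degrees of freedom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "NestedFitResult",
    "ContrastResult",
    "ConvergenceError",
    "CompleteSeparationError",
    "NestedLinearMixedModel",
    "NestedNegativeBinomialModel",
    "fit_lmm_nested",
    "fit_count_glmm_nested",
    "emmeans_tukey",
]

MIN_NUCLEI_GUIDELINE = 600  # per-condition scale used in practice; warning only


class ConvergenceError(RuntimeError):
    """Model fit did not converge; diagnostics in the message."""


class CompleteSeparationError(RuntimeError):
    """A treatment has degenerate data (e.g. all counts zero): the MLE diverges."""


@dataclass
class NestedFitResult:
    """Common fitted-model summary consumed by :func:`emmeans_tukey`.

    ``emm`` holds per-state estimates on the model scale (identity for
    gaussian, log for counts) under cell-means coding, with covariance
    ``cov_emm``; ``df`` is the containment denominator df used for
    contrasts (``inf`` for the count model's asymptotic tests).
    """

    family: str
    states: list[str]
    emm: np.ndarray
    cov_emm: np.ndarray
    df: float
    variance_components: dict[str, float]
    n_obs: int
    converged: bool
    singular: bool = False
    dispersion: float | None = None  # NB size parameter theta
    scale: float | None = None  # gaussian residual variance
    loglik: float | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class ContrastResult:
    emmeans: pd.DataFrame  # state, estimate, sem
    contrasts: pd.DataFrame  # pair, estimate, se, t, p_raw, p_tukey (+ rate_ratio)
    variance_components: dict[str, float]
    df: float


def _validate_nested(data: pd.DataFrame, response: str, state_col: str, levels: tuple[str, ...]):
    for col in (response, state_col, *levels):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    if data[list(levels)].isna().any().any():
        raise ValueError("lineage labels must be non-null")
    states = sorted(data[state_col].astype(str).unique())
    if len(states) < 2:
        raise ValueError("need at least 2 treatment states")
    return states


def _nested_group_codes(data: pd.DataFrame, levels: tuple[str, ...]) -> list[np.ndarray]:
    """Integer codes for each nesting level, each fully crossed with its parents."""
    codes = []
    key = None
    for lev in levels:
        key = data[lev].astype(str) if key is None else key + ":" + data[lev].astype(str)
        codes.append(pd.factorize(key)[0])
    return codes


class NestedLinearMixedModel(BaseEstimator):
    """Gaussian LMM with nested random intercepts, REML.

    Parameters
    ----------
    levels : tuple of str
        Nesting columns outermost first, e.g. ``("experiment", "sample")``
        or ``("experiment", "sample", "nucleus")`` for focus-level
        intensity.  The first level becomes the grouping factor; deeper
        levels enter as variance components.
    random_effects : bool
        With ``False`` the random structure is dropped and the fit is
        ordinary least squares on the same cell-means design (the
        zero-variance limit of the model).
    """

    def __init__(
        self,
        levels: tuple[str, ...] = ("experiment", "sample"),
        state_col: str = "state",
        random_effects: bool = True,
        reml: bool = True,
    ):
        self.levels = levels
        self.state_col = state_col
        self.random_effects = random_effects
        self.reml = reml

    def fit(self, data: pd.DataFrame, response: str = "value") -> "NestedLinearMixedModel":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        states = _validate_nested(data, response, self.state_col, self.levels)
        work = data.copy()
        work["_state"] = work[self.state_col].astype(str)
        n = len(work)
        k = len(states)

        if not self.random_effects:
            res = smf.ols(f"Q('{response}') ~ 0 + C(_state)", data=work).fit()
            names = [f"C(_state)[{s}]" for s in states]
            emm = np.array([res.params[nm] for nm in names])
            cov = pd.DataFrame(res.cov_params()).loc[names, names].to_numpy()
            self.result_ = NestedFitResult(
                family="gaussian",
                states=states,
                emm=emm,
                cov_emm=cov,
                df=float(res.df_resid),
                variance_components={"residual": float(res.mse_resid)},
                n_obs=n,
                converged=True,
                scale=float(res.mse_resid),
                loglik=float(res.llf),
            )
            return self

    # nested labels: sample codes unique across experiments, etc.
        codes = _nested_group_codes(work, self.levels)
        work["_g0"] = codes[0]
        vc_formula = {}
        for i, lev in enumerate(self.levels[1:], start=1):
            work[f"_g{i}"] = codes[i]
            vc_formula[lev] = f"0 + C(_g{i})"

        model = smf.mixedlm(
            f"Q('{response}') ~ 0 + C(_state)",
            data=work,
            groups=work["_g0"],
            re_formula="1",
            vc_formula=vc_formula or None,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=self.reml, method="lbfgs")
            if not res.converged:
                # gradient methods stall near the variance boundary;
                # derivative-free restart usually certifies the optimum
                res = model.fit(reml=self.reml, method="powell")
        if not res.converged:
            raise ConvergenceError(
                f"REML fit failed to converge (n={n}, states={states}); "
                "check group sizes and response scaling"
            )

        names = [f"C(_state)[{s}]" for s in states]
        emm = np.array([res.params[nm] for nm in names])
        cov = pd.DataFrame(res.cov_params()).loc[names, names].to_numpy()

        vc = {self.levels[0]: float(np.asarray(res.cov_re)[0, 0])}
        for i, lev in enumerate(self.levels[1:]):
            vc[lev] = float(res.vcomp[i])
        vc["residual"] = float(res.scale)
        singular = any(
            v < 1e-8 * (vc["residual"] + 1e-8) for lv, v in vc.items() if lv != "residual"
        )

        n_finest = len(np.unique(codes[-1]))
        # containment-style denominator df: the state effect varies within the
        # finest random grouping, so its error stratum is the residual one
        df = float(max(n - n_finest - (k - 1), 1))
        self.result_ = NestedFitResult(
            family="gaussian",
            states=states,
            emm=emm,
            cov_emm=cov,
            df=df,
            variance_components=vc,
            n_obs=n,
            converged=bool(res.converged),
            singular=singular,
            scale=vc["residual"],
            loglik=float(res.llf),
        )
        if singular:
            warnings.warn(
                "singular fit: at least one variance component is on the zero boundary",
                stacklevel=2,
            )
        return self


def _nb_loglik_terms(y, eta, theta):
    mu = np.exp(eta)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * (eta - np.log(theta + mu))
    )


class NestedNegativeBinomialModel(BaseEstimator):
    """NB2 mixed model with nested random intercepts, log link, Laplace fit.

    The marginal likelihood integrates the random intercepts out by the
    Laplace approximation: for each candidate (beta, sigma, theta) the joint
    log posterior of the random effects is maximised by Newton iterations
    (it is strictly concave), and the curvature term corrects the maximised
    joint likelihood.  The outer optimisation runs L-BFGS-B on (beta,
    log sigma per level, log theta).  Standard errors come from the numeric
    Hessian of the Laplace marginal log-likelihood.

    With ``random_effects=False`` this reduces to plain NB regression.
    """

    def __init__(
        self,
        levels: tuple[str, ...] = ("experiment", "sample"),
        state_col: str = "state",
        random_effects: bool = True,
        max_outer_iter: int = 500,
    ):
        self.levels = levels
        self.state_col = state_col
        self.random_effects = random_effects
        self.max_outer_iter = max_outer_iter

    # ---- Laplace machinery -------------------------------------------------
    @staticmethod
    def _inner_mode(y, X, beta, theta, sigmas, code_list, u0):
        """Newton maximisation of the joint log-likelihood over random effects."""
        q_sizes = [c.max() + 1 for c in code_list]
        q = sum(q_sizes)
        offsets = np.cumsum([0] + q_sizes[:-1])
        u = u0.copy() if u0 is not None and u0.size == q else np.zeros(q)
        fixed = X @ beta
        prec = np.concatenate(
            [np.full(qs, 1.0 / s**2) for qs, s in zip(q_sizes, sigmas)]
        )
        for _ in range(100):
            eta = fixed.copy()
            for off, c in zip(offsets, code_list):
                eta += u[off + c]
            mu = np.exp(np.clip(eta, -30, 30))
            dl = y - (y + theta) * mu / (theta + mu)
            w = (y + theta) * theta * mu / (theta + mu) ** 2
            grad = np.concatenate(
                [np.bincount(c, weights=dl, minlength=qs) for c, qs in zip(code_list, q_sizes)]
            ) - u * prec
            if np.max(np.abs(grad)) < 1e-9:
                break
            H = np.zeros((q, q))
            for a, (offa, ca, qa) in enumerate(zip(offsets, code_list, q_sizes)):
                H[offa : offa + qa, offa : offa + qa] += np.diag(
                    np.bincount(ca, weights=w, minlength=qa)
                )
                for offb, cb, qb in list(zip(offsets, code_list, q_sizes))[a + 1 :]:
                    cross = np.zeros((qa, qb))
                    np.add.at(cross, (ca, cb), w)
                    H[offa : offa + qa, offb : offb + qb] += cross
                    H[offb : offb + qb, offa : offa + qa] += cross.T
            H[np.diag_indices(q)] += prec
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # damped Newton for stability far from the mode
            for damp in (1.0, 0.5, 0.25, 0.1):
                u_new = u + damp * step
                if np.all(np.isfinite(u_new)):
                    u = u_new
                    break
        eta = fixed.copy()
        for off, c in zip(offsets, code_list):
            eta += u[off + c]
        mu = np.exp(np.clip(eta, -30, 30))
        w = (y + theta) * theta * mu / (theta + mu) ** 2
        H = np.zeros((q, q))
        for a, (offa, ca, qa) in enumerate(zip(offsets, code_list, q_sizes)):
            H[offa : offa + qa, offa : offa + qa] += np.diag(
                np.bincount(ca, weights=w, minlength=qa)
            )
            for offb, cb, qb in list(zip(offsets, code_list, q_sizes))[a + 1 :]:
                cross = np.zeros((qa, qb))
                np.add.at(cross, (ca, cb), w)
                H[offa : offa + qa, offb : offb + qb] += cross
                H[offb : offb + qb, offa : offa + qa] += cross.T
        H[np.diag_indices(q)] += prec
        return u, eta, H

    def _marginal_negloglik(self, phi, y, X, code_list, u_cache):
        k = X.shape[1]
        n_lev = len(code_list)
        beta = phi[:k]
        sigmas = np.exp(phi[k : k + n_lev])
        theta = np.exp(phi[k + n_lev])
        u, eta, H = self._inner_mode(y, X, beta, theta, sigmas, code_list, u_cache.get("u"))
        u_cache["u"] = u
        q_sizes = [c.max() + 1 for c in code_list]
        lj = _nb_loglik_terms(y, eta, theta).sum()
        off = 0
        for qs, s in zip(q_sizes, sigmas):
            ue = u[off : off + qs]
            lj += -0.5 * np.sum(ue**2) / s**2 - qs * np.log(s) - 0.5 * qs * np.log(2 * np.pi)
            off += qs
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        q = sum(q_sizes)
        lm = lj + 0.5 * q * np.log(2 * np.pi) - 0.5 * logdet
        return -lm if np.isfinite(lm) else 1e10

    def fit(self, data: pd.DataFrame, response: str = "foci_count") -> "NestedNegativeBinomialModel":
        states = _validate_nested(data, response, self.state_col, self.levels)
        y = data[response].to_numpy()
        if not np.all(np.isfinite(y)) or np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("count responses must be nonnegative integers")
        y = y.astype(float)
        state_arr = data[self.state_col].astype(str).to_numpy()
        k = len(states)
        X = np.column_stack([(state_arr == s).astype(float) for s in states])

        for s in states:
            if y[state_arr == s].sum() == 0:
                raise CompleteSeparationError(
                    f"state {s!r} has all-zero counts: its log-mean diverges to -inf "
                    "and the NB fit is not identified"
                )

        group_means = np.array([y[state_arr == s].mean() for s in states])
        beta0 = np.log(np.maximum(group_means, 1e-3))

        if not self.random_effects:
            self._fit_plain_nb(y, X, states, beta0, len(data))
            return self

        code_list = _nested_group_codes(data, self.levels)
        n_lev = len(code_list)
        phi0 = np.concatenate([beta0, np.full(n_lev, np.log(0.3)), [0.0]])
        bounds = [(None, None)] * k + [(-6.0, 3.0)] * n_lev + [(-4.0, 7.0)]
        u_cache: dict = {}
        res = optimize.minimize(
            self._marginal_negloglik,
            phi0,
            args=(y, X, code_list, u_cache),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.max_outer_iter, "ftol": 1e-10},
        )
        if not res.success and "ABNORMAL" in str(res.message):
            raise ConvergenceError(f"Laplace NB fit failed: {res.message}")

        phi = res.x
        hess = _numeric_hessian(
            lambda p: self._marginal_negloglik(p, y, X, code_list, dict(u_cache)), phi
        )
        cov_phi = _safe_inverse(hess)
        sigmas = np.exp(phi[k : k + n_lev])
        theta = float(np.exp(phi[k + n_lev]))
        vc = {lev: float(s**2) for lev, s in zip(self.levels, sigmas)}
        singular = any(s < 1.5 * np.exp(-6.0) for s in sigmas)

        self.result_ = NestedFitResult(
            family="nb",
            states=states,
            emm=phi[:k].copy(),
            cov_emm=cov_phi[:k, :k],
            df=np.inf,
            variance_components=vc,
            n_obs=len(y),
            converged=bool(res.success),
            singular=singular,
            dispersion=theta,
            loglik=float(-res.fun),
        )
        return self

    def _fit_plain_nb(self, y, X, states, beta0, n):
        def negll(phi):
            eta = X @ phi[:-1]
            theta = np.exp(phi[-1])
            return -_nb_loglik_terms(y, eta, theta).sum()

        phi0 = np.concatenate([beta0, [0.0]])
        res = optimize.minimize(negll, phi0, method="L-BFGS-B")
        if not res.success:
            raise ConvergenceError(f"NB regression failed: {res.message}")
        hess = _numeric_hessian(negll, res.x)
        cov = _safe_inverse(hess)
        k = len(states)
        self.result_ = NestedFitResult(
            family="nb",
            states=states,
            emm=res.x[:k].copy(),
            cov_emm=cov[:k, :k],
            df=np.inf,
            variance_components={},
            n_obs=n,
            converged=True,
            dispersion=float(np.exp(res.x[-1])),
            loglik=float(-res.fun),
        )


def _numeric_hessian(f, x, rel_step: float = 1e-4):
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def _safe_inverse(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def fit_lmm_nested(
    data: pd.DataFrame,
    response: str,
    levels: tuple[str, ...] = ("experiment", "sample"),
    state_col: str = "state",
    random_effects: bool = True,
) -> NestedFitResult:
    """Functional wrapper over :class:`NestedLinearMixedModel`."""
    model = NestedLinearMixedModel(
        levels=levels, state_col=state_col, random_effects=random_effects
    )
    return model.fit(data, response=response).result_


def fit_count_glmm_nested(
    data: pd.DataFrame,
    response: str,
    levels: tuple[str, ...] = ("experiment", "sample"),
    state_col: str = "state",
    random_effects: bool = True,
) -> NestedFitResult:
    """Functional wrapper over :class:`NestedNegativeBinomialModel`."""
    model = NestedNegativeBinomialModel(
        levels=levels, state_col=state_col, random_effects=random_effects
    )
    return model.fit(data, response=response).result_


def emmeans_tukey(fit: NestedFitResult) -> ContrastResult:
    """Estimated marginal means and Tukey-adjusted pairwise contrasts.

    With state as the only fixed term under cell-means coding the marginal
    means are the model's state estimates; each pairwise difference is
    tested with t = diff / SE(diff) and adjusted with the studentized-range
    distribution on the fit's containment df (asymptotic for count models,
    where a large-df range distribution is used).  With two states the
    adjusted p equals the raw p.  Count-model contrasts additionally report
    rate ratios exp(diff).
    """
    k = len(fit.states)
    emm_df = pd.DataFrame(
        {
            "state": fit.states,
            "estimate": fit.emm,
            "sem": np.sqrt(np.diag(fit.cov_emm)),
        }
    )
    df = fit.df if np.isfinite(fit.df) else 1e6
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = fit.emm[i] - fit.emm[j]
            se = float(
                np.sqrt(fit.cov_emm[i, i] + fit.cov_emm[j, j] - 2 * fit.cov_emm[i, j])
            )
            t = diff / se
            if np.isfinite(fit.df):
                p_raw = 2 * stats.t.sf(abs(t), df)
            else:
                p_raw = 2 * stats.norm.sf(abs(t))
            p_tukey = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df))
            row = {
                "contrast": f"{fit.states[i]} - {fit.states[j]}",
                "estimate": float(diff),
                "se": se,
                "t": float(t),
                "p_raw": float(p_raw),
                "p_tukey": max(p_tukey, float(p_raw)) if k == 2 else p_tukey,
            }
            if fit.family == "nb":
                row["rate_ratio"] = float(np.exp(diff))
            rows.append(row)
    contrasts = pd.DataFrame(rows)
    return ContrastResult(
        emmeans=emm_df,
        contrasts=contrasts,
        variance_components=fit.variance_components,
        df=fit.df,
    )
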