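"""Binomial-response models for seed- and seedling-fate experiments.

Multi-category fates are collapsed to the binary responses actually analysed
(seed survival: removed/germinated or not; seedling survival or not).  Fixed
effects are fitted by iteratively reweighted least squares; an optional
single random intercept (experimental unit) is integrated out by adaptive
Gauss-Hermite quadrature (Laplace approximation when one node is used).
Model selection is backward stepwise by likelihood-ratio tests; treatment
effects are summarised as pairwise odds ratios with Holm-adjusted Wald tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fsgs import holm_adjust
from .simulate import SeedFateRecord, seed_fate_frame

#: fates counted as the favourable binary outcome by default
SUCCESS_FATES = frozenset({"intact", "germinated", "established"})


class SeparationError(RuntimeError):
    pass


class AliasingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design matrices


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return seed_fate_frame(list(records))


def build_design(df: pd.DataFrame, terms: list[str]
                 ) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept, treatment-coded factors and ``:``
    interactions; columns named e.g. ``hunting[high]`` or
    ``distance:hunting[high]``."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]

    def factor_columns(term: str) -> list[tuple[str, np.ndarray]]:
        if term not in df.columns:
            raise KeyError(f"unknown covariate {term!r}")
        s = df[term]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2 or \
           pd.api.types.is_float_dtype(s):
            return [(term, s.to_numpy(float))]
        levels = list(pd.unique(s.astype(str)))
        if len(levels) < 2:
            raise AliasingError(f"factor {term!r} has a single level")
        return [(f"{term}[{lev}]", (s.astype(str) == lev).to_numpy(float))
                for lev in levels[1:]]

    for term in terms:
        parts = term.split(":")
        combos: list[tuple[str, np.ndarray]] = [("", np.ones(len(df)))]
        for part in parts:
            combos = [(f"{n}:{pn}" if n else pn, c * pc)
                      for n, c in combos for pn, pc in factor_columns(part)]
        for name, col in combos:
            cols.append(col)
            names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AliasingError(f"design matrix not full rank for terms {terms}")
    return X, names


def binary_response(df: pd.DataFrame, success_fates=SUCCESS_FATES) -> np.ndarray:
    return df["fate"].isin(success_fates).to_numpy(float)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class LogisticFit:
    terms: list[str]                 # model terms as requested
    names: list[str]                 # design-matrix column names
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    re_sd: float | None = None       # random-intercept sd (None: fixed-only)
    n_groups: int = 0
    converged: bool = True
    n_obs: int = 0
    _frame: pd.DataFrame | None = field(default=None, repr=False)
    _group: str | None = None
    _success: frozenset = SUCCESS_FATES

    @property
    def n_params(self) -> int:
        return len(self.coef) + (1 if self.re_sd is not None else 0)


def _bernoulli_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
          max_iter: int = 100,
          names: list[str] | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton/IRLS with step halving; detects complete separation."""
    beta = np.zeros(X.shape[1])
    ll = _bernoulli_loglik(X, y, beta)

    def separation_check(eta, mu):
        fitted_perfectly = np.all(np.abs(y - mu) < 1e-6)
        diverging = np.max(np.abs(eta)) > 40 and np.all((2 * y - 1) * eta > 0)
        if fitted_perfectly or diverging:
            worst = int(np.argmax(np.abs(beta[1:])) + 1) if len(beta) > 1 else 0
            term = names[worst] if names else f"column {worst}"
            raise SeparationError(f"complete separation: coefficient for "
                                  f"{term} diverges")

    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            break
        separation_check(eta, mu)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        H = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise AliasingError("singular information matrix") from exc
        for _ in range(30):                      # step halving
            if _bernoulli_loglik(X, y, beta + step) >= ll - 1e-12:
                break
            step = step / 2
        beta = beta + step
        ll = _bernoulli_loglik(X, y, beta)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    separation_check(eta, mu)
    cov = np.linalg.inv(X.T @ ((mu * (1 - mu))[:, None] * X))
    return beta, cov, ll


def _group_loglik_gh(beta, log_sd, X, y, group_idx, n_groups, nodes):
    """Marginal log-likelihood with a single Normal random intercept,
    integrated by adaptive Gauss-Hermite quadrature."""
    sd = np.exp(log_sd)
    z, wq = np.polynomial.hermite.hermgauss(nodes)
    eta0 = X @ beta
    total = 0.0
    for g in range(n_groups):
        idx = group_idx == g
        xg, yg = eta0[idx], y[idx]

        def h(u):      # log integrand: conditional loglik + N(0,1) prior on u
            eta = xg + sd * u
            ll = np.sum(yg * eta - np.log1p(np.exp(eta)))
            return ll - 0.5 * u * u - 0.5 * np.log(2 * np.pi)

        # inner Newton for the conditional mode
        u = 0.0
        for _ in range(30):
            eta = xg + sd * u
            mu = 1.0 / (1.0 + np.exp(-eta))
            g1 = sd * np.sum(yg - mu) - u
            g2 = -sd * sd * np.sum(mu * (1 - mu)) - 1.0
            step = g1 / g2
            u -= step
            if abs(step) < 1e-10:
                break
        tau = 1.0 / np.sqrt(-g2)
        if nodes == 1:
            total += h(u) + 0.5 * np.log(2 * np.pi) + np.log(tau)
        else:
            pts = u + np.sqrt(2.0) * tau * z
            vals = np.array([h(p) for p in pts]) + z * z
            m = vals.max()
            total += m + np.log(np.sum(wq * np.exp(vals - m))) \
                + 0.5 * np.log(2.0) + np.log(tau)
    return total


def fit_logistic(records, terms: list[str], group: str | None = None,
                 nodes: int = 15, success_fates=SUCCESS_FATES,
                 response: np.ndarray | None = None) -> LogisticFit:
    """Logistic model of a binary fate outcome.

    ``terms`` are fixed effects (``[]`` for intercept-only); ``group`` names a
    column used as a single random intercept, integrated by adaptive
    Gauss-Hermite quadrature with ``nodes`` nodes (``nodes=1`` = Laplace).
    """
    df = _records_frame(records)
    y = binary_response(df, success_fates) if response is None \
        else np.asarray(response, float)
    X, names = build_design(df, terms)

    if group is None:
        beta, cov, ll = _irls(X, y, names=names)
        return LogisticFit(terms, names, beta, cov, ll, None, 0, True, len(y),
                           df, None, frozenset(success_fates))

    labels, group_idx = np.unique(df[group].astype(str), return_inverse=True)
    n_groups = len(labels)
    try:
        beta0, _, _ = _irls(X, y, names=names)
    except SeparationError:
        raise
    except AliasingError:
        beta0 = np.zeros(X.shape[1])
    theta0 = np.append(beta0, np.log(0.5))

    def nll(theta):
        return -_group_loglik_gh(theta[:-1], theta[-1], X, y, group_idx,
                                 n_groups, nodes)

    bounds = [(None, None)] * X.shape[1] + [(np.log(1e-4), np.log(50.0))]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    beta, log_sd = res.x[:-1], res.x[-1]
    cov_full = _numeric_hessian_inv(nll, res.x)
    return LogisticFit(terms, names, beta, cov_full[:-1, :-1], -float(res.fun),
                       float(np.exp(log_sd)), n_groups, bool(res.success),
                       len(y), df, group, frozenset(success_fates))


def _numeric_hessian_inv(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei, ej = np.zeros(n), np.zeros(n)
            ei[i], ej[j] = eps, eps
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps * eps)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# model comparison


def likelihood_ratio_test(nested: LogisticFit, full: LogisticFit
                          ) -> tuple[float, int, float]:
    """LRT of two nested fits: chi2 = 2 * delta-loglik, df = parameter diff."""
    if nested.n_obs != full.n_obs:
        raise ValueError("fits use different data")
    if not set(nested.terms) <= set(full.terms):
        raise ValueError("models are not nested")
    df = full.n_params - nested.n_params
    if df <= 0:
        raise ValueError("full model has no extra parameters")
    chi2 = max(0.0, 2.0 * (full.loglik - nested.loglik))
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _droppable(terms: list[str], forced: set[str]) -> list[str]:
    """Terms that may be removed: not forced, and main effects only once no
    remaining interaction contains them."""
    out = []
    for t in terms:
        if t in forced:
            continue
        if any(t != other and t in other.split(":") for other in terms):
            continue
        out.append(t)
    return out


def stepwise_selection(records, global_terms: list[str], alpha: float = 0.05,
                       group: str | None = None, forced: tuple[str, ...] = (),
                       nodes: int = 15, success_fates=SUCCESS_FATES
                       ) -> tuple[LogisticFit, pd.DataFrame]:
    """Backward elimination by LRT from a global model.

    At each step the candidate with the weakest support (largest LRT p-value
    above ``alpha``) is removed; interactions are removed before their main
    effects; ``forced`` terms are never dropped.  Returns the selected fit and
    the full comparison trace.
    """
    df = _records_frame(records)
    terms = list(global_terms)
    current = fit_logistic(df, terms, group, nodes, success_fates)
    trace = []
    while True:
        candidates = _droppable(terms, set(forced))
        if not candidates:
            break
        trials = []
        for t in candidates:
            reduced_terms = [x for x in terms if x != t]
            reduced = fit_logistic(df, reduced_terms, group, nodes, success_fates)
            chi2, dfree, p = likelihood_ratio_test(reduced, current)
            trials.append((t, reduced, chi2, dfree, p))
            trace.append(dict(dropped=t, kept=",".join(reduced_terms),
                              chi2=chi2, df=dfree, p=p))
        worst = max(trials, key=lambda r: r[4])
        if worst[4] <= alpha:
            break
        terms = [x for x in terms if x != worst[0]]
        current = worst[1]
    return current, pd.DataFrame(trace)


def pairwise_treatment_contrasts(fit: LogisticFit, factor: str,
                                 adjust: str = "holm",
                                 alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise odds ratios between levels of a fitted factor.

    Differences are Wald contrasts on the logit scale; p-values are
    Holm-adjusted across the family.
    """
    idx = {}
    for i, name in enumerate(fit.names):
        if name.startswith(f"{factor}[") and ":" not in name:
            idx[name[len(factor) + 1:-1]] = i
    if not idx and fit._frame is not None and factor in fit._frame.columns:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    if fit._frame is not None:
        levels = list(pd.unique(fit._frame[factor].astype(str)))
    else:
        levels = list(idx)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than two levels")

    def contrast_vec(level):
        c = np.zeros(len(fit.coef))
        if level in idx:
            c[idx[level]] = 1.0
        return c

    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            c = contrast_vec(levels[i]) - contrast_vec(levels[j])
            est = float(c @ fit.coef)
            se = float(np.sqrt(c @ fit.cov @ c))
            z = est / se if se > 0 else np.inf
            p = 2 * stats.norm.sf(abs(z))
            zc = stats.norm.ppf(1 - alpha / 2)
            rows.append(dict(level_a=levels[i], level_b=levels[j],
                             log_or=est, odds_ratio=float(np.exp(est)),
                             ci_low=float(np.exp(est - zc * se)),
                             ci_high=float(np.exp(est + zc * se)),
                             z=z, p=p))
    out = pd.DataFrame(rows)
    if adjust == "holm":
        out["p_adj"] = holm_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = out["p"]
    return out
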