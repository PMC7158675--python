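"""Permutation inference for dyadic data: QAP, MRQAP-DSP and logistic LRQAP.

Dyadic observations violate the independence assumptions of ordinary
regression: all dyads sharing an actor are correlated. The quadratic
assignment procedure (QAP) sidesteps this by building the null
distribution from *node* permutations — relabelling actors permutes the
rows and columns of a matrix simultaneously, which preserves the dyadic
dependence structure while breaking any association between matrices.

Three inference routines are provided:

``qap_correlation``
    Pearson correlation between two dyadic matrices with a node-permutation
    p-value.
``mrqap_dsp``
    Multiple linear regression over ordered dyads. Point estimates are
    plain OLS; per-coefficient p-values use the double semi-partialing
    (DSP) scheme — each predictor is residualised on the others, the
    residual matrix is node-permuted, and the pivotal t statistic is
    recomputed — which stays well calibrated under collinearity among the
    dyadic predictors.
``lrqap``
    Maximum-likelihood logistic regression over ordered dyads for a binary
    dyadic response, with odds ratios ``exp(b)``. The default null permutes
    the response matrix (classic Y-permutation logistic QAP); a DSP-style
    residual-permutation scheme is available as an explicit mode. The model
    p-value permutes the response and compares the overall fit statistic
    (McFadden pseudo R²).

Monte-Carlo p-values follow the add-one rule (the observed statistic is
counted in its own null set), so p > 0 always; in exhaustive mode the
identity permutation plays that role. One permutation sequence is drawn
per model fit and reused across coefficients.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .net_model import DyadDesign, DyadicMatrix, ValidationError, devectorize, vectorize

__all__ = [
    "PermutationEngine",
    "QapCorrelationResult",
    "QapRegressionResult",
    "node_permute",
    "qap_correlation",
    "mrqap_dsp",
    "lrqap",
    "significance_stars",
]

_EXHAUSTIVE_MAX_N = 8
_SEPARATION_BOUND = 30.0
#: tolerance for "as extreme as observed" comparisons, absorbing float
#: jitter so exact ties (common with binary matrices) count as ties
_TIE_EPS = 1e-12


def _at_least(a: float, b: float) -> bool:
    return a >= b - _TIE_EPS


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


@dataclass
class PermutationEngine:
    """Source of node permutations for QAP nulls.

    ``monte_carlo`` draws ``n_permutations`` uniform node permutations from
    a seeded generator; ``exhaustive`` enumerates all n! permutations
    (permitted only for n <= 8).
    """

    n_permutations: int = 10_000
    seed: int | None = None
    mode: str = "monte_carlo"

    def __post_init__(self) -> None:
        if self.mode not in ("monte_carlo", "exhaustive"):
            raise ValidationError(f"unknown permutation mode {self.mode!r}")
        if self.mode == "monte_carlo" and self.n_permutations < 1:
            raise ValidationError("n_permutations must be positive")

    @property
    def exhaustive(self) -> bool:
        return self.mode == "exhaustive"

    def permutations(self, n: int) -> np.ndarray:
        """Permutation array of shape (P, n); includes the identity first in
        exhaustive mode (itertools enumerates in lexicographic order)."""
        if self.exhaustive:
            if n > _EXHAUSTIVE_MAX_N:
                raise ValidationError(
                    f"exhaustive mode enumerates n! permutations; n={n} > {_EXHAUSTIVE_MAX_N}"
                )
            return np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        rng = np.random.default_rng(self.seed)
        return rng.permuted(
            np.tile(np.arange(n, dtype=np.intp), (self.n_permutations, 1)), axis=1
        )

    def pvalue(self, count_extreme: int, n_draws: int) -> float:
        if self.exhaustive:
            # identity permutation reproduces the observed statistic, so the
            # count is >= 1 and p > 0 without an add-one correction
            return count_extreme / n_draws
        return (count_extreme + 1) / (n_draws + 1)


def node_permute(matrix: DyadicMatrix | np.ndarray, perm: np.ndarray) -> DyadicMatrix:
    """Relabel nodes: permute rows and columns by the same permutation."""
    values = matrix.values if isinstance(matrix, DyadicMatrix) else np.asarray(matrix)
    perm = np.asarray(perm, dtype=np.intp)
    n = values.shape[0]
    if sorted(perm.tolist()) != list(range(n)):
        raise ValidationError("perm must be a bijection over node indices")
    permuted = values[np.ix_(perm, perm)]
    label = matrix.label if isinstance(matrix, DyadicMatrix) else "permuted"
    return DyadicMatrix(values=permuted, label=label)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class QapCorrelationResult:
    r_obs: float
    p_two_sided: float
    n_permutations: int
    degenerate: bool = False
    mode: str = "monte_carlo"

    def stars(self) -> str:
        return "" if self.degenerate else significance_stars(self.p_two_sided)


@dataclass
class QapRegressionResult:
    """Fitted network regression with permutation p-values.

    ``coefficients`` and ``p_values`` are keyed by covariate name with
    ``"Intercept"`` first; the intercept carries no permutation p-value
    (NaN). For the logistic family ``odds_ratios[k] == exp(coefficients[k])``.
    """

    coefficients: dict[str, float]
    p_values: dict[str, float]
    model_p: float
    fit_stat: float
    fit_stat_name: str
    n_obs: int
    n_permutations: int
    family: str
    odds_ratios: dict[str, float] | None = None
    scheme: str = "dsp"
    converged: bool = True
    metadata: dict = field(default_factory=dict)

    def stars(self, name: str) -> str:
        p = self.p_values[name]
        return "" if (p is None or np.isnan(p)) else significance_stars(p)


def significance_stars(p: float) -> str:
    """Published star convention: '**' for p <= 0.05, '*' for p <= 0.1."""
    if not (0 < p <= 1):
        raise ValidationError(f"p-value must lie in (0, 1], got {p!r}")
    if p <= 0.05:
        return "**"
    if p <= 0.1:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# internal numerics
# ---------------------------------------------------------------------------


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    # cross-products via dot keep integer-valued data exact, so exhaustive
    # statistics are invariant to node relabelling at the bit level
    m = x.size
    sx, sy = x.sum(), y.sum()
    num = m * (x @ y) - sx * sy
    den_sq = (m * (x @ x) - sx * sx) * (m * (y @ y) - sy * sy)
    if den_sq <= 0:
        return math.nan
    return num / math.sqrt(den_sq)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS via normal equations: (beta, t, r_squared)."""
    m, p = x.shape
    gram = x.T @ x
    beta = np.linalg.solve(gram, x.T @ y)
    resid = y - x @ beta
    rss = resid @ resid
    sigma2 = rss / (m - p)
    se = np.sqrt(sigma2 * np.linalg.inv(gram).diagonal())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    centred = y - y.mean()
    tss = centred @ centred
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    return beta, t, r2


def _fit_logit(
    x: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-9
) -> tuple[np.ndarray, float, bool]:
    """Newton/IRLS maximum-likelihood logistic fit: (beta, llf, converged).

    A lean fixed-design solver sized for the permutation loop; tests
    cross-check its estimates against statsmodels' Logit.
    """
    m, p = x.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -_SEPARATION_BOUND, _SEPARATION_BOUND)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = x.T @ (y - mu)
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(x @ beta, -_SEPARATION_BOUND, _SEPARATION_BOUND)
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    llf = float(y @ np.log(mu) + (1.0 - y) @ np.log1p(-mu))
    if np.max(np.abs(beta)) >= _SEPARATION_BOUND:
        converged = False
    return beta, llf, converged


def _fit_logit_canonical(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """Logistic fit on canonically ordered rows.

    Sorting the stacked dyads lexicographically by content makes every
    floating-point reduction independent of the incoming row order, so
    exhaustive-mode statistics are bit-identical under node relabelling.
    Used only at exhaustive (small-n) scale, where the sort is free.
    """
    order = np.lexsort(np.column_stack([x, y]).T)
    return _fit_logit(x[order], y[order])


def _null_loglik(y: np.ndarray) -> float:
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        return 0.0
    m = y.size
    return m * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))


def _design_matrix(design: DyadDesign) -> tuple[np.ndarray, list[str]]:
    names = ["Intercept"] + list(design.predictor_names)
    x = np.column_stack([np.ones(design.n_obs)] + [design.predictors[k] for k in design.predictor_names])
    _check_collinearity(x, names)
    return x, names


def _check_collinearity(x: np.ndarray, names: list[str]) -> None:
    p = x.shape[1]
    if p <= 2:
        deficient = np.linalg.matrix_rank(x) < p
        if deficient:
            raise ValidationError("constant predictor besides the intercept")
        return
    cols = x[:, 1:]
    sds = cols.std(axis=0)
    if (sds == 0).any():
        k = int(np.nonzero(sds == 0)[0][0])
        raise ValidationError(f"predictor {names[k + 1]!r} is constant")
    corr = np.corrcoef(cols, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
    if abs(corr[i, j]) > 1 - 1e-10:
        raise ValidationError(
            f"perfectly collinear predictors: {names[i + 1]!r} and {names[j + 1]!r}"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("design matrix is rank deficient")


# ---------------------------------------------------------------------------
# QAP correlation
# ---------------------------------------------------------------------------


def qap_correlation(
    m1: DyadicMatrix | np.ndarray,
    m2: DyadicMatrix | np.ndarray,
    engine: PermutationEngine | None = None,
) -> QapCorrelationResult:
    """Pearson correlation of two dyadic matrices with a QAP p-value.

    ``r_obs`` is the correlation of the off-diagonal cells. The null keeps
    ``m1`` fixed and node-permutes ``m2``; the two-sided p-value is the
    share of permutations with ``|r| >= |r_obs|``.
    """
    engine = engine or PermutationEngine()
    v1 = vectorize(m1)
    a2 = m2.values if isinstance(m2, DyadicMatrix) else np.asarray(m2, dtype=float)
    v2 = vectorize(a2)
    if v1.size != v2.size:
        raise ValidationError("matrices have different dimensions")
    r_obs = _pearson(v1, v2)
    if math.isnan(r_obs):
        return QapCorrelationResult(
            r_obs=math.nan,
            p_two_sided=math.nan,
            n_permutations=0,
            degenerate=True,
            mode=engine.mode,
        )
    n = int(round((1 + math.sqrt(1 + 4 * v1.size)) / 2))
    perms = engine.permutations(n)
    count = 0
    for perm in perms:
        r_perm = _pearson(v1, vectorize(a2[np.ix_(perm, perm)]))
        if not math.isnan(r_perm) and _at_least(abs(r_perm), abs(r_obs)):
            count += 1
    return QapCorrelationResult(
        r_obs=float(r_obs),
        p_two_sided=engine.pvalue(count, len(perms)),
        n_permutations=len(perms),
        mode=engine.mode,
    )


# ---------------------------------------------------------------------------
# MRQAP with double semi-partialing
# ---------------------------------------------------------------------------


def mrqap_dsp(design: DyadDesign, engine: PermutationEngine | None = None) -> QapRegressionResult:
    """Linear network regression with DSP permutation p-values.

    Point estimates are the OLS fit on the stacked dyad vectors; the
    permutation machinery affects only the p-values. For each predictor k
    the null distribution comes from node-permuting the matrix of residuals
    of predictor k on the remaining predictors and recomputing the pivotal
    t statistic of the permuted residual in a regression that keeps the
    other predictors fixed. The model p-value node-permutes the response
    and compares R².
    """
    engine = engine or PermutationEngine()
    if not design.predictor_names:
        raise ValidationError("at least one predictor is required")
    x, names = _design_matrix(design)
    y = design.response
    n = design.n_nodes
    beta, t_full, r2 = _ols(x, y)

    perms = engine.permutations(n)
    p_values: dict[str, float] = {"Intercept": math.nan}

    for k in range(1, x.shape[1]):
        x_minus = np.delete(x, k, axis=1)
        gram_minus = x_minus.T @ x_minus
        coef_xk = np.linalg.solve(gram_minus, x_minus.T @ x[:, k])
        e_k = x[:, k] - x_minus @ coef_xk  # residual of predictor k on the rest
        e_mat = devectorize(e_k, n)
        r_y = y - x_minus @ np.linalg.solve(gram_minus, x_minus.T @ y)
        df = y.size - x.shape[1]

        def dsp_t(u: np.ndarray) -> float:
            coef_u = np.linalg.solve(gram_minus, x_minus.T @ u)
            u_t = u - x_minus @ coef_u  # residualise the permuted residual
            denom = u_t @ u_t
            if denom <= 0:
                return 0.0
            b = (u_t @ r_y) / denom
            rss = r_y @ r_y - b * b * denom
            sigma2 = rss / df
            if sigma2 <= 0:
                return math.inf if b != 0 else 0.0
            return b / math.sqrt(sigma2 / denom)

        t_obs = dsp_t(e_k)
        count = 0
        for perm in perms:
            t_perm = dsp_t(vectorize(e_mat[np.ix_(perm, perm)]))
            if _at_least(abs(t_perm), abs(t_obs)):
                count += 1
        p_values[names[k]] = engine.pvalue(count, len(perms))

    y_mat = devectorize(y, n)
    count_model = 0
    for perm in perms:
        _, _, r2_perm = _ols(x, vectorize(y_mat[np.ix_(perm, perm)]))
        if _at_least(r2_perm, r2):
            count_model += 1
    model_p = engine.pvalue(count_model, len(perms))

    return QapRegressionResult(
        coefficients=dict(zip(names, beta.astype(float))),
        p_values=p_values,
        model_p=model_p,
        fit_stat=float(r2),
        fit_stat_name="r_squared",
        n_obs=design.n_obs,
        n_permutations=len(perms),
        family="linear",
        scheme="dsp",
        metadata={"t_statistics": dict(zip(names, t_full.astype(float)))},
    )


# ---------------------------------------------------------------------------
# logistic LRQAP
# ---------------------------------------------------------------------------


def lrqap(
    design: DyadDesign,
    engine: PermutationEngine | None = None,
    scheme: str = "y_permute",
) -> QapRegressionResult:
    """Logistic network regression with node-permutation p-values.

    The response must be strictly binary with both classes present.
    ``scheme="y_permute"`` (default) rebuilds the null by node-permuting
    the response matrix and refitting the full model; ``scheme="dsp"``
    permutes each predictor's linear residual matrix instead, mirroring
    the MRQAP scheme in the logistic family. The two are never mixed: the
    scheme used is recorded on the result. The model p-value always comes
    from response permutation of the McFadden pseudo-R² fit statistic.
    """
    engine = engine or PermutationEngine()
    if scheme not in ("y_permute", "dsp"):
        raise ValidationError(f"unknown LRQAP scheme {scheme!r}")
    if not design.predictor_names:
        raise ValidationError("at least one predictor is required")
    y = design.response
    if not np.isin(y, [0, 1]).all():
        raise ValidationError("LRQAP requires a strictly binary response")
    if y.min() == y.max():
        raise ValidationError("response is constant (all 0 or all 1)")
    x, names = _design_matrix(design)
    n = design.n_nodes
    fit = _fit_logit_canonical if engine.exhaustive else _fit_logit

    beta, llf, converged = fit(x, y)
    if not converged:
        warnings.warn(
            "logistic fit did not converge cleanly (possible complete separation); "
            "estimates are flagged",
            stacklevel=2,
        )
    ll0 = _null_loglik(y)
    fit_stat = 1.0 - llf / ll0 if ll0 != 0 else math.nan

    perms = engine.permutations(n)
    y_mat = devectorize(y, n)
    p_values: dict[str, float] = {"Intercept": math.nan}
    counts = np.zeros(x.shape[1], dtype=int)
    count_model = 0

    if scheme == "y_permute":
        for perm in perms:
            y_perm = vectorize(y_mat[np.ix_(perm, perm)])
            b_perm, llf_perm, _ = fit(x, y_perm)
            counts += np.abs(b_perm) >= np.abs(beta) - _TIE_EPS
            fit_perm = 1.0 - llf_perm / ll0 if ll0 != 0 else math.nan
            if _at_least(fit_perm, fit_stat):
                count_model += 1
        for k in range(1, x.shape[1]):
            p_values[names[k]] = engine.pvalue(int(counts[k]), len(perms))
        model_p = engine.pvalue(count_model, len(perms))
    else:
        for k in range(1, x.shape[1]):
            x_minus = np.delete(x, k, axis=1)
            gram_minus = x_minus.T @ x_minus
            e_k = x[:, k] - x_minus @ np.linalg.solve(gram_minus, x_minus.T @ x[:, k])
            e_mat = devectorize(e_k, n)
            x_work = np.column_stack([x_minus, e_k])
            b_obs = fit(x_work, y)[0][-1]
            count = 0
            for perm in perms:
                x_work[:, -1] = vectorize(e_mat[np.ix_(perm, perm)])
                b_perm = fit(x_work, y)[0][-1]
                if _at_least(abs(b_perm), abs(b_obs)):
                    count += 1
            p_values[names[k]] = engine.pvalue(count, len(perms))
        for perm in perms:
            y_perm = vectorize(y_mat[np.ix_(perm, perm)])
            _, llf_perm, _ = fit(x, y_perm)
            fit_perm = 1.0 - llf_perm / ll0 if ll0 != 0 else math.nan
            if _at_least(fit_perm, fit_stat):
                count_model += 1
        model_p = engine.pvalue(count_model, len(perms))

    coefficients = dict(zip(names, beta.astype(float)))
    return QapRegressionResult(
        coefficients=coefficients,
        p_values=p_values,
        model_p=model_p,
        fit_stat=float(fit_stat),
        fit_stat_name="mcfadden_pseudo_r_squared",
        n_obs=design.n_obs,
        n_permutations=len(perms),
        family="logistic",
        odds_ratios={k: math.exp(v) for k, v in coefficients.items()},
        scheme=scheme,
        converged=converged,
        metadata={"log_likelihood": llf, "null_log_likelihood": ll0},
    )
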