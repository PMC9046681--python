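"""Rasch calibration by marginal maximum likelihood.

The measurement model is P(X = 1 | theta) = logistic(a (theta - b_i)) with a
standard-normal latent trait integrated out by Gauss-Hermite quadrature
(61 nodes by default).  The "constrained" model fixes the common discrimination
a = 1 (the Rasch model proper, making the total score sufficient for ability);
the "unconstrained" variant frees one common a.  On top of the fit sit the
item-screening circle (negative point-biserial + chi-square item fit), the
parametric-bootstrap global goodness-of-fit test, a Monte-Carlo second-
eigenvalue unidimensionality test on tetrachoric correlations, EAP ability
estimation, the total-score -> ability -> percent conversion table, and Lord's
chi-square DIF test with Holm correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit, roots_legendre
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

from .matrices import BinaryResponseMatrix, PipelineError, ValidationError

# ---------------------------------------------------------------------------
# Quadrature and marginal likelihood
# ---------------------------------------------------------------------------


def _gauss_hermite_normal(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights integrating against the standard normal density."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _compress(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(values, axis=0, return_counts=True)
    return patterns, counts.astype(float)


def _loglik_grad(
    b: np.ndarray,
    a: float,
    patterns: np.ndarray,
    counts: np.ndarray,
    theta: np.ndarray,
    w: np.ndarray,
    want_grad_a: bool,
):
    """Marginal log-likelihood and analytic gradient over unique patterns."""
    z = a * (theta[None, :] - b[:, None])  # k x Q
    P = expit(z)
    logP = log_expit(z)
    log1mP = log_expit(-z)
    L = patterns @ logP + (1 - patterns) @ log1mP  # U x Q
    M = L + np.log(w)[None, :]
    mx = M.max(axis=1, keepdims=True)
    lik = np.exp(M - mx)
    s = lik.sum(axis=1, keepdims=True)
    ll = float((counts * (np.log(s).ravel() + mx.ravel())).sum())
    post = (lik / s) * counts[:, None]  # U x Q, person-count weighted
    Nq = post.sum(axis=0)
    Rq = patterns.T @ post  # k x Q
    grad_b = a * (P * Nq[None, :] - Rq).sum(axis=1)
    grad_a = None
    if want_grad_a:
        grad_a = float(((Rq - Nq[None, :] * P) * (theta[None, :] - b[:, None])).sum())
    return ll, grad_b, grad_a


@dataclass
class RaschFit:
    item_codes: list[str]
    difficulties: np.ndarray
    difficulty_se: np.ndarray
    discrimination: float
    discrimination_se: float  # NaN when constrained
    constrained: bool
    log_likelihood: float
    aic: float
    n_quadrature: int
    converged: bool

    @property
    def n_items(self) -> int:
        return len(self.item_codes)

    @property
    def n_parameters(self) -> int:
        return self.n_items + (0 if self.constrained else 1)

    def prob(self, theta: np.ndarray) -> np.ndarray:
        """IRF values, persons/grid x items."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        return expit(self.discrimination * (theta[:, None] - self.difficulties[None, :]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"difficulty": self.difficulties, "se": self.difficulty_se},
            index=self.item_codes,
        )


def fit_rasch(
    matrix: BinaryResponseMatrix,
    constrained: bool = True,
    n_quadrature: int = 61,
    max_restarts: int = 3,
) -> RaschFit:
    """Fit the (un)constrained Rasch model by marginal maximum likelihood.

    Latent trait fixed at N(0, 1) for identification; standard errors come
    from the inverse observed information (numerical Hessian of the marginal
    deviance).  Deterministic given the data.
    """
    values = matrix.values
    p = values.mean(axis=0)
    if ((p == 0) | (p == 1)).any():
        raise ValidationError("fit_rasch requires no constant items")
    if matrix.n_persons < 30:
        warnings.warn("fewer than 30 persons: Rasch estimates will be unstable")
    theta, w = _gauss_hermite_normal(n_quadrature)
    patterns, counts = _compress(values)
    k = values.shape[1]

    def unpack(x):
        if constrained:
            return x, 1.0
        return x[:-1], float(np.exp(x[-1]))

    def objective(x):
        b, a = unpack(x)
        ll, gb, ga = _loglik_grad(b, a, patterns, counts, theta, w, not constrained)
        if constrained:
            return -ll, -gb
        # chain rule through a = exp(eta)
        return -ll, -np.concatenate([gb, [ga * a]])

    b0 = np.clip(-np.log(p / (1 - p)) * 1.2, -4, 4)
    x0 = b0 if constrained else np.concatenate([b0, [0.0]])
    bounds = [(-15.0, 15.0)] * k + ([] if constrained else [(-3.0, 3.0)])
    result = None
    for attempt in range(max_restarts):
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-9},
        )
        if res.success or res.status == 2:  # status 2: precision loss at optimum
            result = res
            break
        x0 = res.x + 0.1 * np.random.default_rng(attempt).standard_normal(len(x0))
    if result is None:
        raise PipelineError(f"Rasch optimization failed: {res.message}")
    b_hat, a_hat = unpack(result.x)
    ll = -result.fun
    n_par = k + (0 if constrained else 1)
    aic = -2 * ll + 2 * n_par
    # observed information via central differences of the analytic gradient
    hess = _numerical_hessian(objective, result.x)
    se = np.full(len(result.x), np.nan)
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; standard errors unavailable")
    if constrained:
        b_se, a_se = se, np.nan
    else:
        b_se = se[:-1]
        a_se = float(se[-1] * a_hat)  # delta method through a = exp(eta)
    return RaschFit(
        item_codes=list(matrix.item_codes),
        difficulties=np.asarray(b_hat, dtype=float),
        difficulty_se=np.asarray(b_se, dtype=float),
        discrimination=float(a_hat),
        discrimination_se=a_se,
        constrained=constrained,
        log_likelihood=ll,
        aic=aic,
        n_quadrature=n_quadrature,
        converged=True,
    )


def _numerical_hessian(objective, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    m = len(x)
    H = np.empty((m, m))
    for j in range(m):
        xp, xm = x.copy(), x.copy()
        xp[j] += eps
        xm[j] -= eps
        _, gp = objective(xp)
        _, gm = objective(xm)
        H[:, j] = (gp - gm) / (2 * eps)
    return (H + H.T) / 2


def select_model(
    fit_constrained: RaschFit, fit_unconstrained: RaschFit, tol: float = 1e-6
) -> tuple[RaschFit, float, float]:
    """Likelihood-ratio test of a = 1 plus AIC-based model choice.

    Returns (preferred fit by lower AIC, LR statistic, chi-square(1) p-value).
    """
    lr = 2 * (fit_unconstrained.log_likelihood - fit_constrained.log_likelihood)
    if lr < -tol:
        raise PipelineError(
            "unconstrained log-likelihood below constrained: optimization failure"
        )
    lr = max(lr, 0.0)
    p = float(chi2.sf(lr, df=1))
    choice = (
        fit_constrained
        if fit_constrained.aic <= fit_unconstrained.aic
        else fit_unconstrained
    )
    return choice, float(lr), p


# ---------------------------------------------------------------------------
# Stage I: screening
# ---------------------------------------------------------------------------


def point_biserial_flags(matrix: BinaryResponseMatrix) -> list[str]:
    """Items whose correlation with the total or the rest score is negative."""
    values = matrix.values.astype(float)
    total = values.sum(axis=1)
    if np.var(total) == 0:
        raise ValidationError("total score has zero variance")
    flagged = []
    for i, code in enumerate(matrix.item_codes):
        x = values[:, i]
        if np.var(x) == 0:
            continue  # constant item: no defined correlation, handled elsewhere
        rest = total - x
        r_total = np.corrcoef(x, total)[0, 1]
        r_rest = np.corrcoef(x, rest)[0, 1] if np.var(rest) > 0 else 0.0
        if r_total < 0 or r_rest < 0:
            flagged.append(code)
    return flagged


def conditional_pass_by_total(fit: RaschFit) -> np.ndarray:
    """Model-implied P(X_i = 1 | total score = r), a k x (K+1) matrix.

    Computed exactly from the marginal pattern distribution: at each quadrature
    node the total-score distribution is the coefficient vector of
    prod_i (1 - P_i + P_i z), built by the elementary-symmetric recursion;
    leave-one-out polynomials come from stable synthetic division (forward when
    P_i < 1/2, backward otherwise).  Columns r = 0 and r = K are the
    deterministic boundaries 0 and 1.
    """
    theta, w = _gauss_hermite_normal(fit.n_quadrature)
    P = expit(fit.discrimination * (theta[None, :] - fit.difficulties[:, None]))  # k x Q
    k, Q = P.shape
    # full polynomial per node: C[q, r] = P(TTS = r | theta_q)
    C = np.zeros((Q, k + 1))
    C[:, 0] = 1.0
    for i in range(k):
        pi = P[i][:, None]
        C[:, 1:] = C[:, 1:] * (1 - pi) + C[:, :-1] * pi
        C[:, 0] *= (1 - P[i])
    den = w @ C  # P(TTS = r)
    num = np.zeros((k, k + 1))
    for i in range(k):
        a_ = 1 - P[i]
        b_ = P[i]
        D = np.zeros((Q, k))  # leave-one-out polynomial coefficients
        fwd = P[i] < 0.5
        if fwd.any():
            Cf, af, bf = C[fwd], a_[fwd][:, None], b_[fwd][:, None]
            Df = np.zeros_like(Cf[:, :-1])
            Df[:, 0] = Cf[:, 0] / af[:, 0]
            for m in range(1, k):
                Df[:, m] = (Cf[:, m] - bf[:, 0] * Df[:, m - 1]) / af[:, 0]
            D[fwd] = Df
        if (~fwd).any():
            Cb, ab, bb = C[~fwd], a_[~fwd][:, None], b_[~fwd][:, None]
            Db = np.zeros_like(Cb[:, :-1])
            Db[:, k - 1] = Cb[:, k] / bb[:, 0]
            for m in range(k - 1, 0, -1):
                Db[:, m - 1] = (Cb[:, m] - ab[:, 0] * Db[:, m]) / bb[:, 0]
            D[~fwd] = Db
        # P(X_i = 1, TTS = r) = E_theta[ P_i * P(rest = r - 1) ]
        num[i, 1:] = (w * P[i]) @ D
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(den[None, :] > 0, num / den[None, :], np.nan)
    return np.clip(cond, 0.0, 1.0)


def item_fit(
    fit: RaschFit, matrix: BinaryResponseMatrix, n_groups: int = 10
) -> pd.DataFrame:
    """Chi-square item fit over EAP-ability groups.

    Persons are split into ``n_groups`` equal-count groups by EAP ability; for
    each item chi2 = sum_g n_g (O_g - E_g)^2 / (E_g (1 - E_g)), df = n_groups -
    #item parameters.  Because the grouping variable is a function of the total
    score, which contains the item itself, E_g is the model-implied conditional
    pass probability given the person's total score, P(X_i = 1 | TTS), averaged
    over the group — the naive IRF-at-EAP expectation is systematically biased
    on short scales.  Groups with a degenerate expectation (0 or 1, e.g. the
    all-pass score group) are skipped.  Returns raw and Bonferroni-adjusted p.
    """
    theta_hat = eap_abilities(fit, matrix)
    # quantize before ranking: persons with equal total scores have EAPs equal
    # up to ~1e-16 rounding noise that is pattern-correlated, and splitting a
    # tie block on that noise would bias the group composition
    order = np.argsort(np.round(theta_hat, 10), kind="stable")
    group_idx = [g for g in np.array_split(order, n_groups) if g.size > 0]
    cond = conditional_pass_by_total(fit)  # k x (K+1)
    tts = matrix.total_scores
    k = matrix.n_items
    df = len(group_idx) - (1 if fit.constrained else 2)
    rows = []
    for i, code in enumerate(matrix.item_codes):
        stat = 0.0
        for g in group_idx:
            e = cond[i, tts[g]].mean()
            if not 0 < e < 1:
                continue  # deterministic group (e.g. everyone at TTS = K)
            o = matrix.values[g, i].mean()
            stat += g.size * (o - e) ** 2 / (e * (1 - e))
        p_raw = float(chi2.sf(stat, df=df))
        rows.append({"item": code, "chi2": stat, "df": df, "p": p_raw,
                     "p_bonferroni": min(1.0, p_raw * k)})
    return pd.DataFrame(rows).set_index("item")


@dataclass
class ScreeningIteration:
    x1_negative_pb: list[str]
    x2_item_misfit: list[str]
    removed: list[str]
    chosen_constrained: bool
    lrt_stat: float
    lrt_p: float


@dataclass
class ScreeningLog:
    iterations: list[ScreeningIteration]

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def all_removed(self) -> list[str]:
        out: list[str] = []
        for it in self.iterations:
            out.extend(it.removed)
        return out


def screening_circle(
    matrix: BinaryResponseMatrix,
    alpha: float = 0.05,
    n_groups: int = 10,
    n_quadrature: int = 61,
) -> tuple[list[str], ScreeningLog, RaschFit]:
    """Iterate {point-biserial flags, model choice, item fit} until clean.

    Each circle removes X1 (items with a negative point-biserial against the
    total or rest score) union X2 (items with raw item-fit p < alpha under the
    AIC-preferred model); the loop stops when the removal set is empty.
    """
    current = matrix
    log = ScreeningLog(iterations=[])
    while True:
        if current.n_items < 3:
            raise PipelineError("screening circle left fewer than 3 items")
        x1 = point_biserial_flags(current)
        fit_c = fit_rasch(current, constrained=True, n_quadrature=n_quadrature)
        fit_u = fit_rasch(current, constrained=False, n_quadrature=n_quadrature)
        chosen, lrt, lrt_p = select_model(fit_c, fit_u)
        fits = item_fit(chosen, current, n_groups=n_groups)
        x2 = list(fits.index[fits["p"] < alpha])
        removed = sorted(set(x1) | set(x2), key=current.item_codes.index)
        log.iterations.append(
            ScreeningIteration(
                x1_negative_pb=x1, x2_item_misfit=x2, removed=removed,
                chosen_constrained=chosen.constrained, lrt_stat=lrt, lrt_p=lrt_p,
            )
        )
        if not removed:
            return list(current.item_codes), log, chosen
        keep = [c for c in current.item_codes if c not in set(removed)]
        if len(keep) < 3:
            raise PipelineError("screening circle left fewer than 3 items")
        current = current.select_items(keep)


# ---------------------------------------------------------------------------
# Stage II: global model checks
# ---------------------------------------------------------------------------


def bootstrap_p(n_exceed: int, n_replicates: int) -> float:
    """Parametric-bootstrap p-value (1 + N+) / (B + 1)."""
    if not 0 <= n_exceed <= n_replicates:
        raise ValidationError("need 0 <= n_exceed <= n_replicates")
    return (1 + n_exceed) / (n_replicates + 1)


def _pattern_chi2(fit: RaschFit, values: np.ndarray) -> float:
    """Pearson chi-square over the observed unique response patterns."""
    theta, w = _gauss_hermite_normal(fit.n_quadrature)
    patterns, counts = _compress(values)
    z = fit.discrimination * (theta[None, :] - fit.difficulties[:, None])
    L = patterns @ log_expit(z) + (1 - patterns) @ log_expit(-z)
    probs = np.exp(L) @ w
    expected = values.shape[0] * probs
    return float(((counts - expected) ** 2 / expected).sum())


@dataclass
class GofResult:
    t_obs: float
    t_sim: np.ndarray
    B: int
    n_exceed: int
    p: float


def bootstrap_gof(
    fit: RaschFit, matrix: BinaryResponseMatrix, B: int = 199, seed: int = 0
) -> GofResult:
    """Parametric bootstrap of the pattern-level Pearson chi-square.

    B data sets of the same size are simulated from the fitted model, each
    refitted and scored; p = (1 + #{T_b > T_obs}) / (B + 1).
    """
    t_obs = _pattern_chi2(fit, matrix.values)
    rng = np.random.default_rng(seed)
    n = matrix.n_persons
    t_sim = np.empty(B)
    for b in range(B):
        sim = _simulate_from_fit(fit, n, rng)
        sim_matrix = BinaryResponseMatrix(sim, person_ids=None, item_codes=list(fit.item_codes))
        try:
            refit = fit_rasch(sim_matrix, constrained=fit.constrained,
                              n_quadrature=fit.n_quadrature)
        except ValidationError:  # degenerate replicate (constant item): score with fit
            refit = fit
        t_sim[b] = _pattern_chi2(refit, sim)
    n_exceed = int((t_sim > t_obs).sum())
    return GofResult(t_obs=t_obs, t_sim=t_sim, B=B, n_exceed=n_exceed,
                     p=bootstrap_p(n_exceed, B))


def _simulate_from_fit(fit: RaschFit, n: int, rng: np.random.Generator) -> np.ndarray:
    theta = rng.standard_normal(n)
    probs = fit.prob(theta)
    return (rng.random(probs.shape) < probs).astype(int)


def _bvn_upper(h: float, k_: float, rho: float, n_nodes: int = 48) -> float:
    """P(Z1 > h, Z2 > k) for standard bivariate normal with correlation rho.

    Uses the identity d/dr Phi2 = bivariate density, integrated from r = 0 by
    Gauss-Legendre quadrature.
    """
    phi_h, phi_k = norm.sf(h), norm.sf(k_)
    if rho == 0:
        return phi_h * phi_k
    x, w = roots_legendre(n_nodes)
    t = 0.5 * rho * (x + 1.0)
    dens = np.exp(-(h * h - 2 * t * h * k_ + k_ * k_) / (2 * (1 - t * t))) / (
        2 * np.pi * np.sqrt(1 - t * t)
    )
    integral = 0.5 * rho * (w * dens).sum()
    return phi_h * phi_k + integral


def tetrachoric(x: np.ndarray, y: np.ndarray) -> float:
    """Pairwise-ML tetrachoric correlation with 0.5 empty-cell correction.

    Falls back to the phi coefficient (with a warning) when the latent-normal
    solve fails.
    """
    n11 = float(((x == 1) & (y == 1)).sum())
    n10 = float(((x == 1) & (y == 0)).sum())
    n01 = float(((x == 0) & (y == 1)).sum())
    n00 = float(((x == 0) & (y == 0)).sum())
    if min(n11, n10, n01, n00) == 0:
        n11 += 0.5
        n10 += 0.5
        n01 += 0.5
        n00 += 0.5
    n = n11 + n10 + n01 + n00
    px, py = (n11 + n10) / n, (n11 + n01) / n
    h, k_ = norm.isf(px), norm.isf(py)
    target = n11 / n

    def f(r):
        return _bvn_upper(h, k_, r) - target

    try:
        return float(optimize.brentq(f, -0.9999, 0.9999, xtol=1e-10))
    except ValueError:
        warnings.warn("tetrachoric solve failed for a pair; using phi coefficient")
        return float(np.corrcoef(x, y)[0, 1])


def tetrachoric_matrix(values: np.ndarray) -> np.ndarray:
    k = values.shape[1]
    R = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            R[i, j] = R[j, i] = tetrachoric(values[:, i], values[:, j])
    return R


def second_eigenvalue(values: np.ndarray) -> float:
    eig = np.linalg.eigvalsh(tetrachoric_matrix(values))
    return float(np.sort(eig)[-2])


@dataclass
class UnidimResult:
    second_eigenvalue_obs: float
    second_eigenvalues_sim: np.ndarray
    p: float


def unidim_test(
    fit: RaschFit, matrix: BinaryResponseMatrix, n_sim: int = 100, seed: int = 0
) -> UnidimResult:
    """Monte-Carlo second-eigenvalue test of unidimensionality.

    The observed statistic is the second-largest eigenvalue of the tetrachoric
    correlation matrix; the null distribution comes from ``n_sim`` data sets
    simulated from the fitted (unidimensional) model.  One-sided
    p = (1 + #{sim >= obs}) / (n_sim + 1).
    """
    obs = second_eigenvalue(matrix.values)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_sim)
    for s in range(n_sim):
        sims[s] = second_eigenvalue(_simulate_from_fit(fit, matrix.n_persons, rng))
    p = (1 + int((sims >= obs).sum())) / (n_sim + 1)
    return UnidimResult(second_eigenvalue_obs=obs, second_eigenvalues_sim=sims, p=p)


# ---------------------------------------------------------------------------
# Stage III: abilities, conversion, DIF, curves
# ---------------------------------------------------------------------------


def eap_abilities(fit: RaschFit, matrix: BinaryResponseMatrix) -> np.ndarray:
    """Expected a posteriori ability per person under the N(0,1) prior."""
    theta, w = _gauss_hermite_normal(fit.n_quadrature)
    z = fit.discrimination * (theta[None, :] - fit.difficulties[:, None])
    L = matrix.values @ log_expit(z) + (1 - matrix.values) @ log_expit(-z)
    M = L + np.log(w)[None, :]
    M -= M.max(axis=1, keepdims=True)
    lik = np.exp(M)
    return (lik @ theta) / lik.sum(axis=1)


def eap_by_total_score(fit: RaschFit) -> np.ndarray:
    """EAP ability at each total score 0..K.

    Both model variants share one discrimination across items, so the total
    score is sufficient and the posterior depends on the response pattern only
    through it.
    """
    theta, w = _gauss_hermite_normal(fit.n_quadrature)
    a = fit.discrimination
    # log of prod_i (1 + exp(a (theta - b_i))) at each node
    log_denom = np.logaddexp(
        0.0, a * (theta[None, :] - fit.difficulties[:, None])
    ).sum(axis=0)
    K = fit.n_items
    out = np.empty(K + 1)
    for r in range(K + 1):
        logpost = np.log(w) + a * r * theta - log_denom
        logpost -= logpost.max()
        post = np.exp(logpost)
        out[r] = (post * theta).sum() / post.sum()
    return out


@dataclass
class ScoreConversionTable:
    total_score: np.ndarray
    theta: np.ndarray
    percent: np.ndarray
    coefficients: tuple[float, float, float]  # beta0 + beta1 TTS + beta2 TTS^2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"total_score": self.total_score, "theta": self.theta, "percent": self.percent}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_pairs(cls, total_score, theta, percent=None) -> "ScoreConversionTable":
        """Build from (TTS, theta) pairs; percent is recomputed unless given."""
        tts = np.asarray(total_score, dtype=int)
        th = np.asarray(theta, dtype=float)
        if not np.all(np.diff(th) > 0):
            raise PipelineError("ability must be strictly increasing in the total score")
        if percent is None:
            percent = percent_scale(th)
        X = np.vstack([np.ones_like(th), tts, tts**2]).T
        beta = np.linalg.lstsq(X, th, rcond=None)[0]
        return cls(tts, th, np.asarray(percent, dtype=int), tuple(float(x) for x in beta))


def percent_scale(theta: np.ndarray) -> np.ndarray:
    """Linear 0-100 rescale of the ability column, half rounded away from zero."""
    th = np.asarray(theta, dtype=float)
    x = 100.0 * (th - th[0]) / (th[-1] - th[0])
    return np.floor(x + 0.5).astype(int)  # x >= 0, so this is half-away-from-zero


def score_conversion_table(fit: RaschFit) -> ScoreConversionTable:
    """Total score -> EAP ability (logits) -> percent (0-100), with the
    quadratic OLS approximation theta ~ beta0 + beta1 TTS + beta2 TTS^2."""
    th = eap_by_total_score(fit)
    return ScoreConversionTable.from_pairs(np.arange(fit.n_items + 1), th)


@dataclass
class DifResult:
    table: pd.DataFrame  # per item: chi2, df, p, p_holm, flagged
    group_sizes: dict[str, int]
    reference_group: str
    equating_shift: float
    excluded_items: list[str]
    icc_curves: pd.DataFrame | None  # ICC data per group for flagged items


def dif_lord(
    matrix: BinaryResponseMatrix,
    groups,
    alpha: float = 0.05,
    n_quadrature: int = 61,
    theta_grid: np.ndarray | None = None,
) -> DifResult:
    """Lord's chi-square test of uniform DIF between two groups.

    A constrained Rasch model is fitted per group; focal-group difficulties are
    shifted so group mean difficulties agree (equal-mean equating); per item
    chi2 = (b_ref - b_foc)^2 / (se_ref^2 + se_foc^2), df = 1, with Holm
    adjustment over items.  Items constant within a group are excluded and
    reported.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValidationError("dif_lord requires exactly two groups")
    sizes = {str(lab): int((groups == lab).sum()) for lab in labels}
    if min(sizes.values()) < 20:
        warnings.warn("a DIF group has fewer than 20 persons; results are unstable")
    ref_label = labels[np.argmax([sizes[str(lab)] for lab in labels])]
    foc_label = labels[labels != ref_label][0]
    masks = {str(lab): groups == lab for lab in labels}
    # exclude items degenerate within either group
    excluded = []
    keep = []
    for i, code in enumerate(matrix.item_codes):
        ok = True
        for lab in labels:
            col = matrix.values[masks[str(lab)], i]
            if col.min() == col.max():
                ok = False
        (keep if ok else excluded).append(code)
    if len(keep) < 2:
        raise PipelineError("fewer than 2 items usable for DIF")
    sub = matrix.select_items(keep)
    fits = {}
    for lab in labels:
        m = masks[str(lab)]
        g_matrix = BinaryResponseMatrix(
            sub.values[m],
            [pid for pid, mm in zip(sub.person_ids, m) if mm],
            list(sub.item_codes),
        )
        fits[str(lab)] = fit_rasch(g_matrix, constrained=True, n_quadrature=n_quadrature)
    b_ref = fits[str(ref_label)].difficulties
    b_foc = fits[str(foc_label)].difficulties
    shift = float(b_ref.mean() - b_foc.mean())
    b_foc_eq = b_foc + shift
    se2 = fits[str(ref_label)].difficulty_se ** 2 + fits[str(foc_label)].difficulty_se ** 2
    stat = (b_ref - b_foc_eq) ** 2 / se2
    p_raw = chi2.sf(stat, df=1)
    _, p_holm, _, _ = multipletests(p_raw, method="holm")
    flagged = p_holm < alpha
    table = pd.DataFrame(
        {"chi2": stat, "df": 1, "p": p_raw, "p_holm": p_holm, "flagged": flagged},
        index=keep,
    )
    icc = None
    if flagged.any():
        grid = theta_grid if theta_grid is not None else np.linspace(-4, 4, 81)
        rows = []
        for code in np.asarray(keep)[flagged]:
            i = keep.index(code)
            for lab, b in ((ref_label, b_ref[i]), (foc_label, b_foc_eq[i])):
                rows.append(pd.DataFrame({
                    "item": code, "group": str(lab), "theta": grid,
                    "prob": expit(grid - b),
                }))
        icc = pd.concat(rows, ignore_index=True)
    return DifResult(
        table=table, group_sizes=sizes, reference_group=str(ref_label),
        equating_shift=shift, excluded_items=excluded, icc_curves=icc,
    )


@dataclass
class CurveData:
    icc: pd.DataFrame  # theta grid x items, IRF values
    item_locations: pd.DataFrame  # difficulty per item
    person_abilities: np.ndarray | None  # EAP distribution for the Wright map


def export_curves(
    fit: RaschFit,
    matrix: BinaryResponseMatrix | None = None,
    theta_grid: np.ndarray | None = None,
) -> CurveData:
    """ICC tables and Wright-map data (person EAPs + item locations)."""
    grid = theta_grid if theta_grid is not None else np.linspace(-4, 4, 81)
    icc = pd.DataFrame(fit.prob(grid), index=pd.Index(grid, name="theta"),
                       columns=fit.item_codes)
    locations = pd.DataFrame({"difficulty": fit.difficulties}, index=fit.item_codes)
    abilities = eap_abilities(fit, matrix) if matrix is not None else None
    return CurveData(icc=icc, item_locations=locations, person_abilities=abilities)
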