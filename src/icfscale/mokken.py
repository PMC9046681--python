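"""Mokken scale analysis on dichotomous items.

Implements the scale-formation and reliability stages of nonparametric IRT
scale construction: Loevinger-type scalability coefficients (Hij, Hi, H) with
bootstrap standard errors, the automated item selection procedure (AISP) driven
by a genetic algorithm, diagnostics for the three monotone-homogeneity
hypotheses (local independence via conditional-association W indices,
manifest monotonicity with the #ac/#vi/#zsig/Crit summary, manifest invariant
item ordering with backward selection), and four reliability coefficients
(Cronbach's alpha, Guttman's lambda2, Molenaar-Sijtsma rho, and the latent
class reliability coefficient).

All statistics are defined for complete {0,1} matrices; run the shaping stage
first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matrices import BinaryResponseMatrix, PipelineError, ValidationError

# ---------------------------------------------------------------------------
# Scalability coefficients
# ---------------------------------------------------------------------------


@dataclass
class ScalabilityResult:
    H: float
    H_se: float
    Hi: np.ndarray
    Hi_se: np.ndarray
    Hij: np.ndarray  # symmetric; NaN where undefined
    item_codes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Hi": self.Hi, "Hi_se": self.Hi_se}, index=self.item_codes
        )


def _pair_quantities(values: np.ndarray):
    """Margins, joint pass proportions, and Guttman-error counts per item pair.

    For a pair the "easier" item is the more popular one (ties broken by column
    order); an error cell is easier failed & harder passed.  F is the observed
    error count, E = n * (1 - p_easier) * p_harder the count expected under
    marginal independence.
    """
    n, k = values.shape
    p = values.mean(axis=0)
    joint = (values.T @ values) / n  # joint pass proportions
    # easier[i, j] True when i is the easier item of the pair
    order_rank = np.lexsort((np.arange(k), -p))  # popularity order, stable
    rank = np.empty(k, dtype=int)
    rank[order_rank] = np.arange(k)
    i_easier = rank[:, None] < rank[None, :]
    p_e = np.where(i_easier, p[:, None], p[None, :])
    p_h = np.where(i_easier, p[None, :], p[:, None])
    F = n * (p_h - joint)
    E = n * (1.0 - p_e) * p_h
    np.fill_diagonal(F, 0.0)
    np.fill_diagonal(E, 0.0)
    return p, joint, F, E


def _h_coefficients(values: np.ndarray):
    p, joint, F, E = _pair_quantities(values)
    cov = joint - np.outer(p, p)
    denom = np.minimum(p[:, None], p[None, :]) - np.outer(p, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        Hij = np.where(denom != 0, cov / denom, np.nan)
    np.fill_diagonal(Hij, np.nan)
    sumE = E.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Hi = np.where(sumE > 0, 1.0 - F.sum(axis=1) / sumE, np.nan)
    totE = E.sum() / 2
    H = 1.0 - (F.sum() / 2) / totE if totE > 0 else np.nan
    return H, Hi, Hij


def scalability(
    matrix: BinaryResponseMatrix, n_boot: int = 1000, seed: int = 0
) -> ScalabilityResult:
    """Loevinger scalability coefficients with person-bootstrap standard errors.

    Hij is the ratio of the observed inter-item covariance to its maximum given
    the margins, equivalently 1 minus the ratio of observed to expected Guttman
    errors for the pair; Hi and H aggregate error counts over an item's pairs
    and over all pairs.  Pairs whose margins make the maximum covariance zero
    are undefined and reported as NaN with a warning.
    """
    values = matrix.values
    if ((values.mean(axis=0) == 0) | (values.mean(axis=0) == 1)).any():
        raise ValidationError("scalability requires no constant items")
    H, Hi, Hij = _h_coefficients(values)
    off_diag = ~np.eye(len(Hi), dtype=bool)
    if np.isnan(Hij[off_diag]).any():
        warnings.warn("some Hij undefined (degenerate pair margins); reported as NaN")
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    h_boot = np.full(n_boot, np.nan)
    hi_boot = np.full((n_boot, len(Hi)), np.nan)
    for b in range(n_boot):
        sample = values[rng.integers(0, n, size=n)]
        if ((sample.mean(axis=0) == 0) | (sample.mean(axis=0) == 1)).any():
            continue  # degenerate resample: excluded from the SE
        hb, hib, _ = _h_coefficients(sample)
        h_boot[b] = hb
        hi_boot[b] = hib
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        H_se = float(np.nanstd(h_boot, ddof=1)) if n_boot > 1 else np.nan
        Hi_se = np.nanstd(hi_boot, axis=0, ddof=1) if n_boot > 1 else np.full_like(Hi, np.nan)
    return ScalabilityResult(
        H=float(H), H_se=H_se, Hi=Hi, Hi_se=Hi_se, Hij=Hij, item_codes=list(matrix.item_codes)
    )


# ---------------------------------------------------------------------------
# AISP via a genetic algorithm
# ---------------------------------------------------------------------------


@dataclass
class GaParams:
    """Genetic-algorithm settings: population 20, crossover 0.05, mutation 0.1."""

    population_size: int = 20
    crossover_prob: float = 0.05
    mutation_prob: float = 0.1
    n_generations: int = 500
    elitism: int = 1


@dataclass
class AispResult:
    cut_value: float
    assignment: dict[str, int]  # item code -> scale index (0 = unscalable)
    scales: list[list[str]]
    ga_params: GaParams
    seed: int

    def n_in_scale(self, index: int) -> int:
        return sum(1 for v in self.assignment.values() if v == index)


class _SubsetEvaluator:
    """Fast within-subset Hi / Hij feasibility checks from precomputed pair counts."""

    def __init__(self, values: np.ndarray):
        p, joint, F, E = _pair_quantities(values)
        cov = joint - np.outer(p, p)
        denom = np.minimum(p[:, None], p[None, :]) - np.outer(p, p)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.Hij = np.where(denom != 0, cov / denom, np.nan)
        self.F = F
        self.E = E

    def subset_hi(self, idx: np.ndarray) -> np.ndarray:
        Fs = self.F[np.ix_(idx, idx)].sum(axis=1)
        Es = self.E[np.ix_(idx, idx)].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(Es > 0, 1.0 - Fs / Es, -np.inf)

    def repair(self, idx: np.ndarray, cut: float) -> np.ndarray:
        """Shrink a candidate subset until every Hi >= cut and every Hij > 0."""
        idx = np.asarray(idx, dtype=int)
        while idx.size >= 2:
            hi = self.subset_hi(idx)
            sub_hij = self.Hij[np.ix_(idx, idx)]
            off = ~np.eye(idx.size, dtype=bool)
            bad_pairs = off & (~(sub_hij > 0))  # non-positive or undefined
            if not bad_pairs.any() and (hi >= cut).all():
                return idx
            if bad_pairs.any():
                in_bad = bad_pairs.any(axis=1)
                cand = np.flatnonzero(in_bad)
                drop = cand[np.argmin(hi[cand])]
            else:
                drop = int(np.argmin(hi))
            idx = np.delete(idx, drop)
        return np.empty(0, dtype=int)


def _ga_search(
    evaluator: _SubsetEvaluator,
    candidates: np.ndarray,
    cut: float,
    params: GaParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Largest feasible item subset among ``candidates`` (global item indices)."""
    m = candidates.size
    if m < 2:
        return np.empty(0, dtype=int)

    def fitness(chrom: np.ndarray):
        sel = candidates[chrom]
        repaired = evaluator.repair(sel, cut)
        score = repaired.size
        bonus = evaluator.subset_hi(repaired).sum() if repaired.size >= 2 else 0.0
        return score, bonus, repaired

    pop = rng.random((params.population_size, m)) < 0.5
    pop[0] = True  # seed with the full candidate set
    best_score, best_bonus, best_subset = -1, -np.inf, np.empty(0, dtype=int)
    for _ in range(params.n_generations):
        scored = [fitness(c) for c in pop]
        for (score, bonus, repaired), chrom in zip(scored, pop):
            if (score, bonus) > (best_score, best_bonus):
                best_score, best_bonus, best_subset = score, bonus, repaired
        if best_score == m:
            break  # the whole candidate set is feasible
        keys = np.array([(s, b) for s, b, _ in scored], dtype=float)
        new_pop = np.empty_like(pop)
        # elitism: re-inject the best repaired subset as a chromosome
        elite = np.isin(candidates, best_subset)
        new_pop[0] = elite
        for row in range(1, params.population_size):
            a, b = rng.integers(0, params.population_size, size=2)
            parent = pop[a] if tuple(keys[a]) >= tuple(keys[b]) else pop[b]
            child = parent.copy()
            if rng.random() < params.crossover_prob:
                c, d = rng.integers(0, params.population_size, size=2)
                other = pop[c] if tuple(keys[c]) >= tuple(keys[d]) else pop[d]
                mask = rng.random(m) < 0.5
                child = np.where(mask, parent, other)
            flip = rng.random(m) < params.mutation_prob
            child ^= flip
            new_pop[row] = child
        pop = new_pop
    return best_subset


def aisp(
    matrix: BinaryResponseMatrix,
    cut_value: float,
    ga_params: GaParams | None = None,
    seed: int = 0,
) -> AispResult:
    """Automated item selection at boundary ``cut_value``.

    Scales are formed sequentially: a genetic algorithm searches the largest
    subset of the remaining items in which every within-subset Hi >= c and
    every within-subset Hij > 0; the subset becomes the next scale and the
    search repeats on the leftovers.  Items never placed are assigned 0.
    """
    if not 0 < cut_value < 1:
        raise ValidationError("cut_value must lie in (0, 1)")
    params = ga_params or GaParams()
    rng = np.random.default_rng(seed)
    evaluator = _SubsetEvaluator(matrix.values)
    remaining = np.arange(matrix.n_items)
    assignment = {code: 0 for code in matrix.item_codes}
    scales: list[list[str]] = []
    while remaining.size >= 2:
        subset = _ga_search(evaluator, remaining, cut_value, params, rng)
        if subset.size < 2:
            break
        codes = [matrix.item_codes[i] for i in sorted(subset)]
        scales.append(codes)
        for c in codes:
            assignment[c] = len(scales)
        remaining = remaining[~np.isin(remaining, subset)]
    return AispResult(
        cut_value=cut_value, assignment=assignment, scales=scales,
        ga_params=params, seed=seed,
    )


def aisp_scan(
    matrix: BinaryResponseMatrix,
    c_from: float = 0.30,
    c_to: float = 0.54,
    c_step: float = 0.03,
    ga_params: GaParams | None = None,
    seed: int = 0,
) -> list[AispResult]:
    """AISP over a grid of boundary values (default 0.30 to 0.54, step 0.03)."""
    if c_step <= 0 or c_to < c_from:
        raise ValidationError("invalid AISP scan grid")
    grid = np.arange(c_from, c_to + c_step / 2, c_step)
    if grid.size == 0:
        raise ValidationError("empty AISP scan grid")
    return [aisp(matrix, float(c), ga_params, seed) for c in grid]


def aisp_scan_table(results: list[AispResult]) -> pd.DataFrame:
    """Tidy assignment-by-cut table (items as rows, one column per cut value)."""
    data = {f"c={r.cut_value:.2f}": r.assignment for r in results}
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Hypothesis I: local independence (conditional association W indices)
# ---------------------------------------------------------------------------


@dataclass
class ConditionalAssociationResult:
    W1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    W_plus: np.ndarray
    fence: float
    flagged_items: list[str]
    item_codes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"W1": self.W1, "W2": self.W2, "W3": self.W3, "W_plus": self.W_plus,
             "flagged": [c in set(self.flagged_items) for c in self.item_codes]},
            index=self.item_codes,
        )


def _stratum_covs(x: np.ndarray, y: np.ndarray, strata: np.ndarray, min_size: int):
    """Sample covariances of (x, y) within strata holding >= min_size persons."""
    covs = []
    for v in np.unique(strata):
        sel = strata == v
        m = int(sel.sum())
        if m < min_size:
            continue
        xs, ys = x[sel], y[sel]
        covs.append(float((xs * ys).mean() - xs.mean() * ys.mean()) * m / (m - 1))
    return covs


def check_conditional_association(
    matrix: BinaryResponseMatrix, min_stratum: int = 4
) -> ConditionalAssociationResult:
    """Local-independence diagnostics via negative conditional covariances.

    Three conditioning regimes feed each item's indices: W1 pools pair
    covariances given the rest score over the remaining items, for pairs
    containing the item; W2 pools pair covariances given each third item's
    value, for pairs containing the item; W3 pools covariances of other-item
    pairs given the item's own value.  In each regime only strata with at
    least ``min_stratum`` persons count, each negative covariance enters with
    weight equal to the proportion of negative covariances in that regime (no
    sample-size weighting), and W is that weight times the summed magnitude of
    the negatives.  W+ = W1 + W2 + W3 is screened against the one-sided Tukey
    fence Q3 + 3 (Q3 - M).
    """
    values = matrix.values
    n, k = values.shape
    if k < 3:
        raise ValidationError("conditional association needs at least 3 items")
    total = values.sum(axis=1)
    reg1: list[list[float]] = [[] for _ in range(k)]
    reg2: list[list[float]] = [[] for _ in range(k)]
    reg3: list[list[float]] = [[] for _ in range(k)]
    # regime 1: rest-score conditioning, pair-specific rest
    for i in range(k):
        for j in range(i + 1, k):
            rest = total - values[:, i] - values[:, j]
            covs = _stratum_covs(values[:, i], values[:, j], rest, min_stratum)
            reg1[i].extend(covs)
            reg1[j].extend(covs)
    # regimes 2 and 3: conditioning on a third item's value
    for c in range(k):
        for v in (0, 1):
            sel = values[:, c] == v
            m = int(sel.sum())
            if m < min_stratum:
                continue
            sub = values[sel]
            mu = sub.mean(axis=0)
            cov = (sub.T @ sub) / m - np.outer(mu, mu)
            cov *= m / (m - 1)
            for i in range(k):
                if i == c:
                    continue
                for j in range(i + 1, k):
                    if j == c:
                        continue
                    reg2[i].append(float(cov[i, j]))
                    reg2[j].append(float(cov[i, j]))
                    reg3[c].append(float(cov[i, j]))

    def _w(covs: list[float]) -> float:
        if not covs:
            return 0.0
        arr = np.asarray(covs)
        neg = arr[arr < 0]
        if neg.size == 0:
            return 0.0
        return (neg.size / arr.size) * float(-neg.sum())

    W1 = np.array([_w(c) for c in reg1])
    W2 = np.array([_w(c) for c in reg2])
    W3 = np.array([_w(c) for c in reg3])
    available = np.array([bool(reg1[i] or reg2[i] or reg3[i]) for i in range(k)])
    W_plus = np.where(available, W1 + W2 + W3, np.nan)
    ok = W_plus[~np.isnan(W_plus)]
    med, q3 = np.percentile(ok, [50, 75])
    fence = float(q3 + 3 * (q3 - med))
    flagged = [matrix.item_codes[i] for i in range(k) if available[i] and W_plus[i] > fence]
    return ConditionalAssociationResult(
        W1=W1, W2=W2, W3=W3, W_plus=W_plus, fence=fence,
        flagged_items=flagged, item_codes=list(matrix.item_codes),
    )


# ---------------------------------------------------------------------------
# Hypothesis II: manifest monotonicity
# ---------------------------------------------------------------------------


@dataclass
class ItemMonotonicity:
    code: str
    active_comparisons: int  # ac
    violations: int  # vi
    significant: int  # zsig
    max_violation: float
    max_z: float
    sum_violations: float
    crit: float
    n_groups: int
    valid: bool


@dataclass
class MonotonicityResult:
    items: list[ItemMonotonicity]
    minsize: int
    minvi: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"item": r.code, "#ac": r.active_comparisons, "#vi": r.violations,
              "#zsig": r.significant, "maxvi": r.max_violation, "max_z": r.max_z,
              "crit": r.crit, "groups": r.n_groups, "valid": r.valid}
             for r in self.items]
        ).set_index("item")


def _merge_rest_groups(rest: np.ndarray, minsize: int) -> np.ndarray:
    """Group labels from rest scores, merging adjacent scores from the low end
    until every group holds at least ``minsize`` persons."""
    order_vals, counts = np.unique(rest, return_counts=True)
    labels = np.empty_like(order_vals)
    group, acc = 0, 0
    for idx, c in enumerate(counts):
        labels[idx] = group
        acc += c
        if acc >= minsize:
            group += 1
            acc = 0
    if acc > 0 and group > 0:
        labels[labels == group] = group - 1  # trailing short group joins previous
    mapping = dict(zip(order_vals, labels))
    return np.array([mapping[v] for v in rest])


def crit_value(
    hi: float, ac: int, vi: int, zsig: int,
    maxvi: float, sum_vi: float, max_z: float,
) -> float:
    """Weighted composite effect size of model violations (values > 40 are
    conventionally read as serious)."""
    if ac == 0:
        return 0.0
    c = (
        50 * (0.30 - hi)
        + np.sqrt(vi)
        + 100 * (vi / ac)
        + 100 * maxvi
        + 10 * np.sqrt(sum_vi)
        + 1000 * (sum_vi / ac)
        + 5 * max_z
        + 10 * np.sqrt(zsig)
        + 100 * (zsig / ac)
    )
    return float(max(c, 0.0))


def check_monotonicity(
    matrix: BinaryResponseMatrix,
    minsize: int = 50,
    minvi: float = 0.03,
    alpha: float = 0.05,
) -> MonotonicityResult:
    """Manifest-monotonicity check against rest-score groups.

    Persons are grouped by the rest score (total minus the item), adjacent
    scores merged from the low end until every group has >= minsize persons.
    A violation is a decrease in the item's pass proportion larger than
    ``minvi`` between a lower and a higher group; each violation gets a
    one-sided pooled two-proportion z test at level ``alpha``.
    """
    values = matrix.values
    n, k = values.shape
    if n < minsize:
        raise ValidationError(f"need at least minsize={minsize} persons")
    total = values.sum(axis=1)
    zcrit = norm.ppf(1 - alpha)
    H, Hi, _ = _h_coefficients(values)
    out = []
    for i in range(k):
        rest = total - values[:, i]
        groups = _merge_rest_groups(rest, minsize)
        glabels = np.unique(groups)
        G = glabels.size
        if G < 2:
            out.append(ItemMonotonicity(matrix.item_codes[i], 0, 0, 0, 0.0, 0.0, 0.0,
                                        0.0, G, valid=False))
            continue
        ng = np.array([(groups == g).sum() for g in glabels])
        pg = np.array([values[groups == g, i].mean() for g in glabels])
        ac = G * (G - 1) // 2
        vi = zsig = 0
        maxvi = max_z = sum_vi = 0.0
        for lo in range(G):
            for hiG in range(lo + 1, G):
                diff = pg[lo] - pg[hiG]
                if diff > minvi:
                    vi += 1
                    sum_vi += diff
                    maxvi = max(maxvi, diff)
                    pool = (ng[lo] * pg[lo] + ng[hiG] * pg[hiG]) / (ng[lo] + ng[hiG])
                    se = np.sqrt(pool * (1 - pool) * (1 / ng[lo] + 1 / ng[hiG]))
                    z = diff / se if se > 0 else np.inf
                    max_z = max(max_z, z)
                    if z > zcrit:
                        zsig += 1
        crit = crit_value(float(Hi[i]), ac, vi, zsig, maxvi, sum_vi, max_z)
        out.append(ItemMonotonicity(matrix.item_codes[i], ac, vi, zsig, maxvi,
                                    max_z, sum_vi, crit, G, valid=True))
    return MonotonicityResult(items=out, minsize=minsize, minvi=minvi)


# ---------------------------------------------------------------------------
# Hypothesis III: manifest invariant item ordering
# ---------------------------------------------------------------------------


@dataclass
class IioResult:
    pairwise: pd.DataFrame  # one row per (easier, harder, group) violation test
    sig_counts: dict[str, int]  # per item, significant violations in the first round
    removed_items: list[str]  # backward-selection removal order
    final_items: list[str]
    minsize: int
    minvi: float


def _miio_round(values, codes, minsize, minvi, zcrit):
    """One MIIO sweep: significant-violation counts per item plus the test table."""
    n, k = values.shape
    pop = values.mean(axis=0)
    order = np.lexsort((np.arange(k), -pop))  # descending popularity, stable
    total = values.sum(axis=1)
    counts = {c: 0 for c in codes}
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            e, h = order[a], order[b]  # e easier (more popular), h harder
            rest = total - values[:, e] - values[:, h]
            groups = _merge_rest_groups(rest, minsize)
            for g in np.unique(groups):
                sel = groups == g
                if sel.sum() == 0:
                    continue
                pe = values[sel, e].mean()
                ph = values[sel, h].mean()
                diff = ph - pe
                if diff <= minvi:
                    continue
                n01 = int(((values[sel, e] == 0) & (values[sel, h] == 1)).sum())
                n10 = int(((values[sel, e] == 1) & (values[sel, h] == 0)).sum())
                z = (n01 - n10) / np.sqrt(n01 + n10) if (n01 + n10) > 0 else 0.0
                sig = z > zcrit
                rows.append({"easier": codes[e], "harder": codes[h], "group": int(g),
                             "diff": diff, "z": z, "significant": bool(sig)})
                if sig:
                    counts[codes[e]] += 1
                    counts[codes[h]] += 1
    return counts, rows


def check_miio(
    matrix: BinaryResponseMatrix,
    minvi: float = 0.03,
    minsize: int = 50,
    alpha: float = 0.05,
) -> IioResult:
    """Manifest invariant item ordering with backward item selection.

    Items are ordered globally by descending popularity.  For each ordered pair
    and each rest-score group over the remaining items, a violation occurs when
    the harder item's pass proportion exceeds the easier item's by more than
    ``minvi``; significance uses the paired discordant-cell statistic
    z = (n01 - n10) / sqrt(n01 + n10), one-sided.  The item with the most
    significant violations is removed (ties -> lower Hi) and the sweep repeats
    until no significant violations remain.
    """
    values = matrix.values.copy()
    codes = list(matrix.item_codes)
    zcrit = norm.ppf(1 - alpha)
    removed: list[str] = []
    first_counts: dict[str, int] | None = None
    first_rows = None
    while len(codes) >= 2:
        counts, rows = _miio_round(values, codes, minsize, minvi, zcrit)
        if first_counts is None:
            first_counts, first_rows = counts, rows
        worst = max(counts.values())
        if worst == 0:
            break
        candidates = [c for c, v in counts.items() if v == worst]
        if len(candidates) > 1:
            _, Hi, _ = _h_coefficients(values)
            hi_map = dict(zip(codes, Hi))
            drop = min(candidates, key=lambda c: hi_map[c])
        else:
            drop = candidates[0]
        removed.append(drop)
        j = codes.index(drop)
        values = np.delete(values, j, axis=1)
        codes.pop(j)
    table = pd.DataFrame(first_rows or [],
                         columns=["easier", "harder", "group", "diff", "z", "significant"])
    return IioResult(
        pairwise=table, sig_counts=first_counts or {}, removed_items=removed,
        final_items=codes, minsize=minsize, minvi=minvi,
    )


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityResult:
    cronbach_alpha: float
    guttman_lambda2: float
    ms_rho: float
    lcrc: float  # NaN when the latent-class EM failed in every restart
    lcrc_n_classes: int


def _lca_fit(values: np.ndarray, n_classes: int, rng: np.random.Generator,
             n_restarts: int = 20, tol: float = 1e-8, max_iter: int = 1000):
    """Unrestricted latent class model for binary items, EM with restarts.

    Returns (weights, per-class pass probabilities, loglik) of the best
    restart, or None if no restart converged.
    """
    n, k = values.shape
    best = None
    x = values.astype(float)
    for _ in range(n_restarts):
        w = rng.dirichlet(np.full(n_classes, 5.0))
        pi = rng.uniform(0.2, 0.8, size=(n_classes, k))
        last_ll = -np.inf
        converged = False
        for _it in range(max_iter):
            logp = (
                np.log(w)[None, :]
                + x @ np.log(pi).T
                + (1 - x) @ np.log1p(-pi).T
            )
            mx = logp.max(axis=1, keepdims=True)
            lik = np.exp(logp - mx)
            denom = lik.sum(axis=1, keepdims=True)
            resp = lik / denom
            ll = float((np.log(denom).ravel() + mx.ravel()).sum())
            nc = resp.sum(axis=0)
            w = nc / n
            pi = np.clip((resp.T @ x) / nc[:, None], 1e-6, 1 - 1e-6)
            w = np.clip(w, 1e-9, None)
            w /= w.sum()
            if abs(ll - last_ll) < tol:
                converged = True
                break
            last_ll = ll
        if converged and (best is None or ll > best[2]):
            best = (w, pi, ll)
    return best


def cronbach_alpha_from_cov(cov: np.ndarray) -> float:
    """Cronbach's alpha from an item covariance matrix: k/(k-1)(1 - tr S / var X)."""
    k = cov.shape[0]
    var_x = cov.sum()
    return float(k / (k - 1) * (1 - np.trace(cov) / var_x))


def lambda2_from_cov(cov: np.ndarray) -> float:
    """Guttman's lambda2 from an item covariance matrix."""
    k = cov.shape[0]
    var_x = cov.sum()
    off = ~np.eye(k, dtype=bool)
    return float(
        (cov[off].sum() + np.sqrt(k / (k - 1) * (cov[off] ** 2).sum())) / var_x
    )


def reliability(
    matrix: BinaryResponseMatrix, lcrc_classes: int = 3, seed: int = 0
) -> ReliabilityResult:
    """Cronbach's alpha, Guttman's lambda2, Molenaar-Sijtsma rho, and LCRC.

    All four estimate the reliability of the total score.  MS rho replaces the
    unobservable diagonal of the joint pass-proportion matrix by interpolation
    between the nearest off-diagonal neighbours in popularity order; the LCRC
    replaces every joint term by its value under an unrestricted latent class
    model (default 3 classes) fitted by EM with 20 random restarts.
    """
    values = matrix.values
    n, k = values.shape
    if k < 3:
        raise ValidationError("reliability needs at least 3 items")
    p = values.mean(axis=0)
    joint = (values.T @ values) / n
    cov = joint - np.outer(p, p)  # population covariances; diagonal p(1-p)
    var_x = float(np.var(values.sum(axis=1)))
    off = ~np.eye(k, dtype=bool)
    alpha = cronbach_alpha_from_cov(cov)
    lam2 = lambda2_from_cov(cov)
    # MS rho: interpolate the diagonal of the popularity-ordered joint matrix
    order = np.lexsort((np.arange(k), -p))
    joint_ord = joint[np.ix_(order, order)]
    pii = np.empty(k)
    for pos in range(k):
        neighbors = []
        if pos > 0:
            neighbors.append(joint_ord[pos, pos - 1])
        if pos < k - 1:
            neighbors.append(joint_ord[pos, pos + 1])
        pii[order[pos]] = float(np.mean(neighbors))
    ms_num = cov[off].sum() + float((pii - p**2).sum())
    ms_rho = ms_num / var_x
    # LCRC: model-implied joint terms
    rng = np.random.default_rng(seed)
    fit = _lca_fit(values, lcrc_classes, rng)
    if fit is None:
        warnings.warn("latent class EM failed to converge in every restart; LCRC is NaN")
        lcrc = np.nan
    else:
        w, pi, _ = fit
        joint_lc = (pi.T * w) @ pi  # sum_c w_c pi_ic pi_jc, incl. diagonal pi_ic^2
        lc_num = (joint_lc[off] - np.outer(p, p)[off]).sum() + float(
            (np.diag(joint_lc) - p**2).sum()
        )
        lcrc = lc_num / var_x
    return ReliabilityResult(
        cronbach_alpha=float(alpha),
        guttman_lambda2=float(lam2),
        ms_rho=float(ms_rho),
        lcrc=float(lcrc),
        lcrc_n_classes=lcrc_classes,
    )
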