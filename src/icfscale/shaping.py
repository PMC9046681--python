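"""Data shaping: from raw qualifier codes to a clean binary matrix.

The shaping stage mirrors the first stage of Mokken scale construction for ICF
questionnaires: recode 8/9 to missing, drop persons with > 30% missing and
items with >= 5% missing, complete the rest by k-nearest-neighbour imputation
(k = 5), dichotomize (codes 0-1 = functioning = 1; 2-4 = disabled = 0), screen
person misfit by the number of Guttman errors G+ against an adjusted-boxplot
fence, and drop constant items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import nan_euclidean_distances
from statsmodels.stats.stattools import medcouple

from .matrices import (
    BinaryResponseMatrix,
    OrdinalResponseMatrix,
    PipelineError,
    ValidationError,
)


@dataclass
class ShapingConfig:
    """Thresholds for the shaping stage.

    ``item_missing_threshold`` removes an item when its missing proportion is
    *at least* the threshold; ``person_missing_threshold`` removes a person when
    the proportion is *strictly above* it (the conventions the screening rules
    state: ">= 5%" for items, "> 30%" for persons).
    """

    item_missing_threshold: float = 0.05
    person_missing_threshold: float = 0.30
    knn_k: int = 5
    functioning_codes: frozenset[int] = field(default_factory=lambda: frozenset({0, 1}))

    def __post_init__(self) -> None:
        for t in (self.item_missing_threshold, self.person_missing_threshold):
            if not 0 < t <= 1:
                raise ValidationError("missingness thresholds must lie in (0, 1]")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")


@dataclass
class GuttmanErrorReport:
    g_plus: np.ndarray  # per-person Guttman error counts
    upper_fence: float
    flagged_persons: list[str]
    person_ids: list[str]


@dataclass
class ShapingResult:
    """Full record of one shaping run, for the pipeline report."""

    binary: BinaryResponseMatrix
    removed_items_missing: list[str]
    removed_persons_missing: list[str]
    removed_persons_guttman: list[str]
    removed_items_degenerate: list[str]
    guttman_report: GuttmanErrorReport


def recode_missing(matrix: OrdinalResponseMatrix) -> OrdinalResponseMatrix:
    """Map the qualifier missing codes 8 and 9 to NaN; 0-4 pass through."""
    out = matrix.copy()
    out.values[(out.values == 8) | (out.values == 9)] = np.nan
    return out


def filter_by_missingness(
    matrix: OrdinalResponseMatrix, config: ShapingConfig | None = None
) -> tuple[OrdinalResponseMatrix, list[str], list[str]]:
    """Drop high-missingness persons, then high-missingness items.

    Persons with missing proportion > ``person_missing_threshold`` go first
    (they are excluded at recruitment); items with missing proportion >=
    ``item_missing_threshold`` are then removed, computed over the retained
    persons.  Removal lists preserve input order.
    """
    config = config or ShapingConfig()
    vals = matrix.values
    miss = np.isnan(vals)
    person_prop = miss.mean(axis=1)
    keep_p = person_prop <= config.person_missing_threshold
    removed_persons = [pid for pid, k in zip(matrix.person_ids, keep_p) if not k]
    vals = vals[keep_p]
    miss = miss[keep_p]
    if vals.shape[0] == 0:
        raise PipelineError("all persons removed by the missingness filter")
    item_prop = miss.mean(axis=0)
    keep_i = item_prop < config.item_missing_threshold
    removed_items = [code for code, k in zip(matrix.item_codes, keep_i) if not k]
    if not keep_i.any():
        raise PipelineError("all items removed by the missingness filter")
    out = OrdinalResponseMatrix(
        vals[:, keep_i],
        [pid for pid, k in zip(matrix.person_ids, keep_p) if k],
        [code for code, k in zip(matrix.item_codes, keep_i) if k],
    )
    return out, removed_items, removed_persons


def knn_impute(
    matrix: OrdinalResponseMatrix, config: ShapingConfig | None = None
) -> OrdinalResponseMatrix:
    """Fill missing cells from the k nearest persons (default k = 5).

    Distance is Euclidean over co-observed items, rescaled by the co-observed
    count (the ``nan_euclidean`` convention).  The imputed value is the median
    of the k nearest donors observed at that item, rounded to the nearest valid
    code with exact halves resolved toward the lower code.  Observed cells are
    never changed.
    """
    config = config or ShapingConfig()
    out = matrix.copy()
    vals = out.values
    miss_rows = np.unique(np.argwhere(np.isnan(vals))[:, 0])
    if miss_rows.size == 0:
        return out
    dist = nan_euclidean_distances(vals, vals)
    np.fill_diagonal(dist, np.inf)
    for p in miss_rows:
        for i in np.argwhere(np.isnan(vals[p])).ravel():
            donors = np.flatnonzero(~np.isnan(matrix.values[:, i]) & np.isfinite(dist[p]))
            if donors.size == 0:
                raise PipelineError(
                    f"person {out.person_ids[p]!r} has no imputation donors "
                    f"for item {out.item_codes[i]!r}"
                )
            order = donors[np.argsort(dist[p, donors], kind="stable")]
            nearest = order[: config.knn_k]
            m = float(np.median(matrix.values[nearest, i]))
            vals[p, i] = float(np.ceil(m - 0.5))  # round half toward the lower code
    return out


def binarize(
    matrix: OrdinalResponseMatrix, config: ShapingConfig | None = None
) -> BinaryResponseMatrix:
    """Dichotomize: functioning codes (default {0,1}) -> 1, others -> 0."""
    config = config or ShapingConfig()
    if np.isnan(matrix.values).any():
        raise ValidationError("binarize requires a complete matrix; impute first")
    values = np.isin(matrix.values, list(config.functioning_codes)).astype(int)
    return BinaryResponseMatrix(values, list(matrix.person_ids), list(matrix.item_codes))


def guttman_error_counts(values: np.ndarray) -> np.ndarray:
    """G+ per person: ordered item pairs with the easier item failed, harder passed.

    Items are ordered by descending sample popularity, ties broken by input
    column order (stable sort).
    """
    pop = values.mean(axis=0)
    order = np.argsort(-pop, kind="stable")
    x = values[:, order]
    zeros_before = np.cumsum(1 - x, axis=1) - (1 - x)  # zeros strictly left of j
    return (x * zeros_before).sum(axis=1)


def adjusted_fence(values: np.ndarray) -> float:
    """Upper fence of the Hubert-Vandervieren adjusted boxplot.

    Q3 + 1.5 * exp(3 * MC) * IQR when the medcouple MC >= 0, and
    Q3 + 1.5 * exp(4 * MC) * IQR when MC < 0.  A constant sample degenerates
    to Q3 (zero IQR).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValidationError("adjusted_fence needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return float(q3)
    mc = float(medcouple(values))
    scale = np.exp(3 * mc) if mc >= 0 else np.exp(4 * mc)
    return float(q3 + 1.5 * scale * iqr)


def guttman_errors(matrix: BinaryResponseMatrix) -> GuttmanErrorReport:
    """Per-person G+ with the adjusted-boxplot outlier fence."""
    g = guttman_error_counts(matrix.values)
    fence = adjusted_fence(g.astype(float))
    flagged = [pid for pid, v in zip(matrix.person_ids, g) if v > fence]
    return GuttmanErrorReport(
        g_plus=g, upper_fence=fence, flagged_persons=flagged, person_ids=list(matrix.person_ids)
    )


def drop_guttman_outliers(
    matrix: BinaryResponseMatrix, report: GuttmanErrorReport | None = None
) -> tuple[BinaryResponseMatrix, GuttmanErrorReport]:
    report = report or guttman_errors(matrix)
    if not report.flagged_persons:
        return matrix, report
    keep = [pid not in set(report.flagged_persons) for pid in matrix.person_ids]
    if sum(keep) < 2:
        raise PipelineError("Guttman-error screen removed almost all persons")
    out = BinaryResponseMatrix(
        matrix.values[np.asarray(keep)],
        [pid for pid, k in zip(matrix.person_ids, keep) if k],
        list(matrix.item_codes),
    )
    return out, report


def drop_degenerate_items(
    matrix: BinaryResponseMatrix,
) -> tuple[BinaryResponseMatrix, list[str]]:
    """Remove constant (all-0 or all-1) item columns: ceiling/floor control."""
    pop = matrix.values.mean(axis=0)
    keep = (pop > 0) & (pop < 1)
    removed = [c for c, k in zip(matrix.item_codes, keep) if not k]
    if not keep.any() or keep.sum() < 2:
        raise PipelineError("fewer than 2 non-constant items remain")
    if not removed:
        return matrix, []
    out = BinaryResponseMatrix(
        matrix.values[:, keep],
        list(matrix.person_ids),
        [c for c, k in zip(matrix.item_codes, keep) if k],
    )
    return out, removed


def shape(
    matrix: OrdinalResponseMatrix, config: ShapingConfig | None = None
) -> ShapingResult:
    """Run the full shaping stage in its fixed order.

    recode -> person filter -> item filter -> impute -> binarize -> G+ screen
    -> degenerate-item drop.
    """
    config = config or ShapingConfig()
    recoded = recode_missing(matrix)
    filtered, removed_items, removed_persons = filter_by_missingness(recoded, config)
    imputed = knn_impute(filtered, config)
    binary = binarize(imputed, config)
    binary, greport = drop_guttman_outliers(binary)
    binary, degenerate = drop_degenerate_items(binary)
    return ShapingResult(
        binary=binary,
        removed_items_missing=removed_items,
        removed_persons_missing=removed_persons,
        removed_persons_guttman=list(greport.flagged_persons),
        removed_items_degenerate=degenerate,
        guttman_report=greport,
    )
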