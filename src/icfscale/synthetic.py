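"""Synthetic response generators with known latent structure.

The raw patient questionnaires behind the published 45-item stroke functioning
scale are not publicly deposited, so every downstream stage is exercised on
simulated data whose generating process is known exactly.  Dichotomous data
follow a 2PL/Rasch item response function; ordinal 0-4 qualifier codes follow a
graded-response model whose dichotomization at the functioning cut reproduces a
2PL item, keeping the binarized pipeline well-specified.

Orientation: the latent trait theta is *functioning ability*.  High theta means
low impairment codes; dichotomizing codes {0,1} -> 1 ("functioning") gives
P(1 | theta) = logistic(a * (theta - thresholds[2])), increasing in theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .matrices import BinaryResponseMatrix, OrdinalResponseMatrix, ValidationError


@dataclass(frozen=True)
class ItemSpec:
    """Ground-truth parameters of one simulated item.

    Parameters
    ----------
    code:
        ICF-style item identifier, e.g. ``"b110"`` or ``"d450"``.
    difficulty:
        Item location in logits for dichotomous generation (symbol ``b``).
    discrimination:
        Common slope ``a > 0``; 1.0 gives a Rasch item.
    thresholds:
        Four strictly increasing logit cutpoints for 5-category ordinal
        generation.  ``thresholds[2]`` is the functioning/disabled cut
        recovered when codes {0, 1} are mapped to 1.
    """

    code: str
    difficulty: float
    discrimination: float = 1.0
    thresholds: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.discrimination > 0:
            raise ValidationError(f"item {self.code!r}: discrimination must be > 0")
        if self.thresholds is not None:
            t = tuple(float(x) for x in self.thresholds)
            if len(t) != 4:
                raise ValidationError(f"item {self.code!r}: need exactly 4 thresholds")
            if not all(t[i] < t[i + 1] for i in range(3)):
                raise ValidationError(
                    f"item {self.code!r}: thresholds must be strictly increasing"
                )
            object.__setattr__(self, "thresholds", t)


def default_thresholds(difficulty: float, spread: float = 1.0) -> tuple[float, ...]:
    """Evenly spaced ordinal cutpoints centred so thresholds[2] = difficulty."""
    return tuple(difficulty + spread * k for k in (-2.0, -1.0, 0.0, 1.0))


@dataclass
class SimulationConfig:
    """Cohort-level settings for a simulated questionnaire administration."""

    n_persons: int
    items: list[ItemSpec]
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    missing_rate_8: float = 0.0
    missing_rate_9: float = 0.0
    group_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValidationError("n_persons must be >= 1")
        if not self.items:
            raise ValidationError("item list must be non-empty")
        if self.ability_sd < 0:
            raise ValidationError("ability_sd must be >= 0")
        for r in (self.missing_rate_8, self.missing_rate_9):
            if not 0 <= r <= 1:
                raise ValidationError("missing rates must lie in [0, 1]")
        if self.missing_rate_8 + self.missing_rate_9 > 0.5:
            raise ValidationError("combined missing rate must not exceed 0.5")
        if not 0 <= self.group_fraction <= 1:
            raise ValidationError("group_fraction must lie in [0, 1]")


def _draw_thetas(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return config.ability_mean + config.ability_sd * rng.standard_normal(config.n_persons)


def simulate_dichotomous(
    config: SimulationConfig, thetas: np.ndarray | None = None
) -> BinaryResponseMatrix:
    """Simulate 0/1 responses from the 2PL IRF P(1|theta)=logistic(a(theta-b)).

    ``thetas`` overrides the latent draw (useful for fixing the ability of every
    person); otherwise abilities are N(ability_mean, ability_sd**2).
    """
    rng = np.random.default_rng(config.seed)
    theta = _draw_thetas(config, rng) if thetas is None else np.asarray(thetas, float)
    if theta.shape != (config.n_persons,):
        raise ValidationError("thetas must have length n_persons")
    b = np.array([it.difficulty for it in config.items])
    a = np.array([it.discrimination for it in config.items])
    prob = expit(a[None, :] * (theta[:, None] - b[None, :]))
    values = (rng.random(prob.shape) < prob).astype(int)
    return BinaryResponseMatrix(
        values, person_ids=None, item_codes=[it.code for it in config.items]
    )


def simulate_ordinal(
    config: SimulationConfig, thetas: np.ndarray | None = None
) -> OrdinalResponseMatrix:
    """Simulate 0-4 qualifier codes from a graded-response model, then inject 8/9.

    The functioning-graded variable G = 4 - Y follows the homogeneous graded
    response model P(G >= m | theta) = logistic(a (theta - thresholds[m-1])),
    m = 1..4, so the impairment code Y satisfies
    P(Y <= j | theta) = logistic(a (theta - thresholds[3-j])).  High-ability
    persons get low impairment codes; dichotomizing {0,1} -> 1 yields
    P(1 | theta) = logistic(a (theta - thresholds[2])).
    Missing codes 8 and 9 then overwrite cells independently at the configured
    rates.
    """
    for it in config.items:
        if it.thresholds is None:
            raise ValidationError(f"item {it.code!r} has no thresholds for ordinal generation")
    rng = np.random.default_rng(config.seed)
    theta = _draw_thetas(config, rng) if thetas is None else np.asarray(thetas, float)
    if theta.shape != (config.n_persons,):
        raise ValidationError("thetas must have length n_persons")
    n, k = config.n_persons, len(config.items)
    values = np.empty((n, k), dtype=float)
    for j, it in enumerate(config.items):
        tau = np.asarray(it.thresholds)
        # P(G >= m), m = 1..4; G = number of "functioning steps" cleared
        cum = expit(it.discrimination * (theta[:, None] - tau[None, :]))
        g = (rng.random((n, 1)) < cum).sum(axis=1)  # valid because cum is decreasing in m
        values[:, j] = 4 - g
    u = rng.random((n, k))
    r8, r9 = config.missing_rate_8, config.missing_rate_9
    values[u < r8] = 8
    values[(u >= r8) & (u < r8 + r9)] = 9
    return OrdinalResponseMatrix(
        values, person_ids=None, item_codes=[it.code for it in config.items]
    )


def make_group_labels(
    n_persons: int, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary labels with an expected minority fraction, as an integer vector."""
    return (rng.random(n_persons) < fraction).astype(int)


def make_study_like_fixture(
    seed: int,
    n_persons: int = 130,
    n_b_items: int = 59,
    n_d_items: int = 59,
    group_fraction: float = 0.28,
) -> tuple[OrdinalResponseMatrix, np.ndarray, list[ItemSpec]]:
    """A study-shaped cohort: 130 persons x 118 b/d-prefixed ordinal items.

    Mirrors the published study design (59 body-function and 59
    activity/participation items, 130 inpatients, gender-like minority group of
    ~28%).  Most items discriminate well (a = 1.5) and form one latent
    dimension; a 20% minority are weak (a = 0.5) so the item-selection stages
    have genuine screening work to do.  Per-item 8/9 missing rates are drawn
    from a right-skewed Beta so a realistic minority of items crosses the 5%
    missingness screen.

    Returns the ordinal matrix, the group-label vector, and the ground-truth
    item specs.
    """
    rng = np.random.default_rng(seed)
    codes = [f"b{i + 1:03d}" for i in range(n_b_items)] + [
        f"d{i + 1:03d}" for i in range(n_d_items)
    ]
    items = []
    for code in codes:
        difficulty = float(np.clip(rng.normal(-0.5, 1.2), -2.8, 2.8))
        discrimination = 1.5 if rng.random() > 0.2 else 0.5
        items.append(
            ItemSpec(
                code=code,
                difficulty=difficulty,
                discrimination=discrimination,
                thresholds=default_thresholds(difficulty),
            )
        )
    config = SimulationConfig(
        n_persons=n_persons,
        items=items,
        ability_mean=0.0,
        ability_sd=1.0,
        seed=int(rng.integers(2**31 - 1)),
    )
    ordinal = simulate_ordinal(config)
    # Per-item missingness: mostly tiny, occasionally above the 5% screen.
    item_rates = rng.beta(0.8, 19.0, size=len(items))
    u = rng.random(ordinal.values.shape)
    mask8 = u < item_rates[None, :] / 2
    mask9 = (u >= item_rates[None, :] / 2) & (u < item_rates[None, :])
    ordinal.values[mask8] = 8
    ordinal.values[mask9] = 9
    groups = make_group_labels(n_persons, group_fraction, rng)
    return ordinal, groups, items


def write_item_specs_csv(items: list[ItemSpec], path) -> None:
    """Persist ground-truth parameters for recovery checks."""
    import pandas as pd

    rows = []
    for it in items:
        row = {
            "code": it.code,
            "difficulty": it.difficulty,
            "discrimination": it.discrimination,
        }
        if it.thresholds is not None:
            for m, t in enumerate(it.thresholds, start=1):
                row[f"threshold_{m}"] = t
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
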