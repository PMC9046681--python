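"""End-to-end orchestration: shaping -> Mokken -> Rasch -> score conversion.

`run_pipeline` chains the three analysis stages on an ordinal qualifier matrix
and returns a :class:`PipelineReport` in which every input item is either
retained in the final scale or attributed to exactly one removal rule.  All
randomness flows from the single configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import mokken, rasch, shaping
from .matrices import BinaryResponseMatrix, OrdinalResponseMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the full pipeline, with the study-standard defaults."""

    shaping: shaping.ShapingConfig = field(default_factory=shaping.ShapingConfig)
    aisp_cut: float = 0.42
    ga_params: mokken.GaParams = field(default_factory=mokken.GaParams)
    run_aisp_scan: bool = False
    monotonicity_minsize: int = 50
    monotonicity_minvi: float = 0.03
    crit_serious: float = 40.0
    h_bootstrap: int = 1000
    lcrc_classes: int = 3
    gof_B: int = 199
    unidim_n_sim: int = 100
    item_fit_groups: int = 10
    alpha: float = 0.05
    domains_included: tuple[str, ...] = ("b", "d")
    seed: int = 0


@dataclass
class PipelineReport:
    """Stage-by-stage summary with conserved item accounting."""

    n_persons_in: int
    n_items_in: int
    removals: dict[str, list[str]]  # rule name -> item codes removed by it
    removed_persons: dict[str, list[str]]
    scalability_initial: mokken.ScalabilityResult | None
    aisp_result: mokken.AispResult | None
    aisp_scan: list[mokken.AispResult] | None
    local_independence: mokken.ConditionalAssociationResult | None
    monotonicity: mokken.MonotonicityResult | None
    iio: mokken.IioResult | None
    reliability: mokken.ReliabilityResult | None
    scalability_final: mokken.ScalabilityResult | None
    screening_log: rasch.ScreeningLog | None
    final_fit: rasch.RaschFit | None
    gof: rasch.GofResult | None
    unidim: rasch.UnidimResult | None
    conversion: rasch.ScoreConversionTable | None
    dif: rasch.DifResult | None
    abilities: np.ndarray | None
    final_items: list[str]
    status: str
    seed: int

    def accounting_conserved(self) -> bool:
        removed = sum(len(v) for v in self.removals.values())
        return removed + len(self.final_items) == self.n_items_in

    def summary_dict(self) -> dict:
        d = {
            "status": self.status,
            "seed": self.seed,
            "n_persons_in": self.n_persons_in,
            "n_items_in": self.n_items_in,
            "n_final_items": len(self.final_items),
            "final_items": self.final_items,
            "removals": self.removals,
            "removed_persons": self.removed_persons,
        }
        if self.scalability_initial is not None:
            d["H_initial"] = self.scalability_initial.H
            d["H_initial_se"] = self.scalability_initial.H_se
        if self.scalability_final is not None:
            d["H_final"] = self.scalability_final.H
        if self.reliability is not None:
            d["reliability"] = asdict(self.reliability)
        if self.final_fit is not None:
            d["log_likelihood"] = self.final_fit.log_likelihood
            d["aic"] = self.final_fit.aic
            d["constrained"] = self.final_fit.constrained
        if self.gof is not None:
            d["gof_p"] = self.gof.p
        if self.unidim is not None:
            d["unidim_p"] = self.unidim.p
        if self.conversion is not None:
            d["conversion_coefficients"] = list(self.conversion.coefficients)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def read_responses(path, domains_included=("b", "d")) -> OrdinalResponseMatrix:
    """Load a qualifier-code CSV, keeping only the configured code prefixes.

    The header row carries item codes; empty cells are missing.  Malformed
    cells and duplicate item codes raise with coordinates.
    """
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))[1:]  # drop the person-id column
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValidationError(f"duplicate item codes in header: {dupes}")
    frame = pd.read_csv(path, index_col=0)
    keep = [c for c in frame.columns.astype(str) if c.startswith(tuple(domains_included))]
    frame = frame[keep]
    values = frame.to_numpy(dtype=float)
    matrix = OrdinalResponseMatrix(values, list(frame.index.astype(str)), keep)
    return matrix


def load_published_conversion() -> rasch.ScoreConversionTable:
    """The published 46-row conversion chart of the 45-item stroke scale.

    Total score -> ability (logits) -> percent, as printed in the original
    calibration; used for look-up conversion and as a regression target for
    the quadratic score equation.
    """
    with resources.files("icfscale.data").joinpath("published_conversion_45.csv").open() as fh:
        frame = pd.read_csv(fh)
    return rasch.ScoreConversionTable.from_pairs(
        frame["total_score"], frame["theta"], frame["percent"]
    )


def convert_score(table: rasch.ScoreConversionTable, tts: int) -> tuple[float, int]:
    """Exact row lookup: total score -> (theta, percent)."""
    tts = int(tts)
    idx = np.flatnonzero(table.total_score == tts)
    if idx.size == 0:
        raise ValidationError(
            f"total score {tts} outside the table range "
            f"[{table.total_score.min()}, {table.total_score.max()}]"
        )
    i = int(idx[0])
    return float(table.theta[i]), int(table.percent[i])


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(
    matrix: OrdinalResponseMatrix,
    config: PipelineConfig | None = None,
    groups=None,
) -> PipelineReport:
    """Run shaping -> Mokken -> Rasch -> conversion on an ordinal matrix.

    ``groups`` (optional) is a per-person binary label vector aligned with the
    input persons; when given, Lord's DIF test runs on the final scale.
    """
    config = config or PipelineConfig()
    seeds = _spawn_seeds(config.seed, 6)
    report_kwargs = dict(
        n_persons_in=matrix.n_persons,
        n_items_in=matrix.n_items,
        removals={}, removed_persons={},
        scalability_initial=None, aisp_result=None, aisp_scan=None,
        local_independence=None, monotonicity=None, iio=None,
        reliability=None, scalability_final=None, screening_log=None,
        final_fit=None, gof=None, unidim=None, conversion=None, dif=None,
        abilities=None, final_items=[], status="incomplete", seed=config.seed,
    )
    removals: dict[str, list[str]] = report_kwargs["removals"]
    removed_persons: dict[str, list[str]] = report_kwargs["removed_persons"]

    # ---- Stage: shaping -------------------------------------------------
    shaped = shaping.shape(matrix, config.shaping)
    removals["missingness"] = shaped.removed_items_missing
    removals["degenerate"] = shaped.removed_items_degenerate
    removed_persons["missingness"] = shaped.removed_persons_missing
    removed_persons["guttman"] = shaped.removed_persons_guttman
    binary = shaped.binary
    logger.info(
        "shaping: %d x %d -> %d x %d (items: %d missingness, %d degenerate; "
        "persons: %d missingness, %d Guttman outliers)",
        matrix.n_persons, matrix.n_items, binary.n_persons, binary.n_items,
        len(shaped.removed_items_missing), len(shaped.removed_items_degenerate),
        len(shaped.removed_persons_missing), len(shaped.removed_persons_guttman),
    )
    if groups is not None:
        groups = np.asarray(groups)
        keep = [pid in set(binary.person_ids) for pid in matrix.person_ids]
        groups = groups[np.asarray(keep)]

    # ---- Stage: Mokken --------------------------------------------------
    scal = mokken.scalability(binary, n_boot=config.h_bootstrap, seed=seeds[0])
    report_kwargs["scalability_initial"] = scal
    if config.run_aisp_scan:
        report_kwargs["aisp_scan"] = mokken.aisp_scan(
            binary, ga_params=config.ga_params, seed=seeds[1]
        )
    logger.info("mokken: H = %.4f (se %.4f) over %d items", scal.H, scal.H_se, binary.n_items)
    aisp_res = mokken.aisp(binary, config.aisp_cut, config.ga_params, seed=seeds[1])
    report_kwargs["aisp_result"] = aisp_res
    logger.info("aisp (c = %.2f): scale 1 holds %d of %d items",
                config.aisp_cut, aisp_res.n_in_scale(1), binary.n_items)
    removals["aisp_unscalable"] = [
        c for c, s in aisp_res.assignment.items() if s != 1
    ]
    if not aisp_res.scales:
        report_kwargs["status"] = "no scalable items"
        report_kwargs["final_items"] = []
        return PipelineReport(**report_kwargs)
    scale_items = aisp_res.scales[0]
    current = binary.select_items(scale_items)

    li = mokken.check_conditional_association(current)
    report_kwargs["local_independence"] = li
    removals["local_independence"] = list(li.flagged_items)
    if li.flagged_items:
        keep = [c for c in current.item_codes if c not in set(li.flagged_items)]
        current = current.select_items(keep)

    mono = mokken.check_monotonicity(
        current, minsize=config.monotonicity_minsize,
        minvi=config.monotonicity_minvi, alpha=config.alpha,
    )
    report_kwargs["monotonicity"] = mono
    mono_bad = [r.code for r in mono.items
                if r.significant > 0 and r.crit > config.crit_serious]
    removals["monotonicity"] = mono_bad
    if mono_bad:
        current = current.select_items(
            [c for c in current.item_codes if c not in set(mono_bad)]
        )

    iio = mokken.check_miio(
        current, minvi=config.monotonicity_minvi,
        minsize=config.monotonicity_minsize, alpha=config.alpha,
    )
    report_kwargs["iio"] = iio
    removals["iio"] = list(iio.removed_items)
    current = current.select_items(iio.final_items)

    report_kwargs["reliability"] = mokken.reliability(
        current, lcrc_classes=config.lcrc_classes, seed=seeds[2]
    )
    report_kwargs["scalability_final"] = mokken.scalability(
        current, n_boot=config.h_bootstrap, seed=seeds[0]
    )

    # ---- Stage: Rasch ---------------------------------------------------
    final_codes, log, fit = rasch.screening_circle(
        current, alpha=config.alpha, n_groups=config.item_fit_groups
    )
    report_kwargs["screening_log"] = log
    removals["rasch_screening"] = log.all_removed
    logger.info("rasch screening: %d iteration(s), removed %d item(s); final %d items",
                log.n_iterations, len(log.all_removed), len(final_codes))
    current = current.select_items(final_codes)
    report_kwargs["final_fit"] = fit
    report_kwargs["gof"] = rasch.bootstrap_gof(fit, current, B=config.gof_B, seed=seeds[3])
    report_kwargs["unidim"] = rasch.unidim_test(
        fit, current, n_sim=config.unidim_n_sim, seed=seeds[4]
    )
    report_kwargs["abilities"] = rasch.eap_abilities(fit, current)
    report_kwargs["conversion"] = rasch.score_conversion_table(fit)
    if groups is not None and np.unique(groups).size == 2:
        report_kwargs["dif"] = rasch.dif_lord(current, groups, alpha=config.alpha)
    report_kwargs["final_items"] = list(current.item_codes)
    report_kwargs["status"] = "complete"
    return PipelineReport(**report_kwargs)
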