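"""End-to-end segmentation of one image and the cross-validation harness.

The default stage order is: linear contrast stretch (percentile window) →
optional Gaussian smoothing → maximum-entropy threshold search by the
shrinkage-factor PSO → binarization at the found threshold (the largest
threshold when k > 1, selecting the brightest class as the target) →
connected-component labeling → area filtering.  Every stage can be toggled
and parameterized independently, and every run is a pure function of
(image, config, seed).

"2-fold (50/50) cross-validation" of pipeline stability:
:func:`run_cross_validation` shuffles labeled cases into folds, tunes the
cheap preprocessing knobs (stretch percentiles, minimum region area) on
each training split over a small grid by mean Jaccard, applies the winner
to the held-out fold, and aggregates per-case Jaccard overall and per
invasion grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np

from . import entropy, evaluation, preprocess, pso

__all__ = [
    "DegenerateInputError",
    "PipelineConfig",
    "SegmentationResult",
    "LabeledCase",
    "CVReport",
    "DEFAULT_TUNING_GRID",
    "segment_image",
    "run_cross_validation",
]


class DegenerateInputError(ValueError):
    """The image cannot be segmented (e.g. constant intensity)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Stage toggles and parameters for the whole segmentation chain.

    ``n_thresholds`` defaults to 2 so the target (brightest) tissue class
    is separated from both the dark background and the intermediate
    myometrial band; set it to 1 for plain foreground/background images.
    """

    stretch_enabled: bool = True
    stretch_mode: str = "percentile"  # "percentile" or "fixed"
    stretch_low: float = 1.0   # percentile, or intensity when mode == "fixed"
    stretch_high: float = 99.0
    smooth_enabled: bool = False
    smooth_sigma: float = 1.0
    n_thresholds: int = 2
    area_filter_enabled: bool = True
    min_area: int = 64
    max_area: int | None = None
    connectivity: int = 8
    pso: pso.PSOConfig = field(default_factory=pso.PSOConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stretch_mode not in ("percentile", "fixed"):
            raise ValueError(f"stretch_mode must be 'percentile' or 'fixed', got {self.stretch_mode!r}")
        if self.n_thresholds < 1:
            raise ValueError("n_thresholds must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.max_area is not None and self.max_area < self.min_area:
            raise ValueError("max_area must be >= min_area")
        if self.smooth_sigma <= 0:
            raise ValueError("smooth_sigma must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass(frozen=True)
class SegmentationResult:
    """Final mask plus full provenance of how it was produced."""

    mask: np.ndarray
    thresholds: entropy.ThresholdSet
    objective_value: float
    optimizer_trace: pso.OptimizationResult
    stage_log: tuple[dict, ...]


@dataclass(frozen=True)
class LabeledCase:
    """An image paired with its reference mask and grade label."""

    image: np.ndarray
    reference_mask: np.ndarray
    case_id: str
    grade: str = "none"

    def __post_init__(self) -> None:
        if self.image.shape != self.reference_mask.shape:
            raise ValueError(
                f"case {self.case_id}: image {self.image.shape} and mask "
                f"{self.reference_mask.shape} geometry differ"
            )

    @classmethod
    def from_phantom(cls, case) -> "LabeledCase":
        return cls(
            image=case.image,
            reference_mask=case.truth_mask,
            case_id=case.case_id,
            grade=case.grade,
        )


#: Preprocessing knobs tried per training split during cross-validation.
DEFAULT_TUNING_GRID: tuple[dict, ...] = (
    {"stretch_low": 1.0, "stretch_high": 99.0, "min_area": 32},
    {"stretch_low": 1.0, "stretch_high": 99.0, "min_area": 64},
    {"stretch_low": 2.0, "stretch_high": 98.0, "min_area": 32},
    {"stretch_low": 2.0, "stretch_high": 98.0, "min_area": 64},
)


def segment_image(image: np.ndarray, config: PipelineConfig | None = None) -> SegmentationResult:
    """Segment one gray-scale image with the configured stage chain.

    The binarization threshold is the PSO-found maximum-entropy threshold
    (the largest one when several are searched).  Deterministic given the
    config seed.
    """
    if config is None:
        config = PipelineConfig()
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise DegenerateInputError("input must be a nonempty 2-D gray-scale image")
    stage_log: list[dict] = []
    work = image

    if config.stretch_enabled:
        if config.stretch_mode == "percentile":
            try:
                in_low, in_high = preprocess.percentile_window(
                    work, config.stretch_low, config.stretch_high
                )
            except ValueError as exc:
                raise DegenerateInputError(f"contrast stretch failed: {exc}") from exc
        else:
            in_low, in_high = int(config.stretch_low), int(config.stretch_high)
        work = preprocess.linear_stretch(work, in_low, in_high)
        stage_log.append(
            {"stage": "linear_stretch", "in_low": in_low, "in_high": in_high,
             "mode": config.stretch_mode}
        )

    if config.smooth_enabled:
        work = preprocess.gaussian_smooth(work, config.smooth_sigma)
        stage_log.append({"stage": "gaussian_smooth", "sigma": config.smooth_sigma})

    hist = entropy.compute_histogram(work, n_bins=256)
    pso_config = replace(config.pso, seed=config.seed)
    try:
        thresholds, score, trace = entropy.pso_threshold_search(
            hist, k=config.n_thresholds, config=pso_config
        )
    except entropy.DegenerateHistogramError as exc:
        raise DegenerateInputError(f"degenerate input: {exc}") from exc
    stage_log.append(
        {"stage": "entropy_threshold", "k": config.n_thresholds,
         "thresholds": list(thresholds.thresholds), "objective": score,
         "iterations": trace.iterations_run}
    )

    target_threshold = thresholds.thresholds[-1]
    mask = preprocess.binarize(work, target_threshold)
    stage_log.append({"stage": "binarize", "threshold": int(target_threshold)})

    labeling = preprocess.label_connected(mask, connectivity=config.connectivity)
    stage_log.append({"stage": "label_connected", "connectivity": config.connectivity,
                      "n_regions": labeling.n_regions})
    if config.area_filter_enabled:
        mask = preprocess.area_filter(labeling, config.min_area, config.max_area)
        stage_log.append({"stage": "area_filter", "min_area": config.min_area,
                          "max_area": config.max_area})

    return SegmentationResult(
        mask=mask,
        thresholds=thresholds,
        objective_value=score,
        optimizer_trace=trace,
        stage_log=tuple(stage_log),
    )


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome: fold structure and Jaccard summaries."""

    fold_assignments: tuple[tuple[tuple[str, ...], ...], ...]  # [repeat][fold] -> case ids
    per_fold_mean: tuple[tuple[float, ...], ...]
    per_fold_median: tuple[tuple[float, ...], ...]
    overall_mean: float
    per_grade_mean: dict[str, float]
    per_case_jaccard: dict[str, tuple[float, ...]]  # case id -> one value per repeat
    chosen_params: tuple[tuple[dict, ...], ...]  # [repeat][fold] -> winning overrides
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "fold_assignments": [[list(fold) for fold in rep] for rep in self.fold_assignments],
            "per_fold_mean": [list(rep) for rep in self.per_fold_mean],
            "per_fold_median": [list(rep) for rep in self.per_fold_median],
            "overall_mean": self.overall_mean,
            "per_grade_mean": dict(self.per_grade_mean),
            "per_case_jaccard": {k: list(v) for k, v in self.per_case_jaccard.items()},
            "chosen_params": [list(rep) for rep in self.chosen_params],
            "config": self.config,
            "seed": self.seed,
        }


def _mean_jaccard(cases: Sequence[LabeledCase], config: PipelineConfig) -> float:
    scores = []
    for case in cases:
        result = segment_image(case.image, config)
        scores.append(evaluation.jaccard_index(result.mask, case.reference_mask))
    return float(np.mean(scores))


def run_cross_validation(
    cases: Sequence[LabeledCase],
    folds: int = 2,
    repeats: int = 5,
    config: PipelineConfig | None = None,
    tuning_grid: Sequence[dict] = DEFAULT_TUNING_GRID,
) -> CVReport:
    """Repeated k-fold cross-validation of segmentation stability.

    Per repeat, cases are shuffled (seeded) into ``folds`` folds of sizes
    differing by at most one.  For each held-out fold the preprocessing
    knobs in ``tuning_grid`` are selected on the remaining training cases
    by mean Jaccard (ties to the first grid entry) and then applied to the
    held-out cases.  Every case is tested exactly once per repeat.
    """
    if config is None:
        config = PipelineConfig()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(cases) < folds:
        raise ValueError(f"need at least {folds} cases, got {len(cases)}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not tuning_grid:
        raise ValueError("tuning_grid must contain at least one candidate")

    rng = np.random.default_rng(config.seed)
    n = len(cases)
    all_assignments: list[tuple[tuple[str, ...], ...]] = []
    all_fold_means: list[tuple[float, ...]] = []
    all_fold_medians: list[tuple[float, ...]] = []
    all_chosen: list[tuple[dict, ...]] = []
    per_case: dict[str, list[float]] = {c.case_id: [] for c in cases}
    per_grade: dict[str, list[float]] = {}

    for _ in range(repeats):
        order = rng.permutation(n)
        fold_indices = [order[f::folds] for f in range(folds)]
        rep_assignment, rep_means, rep_medians, rep_chosen = [], [], [], []
        for f in range(folds):
            test = [cases[i] for i in fold_indices[f]]
            train = [cases[i] for g in range(folds) if g != f for i in fold_indices[g]]
            best_override, best_score = None, -np.inf
            for override in tuning_grid:
                candidate = replace(config, **override)
                score = _mean_jaccard(train, candidate)
                if score > best_score:
                    best_override, best_score = override, score
            tuned = replace(config, **best_override)
            fold_scores = []
            for case in test:
                result = segment_image(case.image, tuned)
                j = evaluation.jaccard_index(result.mask, case.reference_mask)
                fold_scores.append(j)
                per_case[case.case_id].append(j)
                per_grade.setdefault(case.grade, []).append(j)
            rep_assignment.append(tuple(c.case_id for c in test))
            rep_means.append(float(np.mean(fold_scores)))
            rep_medians.append(float(np.median(fold_scores)))
            rep_chosen.append(dict(best_override))
        all_assignments.append(tuple(rep_assignment))
        all_fold_means.append(tuple(rep_means))
        all_fold_medians.append(tuple(rep_medians))
        all_chosen.append(tuple(rep_chosen))

    all_scores = [s for scores in per_case.values() for s in scores]
    return CVReport(
        fold_assignments=tuple(all_assignments),
        per_fold_mean=tuple(all_fold_means),
        per_fold_median=tuple(all_fold_medians),
        overall_mean=float(np.mean(all_scores)),
        per_grade_mean={g: float(np.mean(v)) for g, v in per_grade.items()},
        per_case_jaccard={k: tuple(v) for k, v in per_case.items()},
        chosen_params=tuple(all_chosen),
        config=config.to_dict(),
        seed=config.seed,
    )
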