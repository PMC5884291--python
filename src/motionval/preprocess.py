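"""Three-stage trajectory cleaning for skeleton joint traces.

Depth-sensor skeleton tracking produces occasional gross per-frame failures
(the joint is inferred, not seen) on top of millimetre-scale Gaussian noise.
The pipeline cleans each coordinate trace of each joint independently, in a
fixed stage order:

1. :func:`remove_outliers` -- a sliding three-sample test: a sample is
   flagged when it falls outside ``mean ± 1.96 sigma`` of a local window and
   is replaced by the mean of its two neighbours,
2. :func:`interpolate_blocks` -- consecutive groups of 10 samples are
   replaced by the straight line joining each group's first and last value,
3. :func:`moving_average` -- a centred moving-average filter that smooths
   without phase shift.

Where the window statistics for stage 1 are taken from is a genuine design
choice with large consequences: with mean and population sigma computed over
the three-sample window *including* the candidate, the standardised
deviation of the candidate can never exceed sqrt(2) < 1.96, so that literal
rule flags nothing, ever.  The default policy therefore takes mean and sigma
over the two neighbours only, which detects isolated spikes and is the
reading consistent with replacement "by the neighbours' mean".  The literal
three-point rule and a whole-series rule remain selectable for transparency
(see :class:`OutlierPolicy`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .skeleton import SkeletonSequence

__all__ = [
    "ScalarSeries",
    "OutlierPolicy",
    "OutlierWindow",
    "SmoothingConfig",
    "SeriesTooShortError",
    "remove_outliers",
    "interpolate_blocks",
    "moving_average",
    "preprocess_sequence",
    "PipelineResult",
    "SIGMA_SOURCES",
]

logger = logging.getLogger(__name__)

SIGMA_SOURCES = ("neighbors-only", "literal-3-point", "global-series")

Z_LIMIT = 1.96  # two-sided 95% Gaussian bound used by every stage-1 policy


class SeriesTooShortError(ValueError):
    """Outlier removal needs at least three samples."""


@dataclass
class ScalarSeries:
    """One coordinate (or angle) trace; ``unit`` is 'm' or 'deg'."""

    values: np.ndarray
    unit: str = "m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class OutlierPolicy:
    """How the stage-1 window statistics are computed.

    sigma_source
        ``"neighbors-only"`` (default): mean and population sigma over the
        two neighbours ``(x[i-1], x[i+1])``.
        ``"literal-3-point"``: mean and population sigma over the full
        three-sample window -- provably inert (see module docstring).
        ``"global-series"``: mean and population sigma over the whole series.
    replacement
        Always the neighbours' mean; recorded for provenance.
    """

    sigma_source: str = "neighbors-only"
    replacement: str = "neighbor-mean"

    def __post_init__(self) -> None:
        if self.sigma_source not in SIGMA_SOURCES:
            raise ValueError(
                f"sigma_source must be one of {SIGMA_SOURCES}, got {self.sigma_source!r}"
            )
        if self.replacement != "neighbor-mean":
            raise ValueError("only 'neighbor-mean' replacement is defined")


@dataclass(frozen=True)
class OutlierWindow:
    """Record of one flagged-and-replaced sample."""

    center_index: int
    mean: float
    sigma: float
    lower: float
    upper: float
    flagged: bool = True


@dataclass(frozen=True)
class SmoothingConfig:
    """Centred moving-average window of ``window_n`` samples (odd).

    ``edge_policy='shrink'`` clips the window at the series bounds so the
    output keeps the input length; a constant series passes unchanged.
    """

    window_n: int = 5
    mode: str = "centered"
    edge_policy: str = "shrink"

    def __post_init__(self) -> None:
        if not isinstance(self.window_n, (int, np.integer)) or self.window_n < 1:
            raise ValueError(f"window_n must be a positive integer, got {self.window_n!r}")
        if self.window_n % 2 == 0:
            raise ValueError(f"window_n must be odd, got {self.window_n}")
        if self.mode != "centered" or self.edge_policy != "shrink":
            raise ValueError("only centered mode with shrink edge policy is defined")


def _values(series) -> np.ndarray:
    if isinstance(series, ScalarSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def _wrap(series, values: np.ndarray):
    if isinstance(series, ScalarSeries):
        return replace(series, values=values)
    return values


# ---------------------------------------------------------------------------
# stage 1: outlier replacement


def _outlier_pass(x: np.ndarray, sigma_source: str):
    """One vectorised sweep over interior samples.

    Thresholds and replacements are all computed from the *input* series
    (simultaneous update), so the result does not depend on scan direction.
    Returns (cleaned, flag mask over interior, mean, sigma, lower, upper).
    """
    prev, cur, nxt = x[:-2], x[1:-1], x[2:]
    nb_mean = 0.5 * (prev + nxt)
    if sigma_source == "neighbors-only":
        mean = nb_mean
        sigma = 0.5 * np.abs(nxt - prev)  # population sd of two values
    elif sigma_source == "literal-3-point":
        mean = (prev + cur + nxt) / 3.0
        sigma = np.sqrt(
            ((prev - mean) ** 2 + (cur - mean) ** 2 + (nxt - mean) ** 2) / 3.0
        )
    elif sigma_source == "global-series":
        mean = np.full_like(cur, x.mean())
        sigma = np.full_like(cur, x.std())  # population
    else:  # pragma: no cover - guarded by OutlierPolicy
        raise ValueError(sigma_source)
    lower = mean - Z_LIMIT * sigma
    upper = mean + Z_LIMIT * sigma
    flagged = (cur < lower) | (cur > upper)
    out = x.copy()
    out[1:-1] = np.where(flagged, nb_mean, cur)
    return out, flagged, mean, sigma, lower, upper


def remove_outliers(series, policy: "OutlierPolicy | None" = None):
    """Replace spike samples by their neighbours' mean.

    Interior samples falling outside ``mean ± 1.96 sigma`` of the policy's
    window are replaced; the first and last samples lack two neighbours and
    are never touched.  Returns ``(cleaned_series, windows)`` where
    ``windows`` holds one :class:`OutlierWindow` per replaced sample.
    """
    policy = policy or OutlierPolicy()
    x = _values(series)
    if x.ndim != 1:
        raise ValueError("remove_outliers expects a 1-D series")
    if x.size < 3:
        raise SeriesTooShortError(
            f"series too short for outlier removal: need >= 3 samples, got {x.size}"
        )
    out, flagged, mean, sigma, lower, upper = _outlier_pass(x, policy.sigma_source)
    idx = np.flatnonzero(flagged)
    windows = [
        OutlierWindow(
            center_index=int(i) + 1,
            mean=float(mean[i]),
            sigma=float(sigma[i]),
            lower=float(lower[i]),
            upper=float(upper[i]),
        )
        for i in idx
    ]
    return _wrap(series, out), windows


# ---------------------------------------------------------------------------
# stage 2: block linear interpolation

BLOCK_SIZE = 10


def interpolate_blocks(series, block_size: int = BLOCK_SIZE):
    """Linear interpolation within consecutive non-overlapping blocks.

    Within each full block the interior samples are replaced by the straight
    line joining the block's first and last values, evaluated at their
    positions; a trailing partial block has no endpoint pair and passes
    through unchanged.  Idempotent: a line through two points is its own
    interpolant.
    """
    if block_size < 2:
        raise ValueError(f"block_size must be >= 2, got {block_size}")
    x = _values(series)
    out = x.copy()
    n_full = (x.size // block_size) * block_size
    if n_full:
        blocks = x[:n_full].reshape(-1, block_size)
        w = np.linspace(0.0, 1.0, block_size)
        out[:n_full] = ((1.0 - w) * blocks[:, :1] + w * blocks[:, -1:]).ravel()
    return _wrap(series, out)


# ---------------------------------------------------------------------------
# stage 3: moving-average filter


def moving_average(series, cfg: "SmoothingConfig | int | None" = None):
    """Centred moving average of up to ``window_n`` samples.

    Each output sample is the mean of the centred window clipped at the
    series bounds, so length is preserved and no phase shift is introduced.
    """
    if cfg is None:
        cfg = SmoothingConfig()
    elif isinstance(cfg, (int, np.integer)):
        cfg = SmoothingConfig(window_n=int(cfg))
    x = _values(series)
    half = cfg.window_n // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(x.size)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, x.size)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return _wrap(series, out)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    """Stage-by-stage output of :func:`preprocess_sequence`.

    ``stages`` keeps the intermediate sequences under the keys ``"raw"``,
    ``"deoutliered"``, ``"interpolated"``, ``"smoothed"`` so original and
    smoothed curves can be plotted side by side; ``flag_counts`` maps each
    joint label to the number of samples replaced in stage 1 (summed over
    x, y, z).
    """

    sequence: SkeletonSequence
    stages: Mapping[str, SkeletonSequence]
    flag_counts: Mapping[str, int]
    policy: OutlierPolicy = field(default_factory=OutlierPolicy)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)


def preprocess_sequence(
    seq: SkeletonSequence,
    policy: "OutlierPolicy | None" = None,
    cfg: "SmoothingConfig | None" = None,
    return_stages: bool = False,
):
    """Clean every joint's x, y, z traces through the three-stage pipeline.

    Stage order is fixed: outlier replacement, block interpolation, moving
    average.  Timestamps, frame count and joint set are preserved.  Returns
    the cleaned :class:`~motionval.skeleton.SkeletonSequence`, or a
    :class:`PipelineResult` with all intermediates when ``return_stages``.
    """
    policy = policy or OutlierPolicy()
    cfg = cfg or SmoothingConfig()
    if seq.n_frames < 3:
        raise SeriesTooShortError(
            f"sequence too short to preprocess: need >= 3 frames, got {seq.n_frames}"
        )
    stage1: dict[str, np.ndarray] = {}
    stage2: dict[str, np.ndarray] = {}
    stage3: dict[str, np.ndarray] = {}
    flag_counts: dict[str, int] = {}
    for joint, arr in seq.positions.items():
        cols1 = np.empty_like(arr)
        n_flagged = 0
        for c in range(3):
            cleaned, flagged, *_ = _outlier_pass(arr[:, c], policy.sigma_source)
            cols1[:, c] = cleaned
            n_flagged += int(flagged.sum())
        flag_counts[joint] = n_flagged
        cols2 = np.column_stack(
            [interpolate_blocks(cols1[:, c]) for c in range(3)]
        )
        cols3 = np.column_stack([moving_average(cols2[:, c], cfg) for c in range(3)])
        stage1[joint] = cols1
        stage2[joint] = cols2
        stage3[joint] = cols3
    total = sum(flag_counts.values())
    logger.debug(
        "preprocess: %d frames, %d joints, %d samples replaced (policy=%s, window=%d)",
        seq.n_frames,
        len(seq.positions),
        total,
        policy.sigma_source,
        cfg.window_n,
    )
    final = seq.with_positions(stage3)
    if not return_stages:
        return final
    return PipelineResult(
        sequence=final,
        stages={
            "raw": seq,
            "deoutliered": seq.with_positions(stage1),
            "interpolated": seq.with_positions(stage2),
            "smoothed": final,
        },
        flag_counts=flag_counts,
        policy=policy,
        smoothing=cfg,
    )
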