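"""Initiation-level quantification, orientation index, and depth matching.

The orientation index (OI) of an element is the maximal strand signal in a
window around its center divided by the total signal from both strands:
OI = max(plus, minus) / (plus + minus), ranging from 0.5 (perfectly
bidirectional) to 1 (perfectly unidirectional). Cross-dataset depth
matching thins counts binomially so that median promoter-window counts
agree between datasets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Element, SignalTrack, ValidationError

log = logging.getLogger(__name__)

DIRECTION_CLASSES = ("bidirectional", "asymmetric", "unidirectional", "undefined")


@dataclass(frozen=True)
class DirectionalityThresholds:
    """OI cutoffs and the minimum read filter for calling directionality.

    Defaults: OI <= 0.6 bidirectional, OI >= 0.8 unidirectional, in
    between asymmetric; elements with total reads <= min_reads (strict
    "more than 30 reads" filter) are undefined.
    """

    bidirectional_max: float = 0.6
    unidirectional_min: float = 0.8
    min_reads: int = 30

    def __post_init__(self) -> None:
        if not (0.5 <= self.bidirectional_max < self.unidirectional_min <= 1.0):
            raise ValidationError(
                "need 0.5 <= bidirectional_max < unidirectional_min <= 1"
            )


@dataclass
class OrientationResult:
    plus_count: int
    minus_count: int
    oi: float | None
    sense_strand: str
    direction_class: str | None = None

    @property
    def total(self) -> int:
        return self.plus_count + self.minus_count


def count_window(
    track: SignalTrack, chrom: str, center: int, halfwidth: int, strand: str
) -> int:
    """Sum of 5'-end counts on one strand in [center - hw, center + hw).

    The window is clipped to chromosome bounds; a center outside the
    chromosome is an error.
    """
    if halfwidth <= 0:
        raise ValidationError(f"halfwidth must be > 0, got {halfwidth}")
    length = track.chrom_lengths.get(chrom)
    if center < 0 or (length is not None and center >= length):
        raise ValidationError(f"center {center} outside chromosome {chrom}")
    start = max(0, center - halfwidth)
    end = center + halfwidth
    if length is not None:
        end = min(end, length)
    return track.window_sum(chrom, strand, start, end)


def orientation_index(plus: int, minus: int) -> OrientationResult:
    """OI = max(plus, minus) / (plus + minus); undefined at zero total.

    A tie resolves to sense '+' with OI exactly 0.5.
    """
    if plus < 0 or minus < 0:
        raise ValidationError(f"negative counts ({plus}, {minus})")
    total = plus + minus
    if total == 0:
        return OrientationResult(plus, minus, None, "+")
    oi = max(plus, minus) / total
    sense = "+" if plus >= minus else "-"
    return OrientationResult(int(plus), int(minus), oi, sense)


def classify_directionality(
    oi: float | None,
    total: int,
    thr: DirectionalityThresholds | None = None,
) -> str:
    thr = thr or DirectionalityThresholds()
    if oi is None or total <= thr.min_reads:
        return "undefined"
    if not (0.5 - 1e-12 <= oi <= 1.0 + 1e-12):
        raise ValidationError(f"OI {oi} outside [0.5, 1]")
    if oi <= thr.bidirectional_max:
        return "bidirectional"
    if oi >= thr.unidirectional_min:
        return "unidirectional"
    return "asymmetric"


def score_elements(
    elements: list[Element],
    track: SignalTrack,
    halfwidth: int = 250,
    thresholds: DirectionalityThresholds | None = None,
) -> pd.DataFrame:
    """Per-element strand counts, OI and directionality class.

    The window is summit +/- halfwidth (half-open on the right), the
    500-base view around the element center at the default halfwidth.
    """
    thresholds = thresholds or DirectionalityThresholds()
    rows = []
    for e in elements:
        plus = count_window(track, e.chrom, e.summit, halfwidth, "+")
        minus = count_window(track, e.chrom, e.summit, halfwidth, "-")
        res = orientation_index(plus, minus)
        res.direction_class = classify_directionality(res.oi, res.total, thresholds)
        rows.append(
            {
                "id": e.id,
                "chrom": e.chrom,
                "summit": e.summit,
                "plus": plus,
                "minus": minus,
                "total": res.total,
                "oi": np.nan if res.oi is None else res.oi,
                "sense_strand": res.sense_strand,
                "direction_class": res.direction_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "summit", "plus", "minus", "total", "oi",
                 "sense_strand", "direction_class"],
    )


def promoter_window_counts(
    track: SignalTrack, promoters: list[Element], halfwidth: int
) -> np.ndarray:
    """Both-strand window counts at promoter elements (summit-centered)."""
    return np.array(
        [
            count_window(track, p.chrom, p.summit, halfwidth, "+")
            + count_window(track, p.chrom, p.summit, halfwidth, "-")
            for p in promoters
        ],
        dtype=np.int64,
    )


@dataclass
class SubsampleReport:
    retention_p: float
    target_median: float
    achieved_median: float
    original_median: float
    n_promoters: int


def subsample_to_matched_median(
    track: SignalTrack,
    promoters: list[Element],
    target_median: float,
    halfwidth: int = 250,
    seed: int = 0,
    median_rtol: float = 0.05,
    p_tol: float = 1e-4,
) -> tuple[SignalTrack, SubsampleReport]:
    """Binomially thin a track so the median promoter count matches a target.

    Every count is thinned by an independent binomial draw with retention
    probability p; p is found by bisection on the realised median of the
    promoter window counts (tolerance: achieved median within
    ``median_rtol`` of the target, or the p-interval below ``p_tol``).
    Reproducible for a fixed seed; upsampling is unsupported.
    """
    if target_median <= 0:
        raise ValidationError("target_median must be > 0")
    counts = promoter_window_counts(track, promoters, halfwidth)
    if len(counts) == 0:
        raise ValidationError("no promoters supplied")
    med0 = float(np.median(counts))
    if med0 < target_median:
        raise ValidationError(
            f"current median {med0} < target {target_median}: upsampling "
            "unsupported"
        )
    if med0 == target_median:
        report = SubsampleReport(1.0, target_median, med0, med0, len(counts))
        return track.thinned(1.0, np.random.default_rng([seed, 0])), report

    lo, hi = 0.0, 1.0
    p = target_median / med0  # warm start at the expectation-matching ratio
    iteration = 0
    while True:
        iteration += 1
        rng = np.random.default_rng([int(seed) % (2**31), iteration])
        med = float(np.median(rng.binomial(counts, p)))
        if abs(med - target_median) <= median_rtol * target_median:
            break
        if med > target_median:
            hi = p
        else:
            lo = p
        if hi - lo < p_tol or iteration > 200:
            break
        p = (lo + hi) / 2.0

    final_rng = np.random.default_rng([int(seed) % (2**31), 10**6])
    thinned = track.thinned(p, final_rng)
    achieved = float(np.median(promoter_window_counts(thinned, promoters, halfwidth)))
    report = SubsampleReport(p, float(target_median), achieved, med0, len(counts))
    log.info(
        "subsample: p=%.4f, median %s -> %s (target %s)",
        p, med0, achieved, target_median,
    )
    return thinned, report


def rank_elements(
    elements: list[Element], track: SignalTrack, halfwidth: int = 250
) -> pd.DataFrame:
    """Rank elements by both-strand window total, descending.

    Ties break by element id (stable, deterministic); a log2(total + 1)
    column is included for display.
    """
    rows = []
    for e in elements:
        total = (
            count_window(track, e.chrom, e.summit, halfwidth, "+")
            + count_window(track, e.chrom, e.summit, halfwidth, "-")
        )
        rows.append({"id": e.id, "total_reads": total})
    df = pd.DataFrame(rows, columns=["id", "total_reads"])
    df = df.sort_values(
        ["total_reads", "id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["log2_reads"] = np.log2(df["total_reads"].to_numpy(dtype=float) + 1.0)
    return df
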