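"""Summed strand-separated signal profiles around aligned element centers.

Profiles are sums of 5'-end counts per offset from the summit ("summed
reads"), optionally flipped per element so that the sense strand (the one
with more signal) reads rightward, then smoothed with a degree-1 locally
weighted regression (tricube weights, no robustness iterations).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Element, SignalTrack, ValidationError


@dataclass
class MetaProfile:
    offsets: np.ndarray
    sense_sum: np.ndarray
    antisense_sum: np.ndarray
    sense_smooth: np.ndarray | None
    antisense_smooth: np.ndarray | None
    n_elements: int

    def to_frame(self) -> pd.DataFrame:
        data = {
            "offset": self.offsets,
            "sense_sum": self.sense_sum,
            "antisense_sum": self.antisense_sum,
        }
        if self.sense_smooth is not None:
            data["sense_smooth"] = self.sense_smooth
            data["antisense_smooth"] = self.antisense_smooth
        return pd.DataFrame(data)


def loess_smooth(x, y, span: float = 0.1) -> np.ndarray:
    """Degree-1 loess: local linear fit with tricube weights.

    At each point the nearest ``ceil(span * n)`` points are used, weighted
    by (1 - (d/dmax)^3)^3. Exact on linear data for any span; deterministic
    (boundary ties all receive zero weight, so tie-breaking cannot change
    the result). When fewer than two points carry positive weight the fit
    falls back to an unweighted fit over the neighbourhood.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or n < 3:
        raise ValidationError("need len(x) == len(y) >= 3")
    if not (0 < span <= 1):
        raise ValidationError(f"span {span} outside (0, 1]")
    k = math.ceil(span * n)
    if k < 2:
        raise ValidationError(
            f"span {span} covers only {k} point(s); need at least 2"
        )
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, k - 1)[:k]
        di = d[idx]
        dmax = di.max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = np.clip(1.0 - (di / dmax) ** 3, 0.0, None) ** 3
        if np.count_nonzero(w) < 2:
            w = np.ones_like(w)
        out[i] = _weighted_linear_at(x[idx], y[idx], w, x[i])
    return out


def _weighted_linear_at(xs, ys, w, x0) -> float:
    sw = w.sum()
    xm = (w * xs).sum() / sw
    ym = (w * ys).sum() / sw
    sxx = (w * (xs - xm) ** 2).sum()
    if sxx <= 0:
        return ym
    slope = (w * (xs - xm) * (ys - ym)).sum() / sxx
    return ym + slope * (x0 - xm)


def build_metaprofile(
    elements: list[Element],
    track: SignalTrack,
    halfwidth: int = 250,
    orient_by: str = "sense_strand",
    span: float | None = 0.1,
    mean: bool = False,
    sense_strands: dict[str, str] | None = None,
) -> MetaProfile:
    """Per-offset summed counts over elements aligned at their summits.

    With ``orient_by='sense_strand'`` every element is flipped so its
    higher-count strand reads rightward; with ``'genome_strand'`` the plus
    strand fills ``sense_sum`` unflipped. Offsets span [-hw, +hw]
    inclusive. ``span=None`` skips smoothing; ``mean=True`` divides the
    sums by the number of elements.
    """
    if orient_by not in ("sense_strand", "genome_strand"):
        raise ValidationError(f"unknown orient_by {orient_by!r}")
    if halfwidth <= 0:
        raise ValidationError("halfwidth must be > 0")
    offsets = np.arange(-halfwidth, halfwidth + 1)
    sense = np.zeros(len(offsets), dtype=float)
    anti = np.zeros(len(offsets), dtype=float)
    for e in elements:
        if e.summit is None:
            raise ValidationError(f"element {e.id or '?'} has no summit")
        center = e.summit
        lo, hi = center - halfwidth, center + halfwidth + 1
        pos_p, cnt_p = track.window_counts(e.chrom, "+", lo, hi)
        pos_m, cnt_m = track.window_counts(e.chrom, "-", lo, hi)
        if orient_by == "sense_strand":
            if sense_strands and e.id in sense_strands:
                s = sense_strands[e.id]
            else:
                s = "+" if cnt_p.sum() >= cnt_m.sum() else "-"
        else:
            s = "+"
        if s == "+":
            np.add.at(sense, pos_p - center + halfwidth, cnt_p)
            np.add.at(anti, pos_m - center + halfwidth, cnt_m)
        else:
            np.add.at(sense, center - pos_m + halfwidth, cnt_m)
            np.add.at(anti, center - pos_p + halfwidth, cnt_p)
    n = len(elements)
    if mean and n > 0:
        sense = sense / n
        anti = anti / n
    if span is not None:
        sm_s = loess_smooth(offsets, sense, span)
        sm_a = loess_smooth(offsets, anti, span)
    else:
        sm_s = sm_a = None
    return MetaProfile(offsets, sense, anti, sm_s, sm_a, n)
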