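"""PWM scanning anchored at initiation maxima and central-enrichment tests.

The central-enrichment statistic is the core binomial test popularised by
CentriMo: count, per element, whether the best-scoring motif site falls
within a fixed central window around the alignment anchor, and compare the
central fraction against the uniform-placement expectation with an
upper-tail binomial probability. One best site per sequence ("zero-or-one
occurrence"), so long elements cannot dominate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMMotif:
    """Position probability matrix over ACGT with a background model.

    Scanning uses log2-odds scores; an ``N`` in the sequence contributes 0
    to the score at every motif position it covers.
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be a width x 4 matrix")
        if self.width < 4:
            raise ValueError(f"PWM width {self.width} < 4")
        rowsums = self.probs.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(rowsums - 1.0)))
            raise ValueError(
                f"PWM row {bad} sums to {rowsums[bad]:.4f}, not 1 within 1e-3"
            )
        if abs(self.background.sum() - 1.0) > 1e-3:
            raise ValueError("background does not sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """width x 5 log2-odds matrix; column 4 is N (score 0)."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background[None, :])
        lo = np.where(np.isneginf(lo), -30.0, lo)  # floor for zero probabilities
        return np.hstack([lo, np.zeros((self.width, 1))])

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))


def default_inr_pwm() -> PWMMotif:
    """A documented INR-like stand-in matrix (TCAGT core, TCAGTY consensus).

    This is a synthetic, package-supplied matrix for testing and simulation;
    analyses of real data should supply their own PWM file.
    """
    strong, rest = 0.85, 0.05
    row = lambda b: [strong if x == b else rest for x in _BASES]  # noqa: E731
    probs = np.array(
        [
            row("T"),
            row("C"),
            row("A"),
            row("G"),
            row("T"),
            [0.05, 0.45, 0.05, 0.45],  # Y = C/T
        ]
    )
    return PWMMotif(probs=probs, name="INR_synthetic")


INR_CONSENSUS = "TCAGTT"
# index of the initiation base (+1) within the consensus/motif
INR_ANCHOR_OFFSET = 2


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    idx = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        idx[arr == ord(b)] = i
    return idx


def scan_pwm(seq: str, pwm: PWMMotif, strand: str = "+") -> tuple[np.ndarray, int]:
    """Log2-odds scores at every offset, plus the best (leftmost max) offset.

    For ``strand == '-'`` the reverse complement is scanned and offsets are
    reported in the original coordinate frame: offset j is the leftmost base
    of the site in the input sequence.
    """
    w = pwm.width
    if len(seq) < w:
        raise ValueError(f"sequence length {len(seq)} < motif width {w}")
    target = revcomp(seq) if strand == "-" else seq
    idx = _encode(target)
    lo = pwm.log_odds
    n_off = len(seq) - w + 1
    scores = np.zeros(n_off)
    for i in range(w):
        scores += lo[i, idx[i:i + n_off]]
    if strand == "-":
        scores = scores[::-1]  # back to original frame (leftmost base of site)
    best = int(np.argmax(scores))
    return scores, best


@dataclass(frozen=True)
class InitiationAnchor:
    element_id: str
    strand: str
    position: int
    count: int


def anchor_initiation_max(track, element, strand: str, halfwidth: int):
    """Position of maximal 5'-end count on one strand around the summit.

    Ties resolve to the leftmost position. Returns None (and logs) when the
    window carries no signal on that strand.
    """
    center = element.summit
    hit = track.argmax(
        element.chrom, strand, center - halfwidth, center + halfwidth + 1
    )
    if hit is None:
        log.debug(
            "element %s: no %s-strand signal in +/-%d window; skipped",
            element.id, strand, halfwidth,
        )
        return None
    pos, count = hit
    return InitiationAnchor(element.id, strand, pos, count)


@dataclass
class CentralEnrichmentResult:
    central_halfwidth: int
    n_total: int
    n_central: int
    p_null: float
    p_value: float
    fold: float


def _central_offset_counts(
    window_halfwidth: int, central_halfwidth: int, motif_width: int
) -> tuple[int, int]:
    """(#valid site-start offsets, #central ones) for a full-window scan.

    Offsets are motif-start positions relative to the window center, valid
    in [-hw, hw - width + 1]; a site is central when its start lies within
    +/- central_halfwidth of the center.
    """
    lo, hi = -window_halfwidth, window_halfwidth - motif_width + 1
    n_valid = hi - lo + 1
    c_lo, c_hi = max(lo, -central_halfwidth), min(hi, central_halfwidth)
    n_central = max(0, c_hi - c_lo + 1)
    return n_valid, n_central


def central_enrichment(
    best_offsets: Sequence[int],
    window_halfwidth: int,
    central_halfwidth: int,
    motif_width: int = 1,
) -> CentralEnrichmentResult:
    """Binomial upper-tail test for overrepresentation of central best sites.

    ``best_offsets`` are site-start offsets relative to the window center.
    The null central fraction accounts for the reduced number of valid
    start offsets at motif width > 1.
    """
    if not (0 < central_halfwidth <= window_halfwidth):
        raise ValueError(
            f"central halfwidth {central_halfwidth} outside "
            f"(0, {window_halfwidth}]"
        )
    offsets = np.asarray(list(best_offsets), dtype=int)
    n_total = len(offsets)
    if n_total < 1:
        raise ValueError("need at least one best-site offset")
    n_valid, n_central_valid = _central_offset_counts(
        window_halfwidth, central_halfwidth, motif_width
    )
    p_null = n_central_valid / n_valid
    n_central = int(np.sum(np.abs(offsets) <= central_halfwidth))
    if p_null >= 1.0:
        p_value = 1.0
    else:
        # upper tail Pr[X >= n_central]
        p_value = float(stats.binom.sf(n_central - 1, n_total, p_null))
    p_value = min(max(p_value, 0.0), 1.0)
    expected = n_total * p_null
    fold = n_central / expected if expected > 0 else float("inf")
    return CentralEnrichmentResult(
        central_halfwidth=central_halfwidth,
        n_total=n_total,
        n_central=n_central,
        p_null=p_null,
        p_value=p_value,
        fold=fold,
    )


def central_enrichment_ladder(
    best_offsets: Sequence[int],
    window_halfwidth: int,
    central_halfwidths: Sequence[int],
    motif_width: int = 1,
) -> tuple[list[CentralEnrichmentResult], CentralEnrichmentResult, float]:
    """Evaluate a ladder of central widths; Bonferroni over windows.

    Returns (all results, best result by raw p, Bonferroni-adjusted p of
    the best window).
    """
    if not central_halfwidths:
        raise ValueError("need at least one central halfwidth")
    results = [
        central_enrichment(best_offsets, window_halfwidth, c, motif_width)
        for c in central_halfwidths
    ]
    best = min(results, key=lambda r: r.p_value)
    adjusted = min(1.0, best.p_value * len(results))
    return results, best, adjusted


def best_site_offset(
    window_seq: str, pwm: PWMMotif, strand: str
) -> int:
    """Best-site start offset relative to the window center, in the
    transcription frame of ``strand``.

    For the minus strand the window is reverse complemented and scanned
    forward, so positive offsets point downstream of leftward transcription;
    window length must be odd so the center maps onto itself.
    """
    if strand == "-":
        window_seq = revcomp(window_seq)
    _, best = scan_pwm(window_seq, pwm, "+")
    center = len(window_seq) // 2
    return best - center


def strand_separated_inr_profile(
    elements: Sequence,
    track,
    genome: Mapping[str, str],
    pwm: PWMMotif,
    window_halfwidth: int = 250,
    central_halfwidth: int = 50,
    sense_strands: Mapping[str, str] | None = None,
) -> dict[str, dict]:
    """Best-site offset profiles around initiation maxima, per strand role.

    For every element, the maximal-initiation base is found separately on
    its sense strand (the strand with more signal) and the antisense
    strand; the sequence window around each anchor is scanned for the best
    motif site (in the transcription frame of that strand) and the offsets
    are tested for central enrichment. Elements with no signal on a strand,
    or whose window runs off the sequence, are skipped with a log entry.
    """
    roles: dict[str, list[int]] = {"sense": [], "antisense": []}
    for e in elements:
        if sense_strands and e.id in sense_strands:
            sense = sense_strands[e.id]
        else:
            plus = track.window_sum(
                e.chrom, "+", e.summit - window_halfwidth,
                e.summit + window_halfwidth,
            )
            minus = track.window_sum(
                e.chrom, "-", e.summit - window_halfwidth,
                e.summit + window_halfwidth,
            )
            sense = "+" if plus >= minus else "-"
        seq = genome.get(e.chrom)
        if seq is None:
            log.debug("element %s: no sequence for %s; skipped", e.id, e.chrom)
            continue
        for role, strand in (("sense", sense), ("antisense", "-" if sense == "+" else "+")):
            anchor = anchor_initiation_max(track, e, strand, window_halfwidth)
            if anchor is None:
                continue
            lo = anchor.position - window_halfwidth
            hi = anchor.position + window_halfwidth + 1
            if lo < 0 or hi > len(seq):
                log.debug("element %s: window off sequence end; skipped", e.id)
                continue
            roles[role].append(
                best_site_offset(seq[lo:hi], pwm, strand)
            )
    out: dict[str, dict] = {}
    for role, offsets in roles.items():
        entry: dict = {"offsets": np.array(offsets, dtype=int)}
        if offsets:
            entry["enrichment"] = central_enrichment(
                offsets, window_halfwidth, central_halfwidth, pwm.width
            )
        else:
            entry["enrichment"] = None
        out[role] = entry
    return out


def _iupac_match_offsets(seq: str, pattern: str) -> list[int]:
    allowed = [set(IUPAC[c]) for c in pattern.upper()]
    w = len(allowed)
    seq = seq.upper()
    hits = []
    for j in range(len(seq) - w + 1):
        if all(seq[j + i] in allowed[i] for i in range(w)):
            hits.append(j)
    return hits


def positional_motif_profile(
    elements: Sequence,
    motif,
    genome: Mapping[str, str],
    anchor: str = "summit",
    track=None,
    window_halfwidth: int = 250,
    score_cutoff: float | None = None,
    strand_aware: bool = True,
    sense_strands: Mapping[str, str] | None = None,
) -> "pd.DataFrame":
    """Per-offset occurrence frequency of a motif around aligned anchors.

    ``motif`` is an IUPAC string (exact matching, e.g. the AATAAA
    polyadenylation signal) or a PWMMotif with ``score_cutoff``. Offsets
    are reported in the transcription frame of each element's sense strand
    when ``strand_aware`` (downstream = positive).
    """
    import pandas as pd

    offsets_axis = np.arange(-window_halfwidth, window_halfwidth + 1)
    hits = np.zeros(len(offsets_axis), dtype=float)
    n_elements = 0
    for e in elements:
        seq = genome.get(e.chrom)
        if seq is None:
            continue
        if anchor == "initiation_max":
            if track is None:
                raise ValueError("anchor='initiation_max' requires a track")
            sense = _element_sense(e, track, window_halfwidth, sense_strands)
            a = anchor_initiation_max(track, e, sense, window_halfwidth)
            if a is None:
                continue
            center = a.position
        else:
            center = e.summit
            sense = _element_sense(e, track, window_halfwidth, sense_strands) \
                if (strand_aware and track is not None) else "+"
        lo, hi = center - window_halfwidth, center + window_halfwidth + 1
        if lo < 0 or hi > len(seq):
            continue
        window = seq[lo:hi]
        if strand_aware and sense == "-":
            window = revcomp(window)
        if isinstance(motif, PWMMotif):
            scores, _ = scan_pwm(window, motif, "+")
            cutoff = score_cutoff if score_cutoff is not None else 0.0
            starts = np.nonzero(scores >= cutoff)[0].tolist()
        else:
            starts = _iupac_match_offsets(window, str(motif))
        for j in starts:
            hits[j] += 1
        n_elements += 1
    freq = hits / n_elements if n_elements else hits
    width = motif.width if isinstance(motif, PWMMotif) else len(str(motif))
    valid = offsets_axis <= window_halfwidth - width + 1
    return pd.DataFrame(
        {"offset": offsets_axis[valid], "frequency": freq[valid],
         "n_elements": n_elements}
    )


def _element_sense(e, track, halfwidth, sense_strands=None) -> str:
    if sense_strands and e.id in sense_strands:
        return sense_strands[e.id]
    if track is None:
        return "+"
    plus = track.window_sum(e.chrom, "+", e.summit - halfwidth, e.summit + halfwidth)
    minus = track.window_sum(e.chrom, "-", e.summit - halfwidth, e.summit + halfwidth)
    return "+" if plus >= minus else "-"
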