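"""Genomic-class assignment and element curation.

Elements are partitioned into promoters (overlapping an annotated TSS
base), intragenic (overlapping a gene body) and intergenic; intergenic
status additionally requires clearance from every gene 5' end (>= 500 bp by
default) and 3' end (>= 1500 bp), the distance rules used to build clean
putative-enhancer sets free of gene read-through. Elements near auxiliary
(RAMPAGE-like / lncRNA) TSSs are removed as unannotated promoters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_formats import Element, GenomeAnnotation, ValidationError

log = logging.getLogger(__name__)

GENOMIC_CLASSES = ("intergenic", "intragenic", "promoter")


@dataclass(frozen=True)
class ClassifierConfig:
    min_dist_5prime: int = 500
    min_dist_3prime: int = 1500
    tss_exclusion_radius: int = 500

    def __post_init__(self) -> None:
        for f in ("min_dist_5prime", "min_dist_3prime", "tss_exclusion_radius"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")


@dataclass
class ClassifiedElement:
    element: Element
    genomic_class: str
    tss_filtered: bool = False


def _point_interval_distance(point: int, start: int, end: int) -> int:
    """Distance from a coordinate to a half-open interval (0 if inside)."""
    if point <= start:
        return start - point
    if point >= end:
        return point - end
    return 0


def classify_element(
    e: Element, ann: GenomeAnnotation, cfg: ClassifierConfig | None = None
) -> ClassifiedElement:
    """Assign one of {promoter, intragenic, intergenic} to an element.

    Promoter wins over intragenic for TSSs nested inside other genes.
    An element that is neither promoter nor intragenic but sits closer than
    the configured clearances to some gene end is labelled intergenic with
    ``tss_filtered=True`` and is excluded from downstream intergenic sets.
    """
    cfg = cfg or ClassifierConfig()
    if not ann.genes:
        raise ValidationError("annotation has no genes")
    if e.chrom not in ann.chromosomes:
        raise ValidationError(f"unknown chromosome {e.chrom!r}")

    genes = [g for g in ann.genes if g.chrom == e.chrom]
    for g in genes:
        if e.start <= g.tss < e.end:
            return ClassifiedElement(e, "promoter")
    for g in genes:
        if e.start < g.end and e.end > g.start:
            return ClassifiedElement(e, "intragenic")
    too_close = False
    for g in genes:
        d5 = _point_interval_distance(g.five_prime_boundary, e.start, e.end)
        d3 = _point_interval_distance(g.three_prime_boundary, e.start, e.end)
        if d5 < cfg.min_dist_5prime or d3 < cfg.min_dist_3prime:
            too_close = True
            break
    return ClassifiedElement(e, "intergenic", tss_filtered=too_close)


def classify_elements(
    elements: list[Element],
    ann: GenomeAnnotation,
    cfg: ClassifierConfig | None = None,
) -> list[ClassifiedElement]:
    return [classify_element(e, ann, cfg) for e in elements]


def filter_unannotated_tss(
    classified: list[ClassifiedElement],
    ann: GenomeAnnotation,
    cfg: ClassifierConfig | None = None,
) -> list[ClassifiedElement]:
    """Drop intergenic/intragenic elements near an auxiliary TSS.

    The element interval is expanded by ``tss_exclusion_radius`` on both
    sides; any auxiliary TSS falling inside the expanded interval flags the
    element as an unannotated promoter, and it is removed from the returned
    list. Promoter-class elements pass through untouched.
    """
    cfg = cfg or ClassifierConfig()
    aux = ann.auxiliary_tss()
    if not aux:
        return list(classified)
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos, _ in aux:
        by_chrom.setdefault(chrom, []).append(pos)
    kept: list[ClassifiedElement] = []
    n_removed = 0
    for ce in classified:
        if ce.genomic_class == "promoter":
            kept.append(ce)
            continue
        e = ce.element
        lo = e.start - cfg.tss_exclusion_radius
        hi = e.end + cfg.tss_exclusion_radius
        near = any(lo <= p < hi for p in by_chrom.get(e.chrom, ()))
        if near:
            n_removed += 1
            continue
        kept.append(ce)
    log.info("removed %d elements near auxiliary TSSs", n_removed)
    return kept


def refine_enhancers(
    enhancers: list[Element], dhs_peaks: list[Element]
) -> list[Element]:
    """Replace each enhancer with its unique overlapping DHS peak.

    Enhancers overlapping exactly one peak are emitted as that peak
    (carrying the enhancer's id and provenance); enhancers overlapping zero
    or multiple peaks (likely spanning several regulatory elements) are
    dropped, with counts logged.
    """
    refined: list[Element] = []
    n_zero = n_multi = 0
    for enh in enhancers:
        overlapping = [
            p for p in dhs_peaks
            if p.chrom == enh.chrom and p.start < enh.end and p.end > enh.start
        ]
        if len(overlapping) == 1:
            p = overlapping[0]
            refined.append(
                Element(
                    p.chrom, p.start, p.end, id=enh.id or p.id,
                    score=p.score, strand=enh.strand, summit=p.summit,
                    source=f"refined:{enh.source or enh.id}",
                )
            )
        elif not overlapping:
            n_zero += 1
        else:
            n_multi += 1
    log.info(
        "refine_enhancers: kept %d, dropped %d without a peak, %d with "
        "multiple peaks", len(refined), n_zero, n_multi,
    )
    return refined


def classified_to_frame(classified: list[ClassifiedElement]) -> pd.DataFrame:
    rows = [
        {
            "id": ce.element.id,
            "chrom": ce.element.chrom,
            "start": ce.element.start,
            "end": ce.element.end,
            "summit": ce.element.summit,
            "class": ce.genomic_class,
            "tss_filtered": ce.tss_filtered,
        }
        for ce in classified
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "start", "end", "summit", "class", "tss_filtered"],
    )
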