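"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:
directional gene promoters, intergenic regulatory elements spanning
bidirectional / asymmetric / unidirectional transcription, strand-split
read counts (Binomial(N, q) with N Poisson or negative binomial),
discretised-Gaussian initiation positions around planted per-strand
anchors, an INR consensus written into the genome at each anchor, and
activity labels with a fold-change in expected reads between active and
inactive elements. All outputs are valid inputs for every other module and
byte-identical across runs with the same seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    Element,
    Gene,
    GenomeAnnotation,
    SignalTrack,
    ValidationError,
    write_bed,
    write_fasta,
    write_gtf_genes,
    write_signal_pair,
)
from .motifs import INR_ANCHOR_OFFSET, INR_CONSENSUS, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic element class.

    q is the probability that a read falls on the element's sense strand
    (0.5 = perfectly bidirectional); lam the expected total reads; sigma
    the initiation-position dispersion in bp around each anchor.
    """

    n: int
    q: float
    lam: float
    sigma: float = 15.0
    divergent_gap: int = 110
    plant_sense: bool = True
    plant_antisense: bool = False

    def __post_init__(self) -> None:
        if not (0.5 <= self.q <= 1.0):
            raise ValidationError(f"q {self.q} outside [0.5, 1]")
        if self.lam <= 0:
            raise ValidationError("lam must be > 0")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


def default_classes() -> dict[str, ClassSpec]:
    return {
        "bidirectional": ClassSpec(n=150, q=0.5, lam=200.0, plant_antisense=True),
        "asymmetric": ClassSpec(n=150, q=0.75, lam=200.0),
        "unidirectional": ClassSpec(n=150, q=0.95, lam=200.0),
        "nonenhancer": ClassSpec(n=50, q=0.5, lam=20.0, plant_sense=False),
    }


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "chr2L"
    n_genes: int = 30
    gene_length_range: tuple[int, int] = (2000, 5000)
    gene_flank: int = 2000
    element_width: int = 400
    element_spacing: int = 1500
    promoter_q: float = 0.97
    promoter_lam: float = 400.0
    gc_content: float = 0.5
    noise: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 0.2  # variance = lam + dispersion * lam^2
    plant_inr: bool = True
    activity_effect: float = 4.0  # active lam / inactive lam
    active_fraction: float = 0.5
    genome_length: int | None = None  # derived from content when None
    classes: dict[str, ClassSpec] = field(default_factory=default_classes)

    def __post_init__(self) -> None:
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if self.activity_effect < 1:
            raise ValidationError("activity_effect must be >= 1")


@dataclass
class SimResult:
    genome: dict[str, str]
    annotation: GenomeAnnotation
    elements: list[Element]  # enhancer-class peaks (the peaks.bed content)
    promoters: list[Element]
    track: SignalTrack
    labels: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def _draw_total(rng: np.random.Generator, lam: float, cfg: SimConfig) -> int:
    if cfg.noise == "poisson":
        return int(rng.poisson(lam))
    # gamma-Poisson mixture: dispersion d gives variance lam + d * lam^2
    shape = 1.0 / cfg.nb_dispersion
    return int(rng.poisson(rng.gamma(shape, lam / shape)))


def _scatter_positions(
    rng: np.random.Generator, anchor: int, sigma: float, n: int, length: int
) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if sigma == 0:
        pos = np.full(n, anchor, dtype=np.int64)
    else:
        pos = np.rint(rng.normal(anchor, sigma, size=n)).astype(np.int64)
    return np.clip(pos, 0, length - 1)


def _plant(seq: np.ndarray, anchor: int, strand: str) -> None:
    """Write the INR consensus so its initiation base sits at ``anchor``."""
    motif = INR_CONSENSUS
    if strand == "+":
        start = anchor - INR_ANCHOR_OFFSET
        bases = motif
    else:
        start = anchor + INR_ANCHOR_OFFSET - len(motif) + 1
        bases = revcomp(motif)
    if start < 0 or start + len(bases) > len(seq):
        return
    seq[start:start + len(bases)] = np.frombuffer(bases.encode(), dtype=np.uint8)


def simulate(cfg: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate a complete synthetic dataset; optionally write the files.

    When ``outdir`` is given, writes genome.fa, genes.gtf, peaks.bed,
    plus.bedGraph, minus.bedGraph, labels.tsv and truth.tsv there.
    """
    rng = np.random.default_rng(int(cfg.seed) % (2**31))
    chrom = cfg.chrom

    # -- gene layout: non-overlapping genes with >= gene_flank on each side
    genes: list[Gene] = []
    cursor = 5000
    for i in range(cfg.n_genes):
        cursor += cfg.gene_flank + int(rng.integers(0, 500))
        glen = int(rng.integers(*cfg.gene_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"g{i:04d}", chrom, cursor, cursor + glen, strand))
        cursor += glen + cfg.gene_flank

    # -- enhancer-class elements in a gene-free desert downstream of genes
    element_specs: list[tuple[str, ClassSpec]] = []
    for cls in sorted(cfg.classes):
        spec = cfg.classes[cls]
        element_specs.extend([(cls, spec)] * spec.n)
    desert_start = cursor + 3 * cfg.element_spacing
    step = cfg.element_width + cfg.element_spacing
    n_el = len(element_specs)
    required = desert_start + n_el * step + 5000
    if cfg.genome_length is not None and cfg.genome_length < required:
        raise ValidationError(
            f"genome length {cfg.genome_length} too small for requested "
            f"content (needs {required})"
        )
    genome_length = cfg.genome_length or required

    # -- background genome sequence (i.i.d., configurable GC)
    p_gc = cfg.gc_content / 2.0
    p_at = (1.0 - cfg.gc_content) / 2.0
    seq = rng.choice(_BASES, size=genome_length, p=[p_at, p_gc, p_gc, p_at])
    seq = np.ascontiguousarray(seq)

    track = SignalTrack({chrom: genome_length})
    truth_rows = []
    label_rows = []
    elements: list[Element] = []
    promoters: list[Element] = []

    # -- promoter elements at gene TSSs (directional, sense = gene strand)
    half_w = cfg.element_width // 2
    for g in genes:
        e = Element(
            chrom, g.tss - half_w, g.tss + half_w, id=f"prom_{g.id}",
            strand=g.strand, summit=g.tss, source="simulated",
        )
        promoters.append(e)
        spec = ClassSpec(n=1, q=cfg.promoter_q, lam=cfg.promoter_lam)
        _simulate_element(
            rng, cfg, spec, e, g.strand, seq, track, truth_rows,
            cls="promoter", status="", plant_inr=cfg.plant_inr,
        )

    # -- enhancer-class elements
    counters: dict[str, int] = {}
    for i, (cls, spec) in enumerate(element_specs):
        counters[cls] = counters.get(cls, 0) + 1
        start = desert_start + i * step
        center = start + half_w
        e = Element(
            chrom, start, start + cfg.element_width,
            id=f"{cls[:3]}_{counters[cls]:04d}", summit=center,
            source="simulated",
        )
        elements.append(e)
        sense = "+" if rng.random() < 0.5 else "-"
        if cls == "nonenhancer":
            status = "nonenhancer"
            eff_spec = spec
        else:
            active = rng.random() < cfg.active_fraction
            status = "active" if active else "inactive"
            eff_spec = spec if active else replace(
                spec, lam=spec.lam / cfg.activity_effect
            )
        label_rows.append(
            {"id": e.id, "stage": "6-8h", "tissue": "embryo", "status": status}
        )
        _simulate_element(
            rng, cfg, eff_spec, e, sense, seq, track, truth_rows,
            cls=cls, status=status, plant_inr=cfg.plant_inr,
        )

    genome = {chrom: seq.tobytes().decode()}
    annotation = GenomeAnnotation(genes=genes, extra_chromosomes={chrom})
    labels = pd.DataFrame(
        label_rows, columns=["id", "stage", "tissue", "status"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["id", "class", "q", "lam", "sense_strand", "anchor_sense",
                 "anchor_antisense", "status", "n_reads"],
    )
    result = SimResult(
        genome, annotation, elements, promoters, track, labels, truth, cfg
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _simulate_element(
    rng, cfg, spec, e, sense, seq, track, truth_rows, cls, status, plant_inr
):
    anti = "-" if sense == "+" else "+"
    jitter = int(rng.integers(-10, 11))
    anchor_sense = e.summit + jitter
    # divergent initiation: the antisense anchor sits upstream of the sense one
    if sense == "+":
        anchor_anti = anchor_sense - spec.divergent_gap
    else:
        anchor_anti = anchor_sense + spec.divergent_gap

    total = _draw_total(rng, spec.lam, cfg)
    n_sense = int(rng.binomial(total, spec.q)) if total else 0
    n_anti = total - n_sense
    length = len(seq)
    for strand, anchor, n in (
        (sense, anchor_sense, n_sense), (anti, anchor_anti, n_anti)
    ):
        pos = _scatter_positions(rng, anchor, spec.sigma, n, length)
        if len(pos):
            upos, ucnt = np.unique(pos, return_counts=True)
            track.add_array(e.chrom, strand, upos, ucnt)
    if plant_inr:
        if spec.plant_sense:
            _plant(seq, anchor_sense, sense)
        if spec.plant_antisense:
            _plant(seq, anchor_anti, anti)
    truth_rows.append(
        {
            "id": e.id, "class": cls, "q": spec.q, "lam": spec.lam,
            "sense_strand": sense, "anchor_sense": anchor_sense,
            "anchor_antisense": anchor_anti, "status": status,
            "n_reads": total,
        }
    )


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gtf",
        "peaks": outdir / "peaks.bed",
        "plus": outdir / "plus.bedGraph",
        "minus": outdir / "minus.bedGraph",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(result.genome, paths["genome"])
    write_gtf_genes(result.annotation, paths["genes"])
    write_bed(result.elements, paths["peaks"])
    write_signal_pair(result.track, paths["plus"], paths["minus"])
    result.labels.to_csv(paths["labels"], sep="\t", index=False)
    result.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    return paths


def truth_recovery_report(
    truth: pd.DataFrame, scored: pd.DataFrame
) -> dict:
    """Compare pipeline calls with simulation ground truth.

    Returns per-class OI bias (mean called OI minus max(q, 1-q)), the
    directionality confusion matrix (true class x called class), and
    per-class recall of the matching directionality call.
    """
    missing = set(truth["id"]) - set(scored["id"])
    if missing:
        raise ValidationError(
            f"{len(missing)} truth ids missing from scored table"
        )
    merged = truth.merge(scored, on="id", suffixes=("_true", ""))
    confusion = pd.crosstab(merged["class"], merged["direction_class"])
    bias = {}
    recall = {}
    for cls, grp in merged.groupby("class"):
        expected_oi = np.maximum(grp["q"], 1 - grp["q"])
        called = grp["oi"].to_numpy(dtype=float)
        ok = ~np.isnan(called)
        bias[cls] = float(np.mean(called[ok] - expected_oi[ok])) if ok.any() else np.nan
        if cls in ("bidirectional", "asymmetric", "unidirectional"):
            recall[cls] = float((grp["direction_class"] == cls).mean())
    return {"confusion": confusion, "oi_bias": bias, "recall": recall,
            "n": len(merged)}
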