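"""End-to-end orchestration: classify -> oi -> metaprofile -> inr -> activity.

Every stage writes a TSV with fixed 6-significant-digit float formatting so
that re-running with the same configuration and inputs yields byte-stable
output; the run manifest records versions, seed and a config hash (no
timestamps, for the same reason).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .activity import join_activity, stratified_summary
from .classify import (
    ClassifierConfig,
    classified_to_frame,
    classify_elements,
    filter_unannotated_tss,
)
from .io_formats import (
    ValidationError,
    elements_to_frame,
    read_bed,
    read_fasta,
    read_gtf_genes,
    read_labels,
    read_pwm,
    read_signal_pair,
    read_tss_bed,
)
from .metaprofile import build_metaprofile
from .metrics import DirectionalityThresholds, score_elements
from .motifs import default_inr_pwm, strand_separated_inr_profile

log = logging.getLogger(__name__)

STAGES = ("classify", "oi", "metaprofile", "inr", "activity")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    peaks: str
    genes: str
    plus: str
    minus: str
    outdir: str
    genome: str | None = None
    pwm: str | None = None
    labels: str | None = None
    aux_tss: list[str] = field(default_factory=list)
    halfwidth: int = 250
    span: float = 0.1
    central_halfwidth: int = 50
    stage: str = "6-8h"
    tissue: str = "embryo"
    seed: int = 0
    skip: tuple[str, ...] = ()
    thresholds: DirectionalityThresholds = field(
        default_factory=DirectionalityThresholds
    )
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def validate(self) -> None:
        for name in ("peaks", "genes", "plus", "minus"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise ValidationError(f"input {name!r} not found: {p}")
        for p in self.aux_tss:
            if not Path(p).is_file():
                raise ValidationError(f"auxiliary TSS file not found: {p}")
        if "inr" not in self.skip:
            if self.genome is None:
                raise ValidationError(
                    "motif stage enabled but no genome FASTA configured"
                )
            if not Path(self.genome).is_file():
                raise ValidationError(f"genome not found: {self.genome}")
            if self.pwm is not None and not Path(self.pwm).is_file():
                raise ValidationError(f"PWM not found: {self.pwm}")
        if "activity" not in self.skip and self.labels is not None:
            if not Path(self.labels).is_file():
                raise ValidationError(f"labels not found: {self.labels}")
        for s in self.skip:
            if s not in STAGES:
                raise ValidationError(f"unknown stage in skip: {s!r}")

    def config_hash(self) -> str:
        payload = {
            k: (list(v) if isinstance(v, (tuple, list)) else str(v))
            for k, v in sorted(self.__dict__.items())
            if k != "outdir"  # hash covers the analysis, not its destination
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(cfg: PipelineConfig) -> Path:
    """Run every enabled stage; fail fast on missing inputs.

    Returns the report directory. A stage failure raises StageError naming
    the stage; nothing is written for stages after the failure.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "ernascope",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": [],
    }

    def timed(stage: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", stage)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is None:
                    log.info("stage %s: done in %.2fs", stage, dt)
                    manifest["stages"].append(stage)
                return False

        return _Timer()

    # ---- load shared inputs -------------------------------------------
    try:
        peaks = read_bed(cfg.peaks)
        ann = read_gtf_genes(cfg.genes)
        for i, path in enumerate(cfg.aux_tss):
            ann.tss_sets[f"aux{i}"] = read_tss_bed(path)
        track = read_signal_pair(cfg.plus, cfg.minus)
    except Exception as exc:
        raise StageError("load", exc) from exc

    # ---- classify ------------------------------------------------------
    try:
        with timed("classify"):
            classified = classify_elements(peaks, ann, cfg.classifier)
            kept = filter_unannotated_tss(classified, ann, cfg.classifier)
            write_tsv(classified_to_frame(classified), outdir / "classified.tsv")
            usable = [
                ce.element for ce in kept
                if not (ce.genomic_class == "intergenic" and ce.tss_filtered)
            ]
    except Exception as exc:
        raise StageError("classify", exc) from exc

    # ---- oi ------------------------------------------------------------
    try:
        with timed("oi"):
            scored = score_elements(usable, track, cfg.halfwidth, cfg.thresholds)
            write_tsv(scored, outdir / "oi.tsv")
    except Exception as exc:
        raise StageError("oi", exc) from exc

    sense_map = dict(zip(scored["id"], scored["sense_strand"]))

    # ---- metaprofile ---------------------------------------------------
    if "metaprofile" not in cfg.skip:
        try:
            with timed("metaprofile"):
                profile = build_metaprofile(
                    usable, track, cfg.halfwidth, span=cfg.span,
                    sense_strands=sense_map,
                )
                write_tsv(profile.to_frame(), outdir / "metaprofile.tsv")
        except Exception as exc:
            raise StageError("metaprofile", exc) from exc

    # ---- inr -----------------------------------------------------------
    if "inr" not in cfg.skip:
        try:
            with timed("inr"):
                genome = read_fasta(cfg.genome)
                pwm = read_pwm(cfg.pwm) if cfg.pwm else default_inr_pwm()
                by_id = {e.id: e for e in usable}
                rows = []
                for cls in ("bidirectional", "asymmetric", "unidirectional"):
                    ids = scored.loc[
                        scored["direction_class"] == cls, "id"
                    ].tolist()
                    subset = [by_id[i] for i in ids if i in by_id]
                    if not subset:
                        continue
                    prof = strand_separated_inr_profile(
                        subset, track, genome, pwm,
                        window_halfwidth=cfg.halfwidth,
                        central_halfwidth=cfg.central_halfwidth,
                        sense_strands=sense_map,
                    )
                    for role in ("sense", "antisense"):
                        enr = prof[role]["enrichment"]
                        if enr is None:
                            continue
                        rows.append(
                            {"direction_class": cls, "strand_role": role,
                             "n_sites": enr.n_total,
                             "n_central": enr.n_central,
                             "p_null": enr.p_null, "fold": enr.fold,
                             "p_value": enr.p_value}
                        )
                write_tsv(
                    pd.DataFrame(
                        rows,
                        columns=["direction_class", "strand_role", "n_sites",
                                 "n_central", "p_null", "fold", "p_value"],
                    ),
                    outdir / "inr.tsv",
                )
        except Exception as exc:
            raise StageError("inr", exc) from exc

    # ---- activity ------------------------------------------------------
    if "activity" not in cfg.skip and cfg.labels is not None:
        try:
            with timed("activity"):
                labels = read_labels(cfg.labels)
                edf = elements_to_frame(usable).merge(
                    scored[["id", "total"]], on="id", how="left"
                )
                annotated = join_activity(edf, labels)
                summary, comparisons = stratified_summary(
                    annotated, track, cfg.stage, cfg.tissue, cfg.halfwidth
                )
                write_tsv(summary, outdir / "activity_summary.tsv")
                write_tsv(comparisons, outdir / "activity_comparisons.tsv")
        except Exception as exc:
            raise StageError("activity", exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
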