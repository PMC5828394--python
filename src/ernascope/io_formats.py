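"""Readers, writers and core containers for the formats the pipeline touches.

All internal coordinates are 0-based, half-open (BED convention). GTF input
(1-based, inclusive) is converted on read. A count at position ``p`` on the
minus strand means an RNA 5' end at ``p`` read leftward; no shifting is
applied anywhere.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a contract (coordinates, counts, schemas)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Element:
    """A genomic interval (0-based, half-open) with an optional summit.

    The summit is the position of maximal DHS or signal within the interval;
    when absent it defaults to the interval midpoint.
    """

    chrom: str
    start: int
    end: int
    id: str = ""
    score: float | None = None
    strand: str | None = None
    summit: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"element {self.id or '?'}: start {self.start} >= end {self.end}"
            )
        if self.summit is None:
            self.summit = (self.start + self.end) // 2
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"element {self.id or '?'}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        """Base coordinate of the transcription start site (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Base coordinate of the transcription end site (0-based)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def five_prime_boundary(self) -> int:
        """5' gene-end as an interval boundary (start on +, end on -)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime_boundary(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class GenomeAnnotation:
    """Gene spans plus named auxiliary TSS collections.

    ``tss_sets`` holds point TSSs, e.g. RAMPAGE-defined or lncRNA TSS sets,
    each a list of ``(chrom, position, strand)`` tuples.
    """

    genes: list[Gene] = field(default_factory=list)
    tss_sets: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    extra_chromosomes: set[str] = field(default_factory=set)

    @property
    def chromosomes(self) -> set[str]:
        chroms = {g.chrom for g in self.genes} | set(self.extra_chromosomes)
        for tset in self.tss_sets.values():
            chroms |= {c for c, _, _ in tset}
        return chroms

    def annotated_tss(self) -> list[tuple[str, int, str]]:
        return [(g.chrom, g.tss, g.strand) for g in self.genes]

    def auxiliary_tss(self) -> list[tuple[str, int, str]]:
        out: list[tuple[str, int, str]] = []
        for tset in self.tss_sets.values():
            out.extend(tset)
        return out


class SignalTrack:
    """Per-chromosome, per-strand sparse single-base 5'-end counts.

    Counts are non-negative integers keyed by (chrom, strand, position).
    Query helpers operate on sorted position arrays and use half-open
    windows throughout.
    """

    def __init__(self, chrom_lengths: Mapping[str, int] | None = None):
        self._counts: dict[tuple[str, str], dict[int, int]] = {}
        self._arrays: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths or {})

    # -- construction -------------------------------------------------
    def add(self, chrom: str, strand: str, position: int, count: int) -> None:
        if strand not in STRANDS:
            raise ValidationError(f"bad strand {strand!r}")
        if count < 0:
            raise ValidationError(f"negative count {count} at {chrom}:{position}")
        if position < 0:
            raise ValidationError(f"negative position {position} on {chrom}")
        length = self.chrom_lengths.get(chrom)
        if length is not None and position >= length:
            raise ValidationError(
                f"position {position} beyond {chrom} length {length}"
            )
        if count == 0:
            return
        bucket = self._counts.setdefault((chrom, strand), {})
        bucket[position] = bucket.get(position, 0) + int(count)
        self._arrays.pop((chrom, strand), None)

    def add_array(
        self, chrom: str, strand: str, positions: np.ndarray, counts: np.ndarray
    ) -> None:
        for p, c in zip(positions.tolist(), counts.tolist()):
            self.add(chrom, strand, int(p), int(c))

    # -- access --------------------------------------------------------
    @property
    def chroms(self) -> set[str]:
        return {c for c, _ in self._counts} | set(self.chrom_lengths)

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted position and count arrays for one chromosome strand."""
        key = (chrom, strand)
        if key not in self._arrays:
            bucket = self._counts.get(key, {})
            pos = np.fromiter(bucket.keys(), dtype=np.int64, count=len(bucket))
            order = np.argsort(pos)
            cnt = np.fromiter(bucket.values(), dtype=np.int64, count=len(bucket))
            self._arrays[key] = (pos[order], cnt[order])
        return self._arrays[key]

    def window_counts(
        self, chrom: str, strand: str, start: int, end: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Positions/counts with start <= position < end."""
        pos, cnt = self.arrays(chrom, strand)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi], cnt[lo:hi]

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> int:
        _, cnt = self.window_counts(chrom, strand, start, end)
        return int(cnt.sum())

    def argmax(
        self, chrom: str, strand: str, start: int, end: int
    ) -> tuple[int, int] | None:
        """Leftmost position of maximal count in [start, end), or None."""
        pos, cnt = self.window_counts(chrom, strand, start, end)
        if len(pos) == 0:
            return None
        i = int(np.argmax(cnt))  # np.argmax returns the first maximum
        return int(pos[i]), int(cnt[i])

    def total(self) -> int:
        return sum(sum(b.values()) for b in self._counts.values())

    def thinned(self, p: float, rng: np.random.Generator) -> "SignalTrack":
        """Binomial thinning: each read kept independently with probability p."""
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"retention probability {p} outside [0, 1]")
        out = SignalTrack(self.chrom_lengths)
        for (chrom, strand) in sorted(self._counts):
            pos, cnt = self.arrays(chrom, strand)
            if len(pos) == 0:
                continue
            kept = rng.binomial(cnt, p)
            keep = kept > 0
            out.add_array(chrom, strand, pos[keep], kept[keep])
        return out

    def iter_bedgraph(self, strand: str) -> Iterator[tuple[str, int, int, int]]:
        """Run-length merged (chrom, start, end, count) records for one strand."""
        for (chrom, s) in sorted(self._counts):
            if s != strand:
                continue
            pos, cnt = self.arrays(chrom, s)
            if len(pos) == 0:
                continue
            run_start = pos[0]
            prev_pos, prev_cnt = pos[0], cnt[0]
            for p, c in zip(pos[1:], cnt[1:]):
                if p == prev_pos + 1 and c == prev_cnt:
                    prev_pos = p
                    continue
                yield chrom, int(run_start), int(prev_pos) + 1, int(prev_cnt)
                run_start, prev_pos, prev_cnt = p, p, c
            yield chrom, int(run_start), int(prev_pos) + 1, int(prev_cnt)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Element]:
    """Read a 3-7 column BED file into Elements.

    Columns 4-6 are name, score and strand when present. A numeric 7th
    column is interpreted as a summit offset from the interval start
    (narrowPeak practice); otherwise the summit defaults to the midpoint.
    """
    path = Path(path)
    elements: list[Element] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad score") from exc
            strand = None
            if len(fields) > 5 and fields[5] in STRANDS:
                strand = fields[5]
            summit = None
            if len(fields) > 6 and fields[6] not in (".", ""):
                try:
                    summit = start + int(fields[6])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad summit offset") from exc
            try:
                elements.append(
                    Element(chrom, start, end, id=name, score=score,
                            strand=strand, summit=summit, source=str(path))
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return elements


def write_bed(elements: Iterable[Element], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fh.write(
                "\t".join([
                    e.chrom, str(e.start), str(e.end), e.id or ".",
                    "." if e.score is None else f"{e.score:g}",
                    e.strand or ".",
                    str(e.summit - e.start),
                ]) + "\n"
            )


def read_tss_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a BED of TSS points; the start coordinate is the TSS base."""
    return [(e.chrom, e.start, e.strand or "+") for e in read_bed(path)]


# ---------------------------------------------------------------------------
# bedGraph signal pairs
# ---------------------------------------------------------------------------

def _read_bedgraph_into(
    track: SignalTrack, path: str | Path, strand: str
) -> None:
    path = Path(path)
    last_end: dict[str, int] = {}
    intervals: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
            if value != int(value):
                raise ValidationError(f"{path}:{lineno}: non-integer count {value}")
            value = int(value)
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {value}")
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end, value))
    intervals.sort(key=lambda r: (r[0], r[1]))
    for chrom, start, end, value in intervals:
        if chrom in last_end and start < last_end[chrom]:
            raise ValidationError(
                f"{path}: overlapping intervals on {chrom} strand {strand} "
                f"near {start} (ambiguous counts)"
            )
        last_end[chrom] = end
        if value == 0:
            continue
        for p in range(start, end):
            track.add(chrom, strand, p, value)


def read_signal_pair(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> SignalTrack:
    """Read a strand-specific bedGraph pair into a SignalTrack.

    Intervals of width > 1 are expanded to per-base counts; overlapping
    intervals within one file are rejected as ambiguous.
    """
    track = SignalTrack(chrom_lengths)
    _read_bedgraph_into(track, plus_path, "+")
    _read_bedgraph_into(track, minus_path, "-")
    return track


def write_signal_pair(
    track: SignalTrack, plus_path: str | Path, minus_path: str | Path
) -> None:
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            for chrom, start, end, count in track.iter_bedgraph(strand):
                fh.write(f"{chrom}\t{start}\t{end}\t{count}\n")


# ---------------------------------------------------------------------------
# GTF / GFF2 genes
# ---------------------------------------------------------------------------

_GENE_FEATURES = {"gene", "transcript", "mRNA"}


def _gtf_attribute(attrs: str, key: str) -> str | None:
    # handles both `key "value";` (GTF) and `key=value;` (GFF) dialects
    for chunk in attrs.replace(";", "\n").splitlines():
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk and " " not in chunk.split("=", 1)[0]:
            k, v = chunk.split("=", 1)
        else:
            parts = chunk.split(None, 1)
            if len(parts) != 2:
                continue
            k, v = parts
        if k == key:
            return v.strip().strip('"')
    return None


def read_gtf_genes(path: str | Path) -> GenomeAnnotation:
    """Extract gene spans from a GTF/GFF2 file.

    One entry per gene id with the min-start/max-end span; duplicate ids
    with disjoint spans are merged into a single spanning entry with a
    warning. Features other than gene/transcript/mRNA are skipped.
    """
    path = Path(path)
    spans: dict[str, list] = {}  # id -> [chrom, start, end, strand, n_records]
    skipped: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, feature, start_s, end_s, _, strand, _, attrs = fields[:9]
            if feature not in _GENE_FEATURES:
                skipped[feature] = skipped.get(feature, 0) + 1
                continue
            if strand not in STRANDS:
                raise ValidationError(
                    f"{path}:{lineno}: missing or invalid strand {strand!r}"
                )
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: empty interval")
            gene_id = _gtf_attribute(attrs, "gene_id") or _gtf_attribute(attrs, "ID")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: no gene_id attribute")
            if gene_id in spans:
                rec = spans[gene_id]
                if rec[0] != chrom or rec[3] != strand:
                    raise ValidationError(
                        f"{path}: gene {gene_id} spans chromosomes/strands"
                    )
                if end <= rec[1] or start >= rec[2]:
                    log.warning(
                        "gene %s has disjoint records; merged into one span",
                        gene_id,
                    )
                rec[1] = min(rec[1], start)
                rec[2] = max(rec[2], end)
                rec[4] += 1
            else:
                spans[gene_id] = [chrom, start, end, strand, 1]
    for feature, n in skipped.items():
        log.warning("skipped %d %r features in %s", n, feature, path)
    genes = [
        Gene(gid, rec[0], rec[1], rec[2], rec[3]) for gid, rec in spans.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.start, g.id))
    return GenomeAnnotation(genes=genes)


def write_gtf_genes(ann: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in ann.genes:
            fh.write(
                f"{g.chrom}\ternascope\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f'{g.strand}\t.\tgene_id "{g.id}";\n'
            )


# ---------------------------------------------------------------------------
# MEME-minimal PWM
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path):
    """Read the first motif from a MEME-minimal letter-probability file."""
    from .motifs import PWMMotif  # local import: motifs does not import back

    path = Path(path)
    name = Path(path).stem
    background = np.full(4, 0.25)
    rows: list[list[float]] = []
    in_matrix = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("MOTIF"):
                parts = line.split()
                if len(parts) > 1:
                    name = parts[1]
                continue
            if line.lower().startswith("background letter frequencies"):
                continue
            if line.startswith(("A ", "A\t")) and ":" not in line:
                # background line of the form "A 0.25 C 0.25 G 0.25 T 0.25"
                toks = line.split()
                if len(toks) == 8:
                    background = np.array([float(toks[i]) for i in (1, 3, 5, 7)])
                continue
            if line.lower().startswith("letter-probability matrix"):
                in_matrix = True
                rows = []
                continue
            if in_matrix:
                if not line:
                    break
                toks = line.split()
                try:
                    vals = [float(t) for t in toks]
                except ValueError:
                    break
                if len(vals) != 4:
                    raise ParseError(f"{path}: matrix row with {len(vals)} columns")
                rows.append(vals)
    if not in_matrix:
        # tolerate bare numeric matrices (one row of 4 probabilities per line)
        rows = []
        with open(path) as fh:
            for raw in fh:
                toks = raw.split()
                if len(toks) == 4:
                    try:
                        rows.append([float(t) for t in toks])
                    except ValueError:
                        continue
    if not rows:
        raise ValidationError(f"{path}: no letter-probability matrix found")
    probs = np.asarray(rows, dtype=float)
    return PWMMotif(probs=probs, background=background, name=name)


def write_pwm(pwm, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwm.background
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:g} C {bg[1]:g} G {bg[2]:g} T {bg[3]:g}\n\n")
        fh.write(f"MOTIF {pwm.name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= 20 E= 0\n"
        )
        for row in pwm.probs:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA and label tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an uppercase chrom -> sequence dict.

    Uses pyfaidx for indexed access, then materialises sequences; genomes
    here are small (synthetic or per-region extracts).
    """
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


LABEL_COLUMNS = ["id", "stage", "tissue", "status"]
LABEL_STATUSES = {"active", "inactive", "nonenhancer"}


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read an activity-label TSV: id, stage, tissue, status."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        # tolerate headerless files with exactly four columns
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] != 4:
            raise ParseError(f"{path}: expected columns {LABEL_COLUMNS}")
        df.columns = LABEL_COLUMNS
    bad = set(df["status"]) - LABEL_STATUSES
    if bad:
        raise ValidationError(f"{path}: unknown status values {sorted(bad)}")
    return df[LABEL_COLUMNS]


def elements_to_frame(elements: Sequence[Element]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [e.id for e in elements],
            "chrom": [e.chrom for e in elements],
            "start": [e.start for e in elements],
            "end": [e.end for e in elements],
            "summit": [e.summit for e in elements],
        }
    )
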