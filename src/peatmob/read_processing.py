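"""Pre-clustering sequence hygiene for paired-end amplicon reads.

Implements the three steps applied to every raw MiSeq library before OTU
inference: merging of read pairs over their 3' overlap, a sliding-window
phred filter that discards any read containing a 50-nt window with mean
quality below 20, and anchored IUPAC primer trimming.  Pipeline order is
merge -> quality filter -> trim.

Rejection is always an explicit return state carrying a reason code, so
that kept + rejected = input at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

# --------------------------------------------------------------------------
# IUPAC degeneracy
# --------------------------------------------------------------------------

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string, degenerate codes included."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_mismatches(pattern: str, text: str) -> int:
    """Count positions of ``text`` not covered by the IUPAC code of ``pattern``.

    ``pattern`` and ``text`` must have equal length.  A plain base in the
    text matches a degenerate pattern code that contains it; an ambiguous
    base in the text (e.g. N from the sequencer) matches only pattern N.
    """
    if len(pattern) != len(text):
        raise ValueError("pattern and text lengths differ")
    mism = 0
    for p, t in zip(pattern, text):
        allowed = IUPAC_SETS.get(p)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {p!r}")
        if t in "ACGT":
            if t not in allowed:
                mism += 1
        else:
            # ambiguous read base: match only the fully degenerate code
            if p != "N":
                mism += 1
    return mism


def expand_iupac(pattern: str) -> list[str]:
    """All concrete ACGT strings matching an IUPAC pattern (test oracle aid)."""
    variants = [""]
    for code in pattern:
        allowed = sorted(IUPAC_SETS[code])
        variants = [v + b for v in variants for b in allowed]
    return variants


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class QualityRead:
    """A sequence with per-base phred scores."""

    id: str
    seq: str
    quals: Sequence[int]

    def __post_init__(self) -> None:
        self.quals = list(self.quals)
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.id}: seq/qual length mismatch")
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= 60):
            raise ValueError(f"{self.id}: phred outside [0, 60]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MergeParams:
    """Overlap-merging parameters (defaults follow the common merger's)."""

    min_overlap: int = 10
    max_mismatch_density: float = 0.25

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_mismatch_density <= 1.0:
            raise ValueError("max_mismatch_density must be in [0, 1]")


@dataclass(frozen=True)
class QCParams:
    """Windowed quality-filter parameters: any ``window``-nt stretch with
    mean phred strictly below ``min_mean_phred`` discards the read."""

    window: int = 50
    min_mean_phred: float = 20.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass(frozen=True)
class PrimerSpec:
    """An anchored amplification primer in IUPAC notation."""

    name: str
    iupac: str
    max_mismatches: int = 0
    end: str = "five-prime"  # or "three-prime"

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("primer sequence is empty")
        if not self.max_mismatches < len(self.iupac):
            raise ValueError("max_mismatches must be < primer length")
        if self.end not in ("five-prime", "three-prime"):
            raise ValueError("end must be 'five-prime' or 'three-prime'")


@dataclass
class Rejection:
    read_id: str
    stage: str
    reason: str


# --------------------------------------------------------------------------
# Merging
# --------------------------------------------------------------------------

def merge_pair(
    r1: QualityRead, r2: QualityRead, p: MergeParams = MergeParams()
) -> QualityRead | Rejection:
    """Merge a read pair over its best 3' overlap.

    ``r2`` is reverse-complemented; all overlap lengths from
    ``p.min_overlap`` up to the shorter read are scanned and the one with
    the lowest mismatch fraction wins (ties favour the longer overlap).
    Within the overlap the base with the higher phred is kept along with
    its phred; on a phred tie the forward read's base is kept.

    Returns the merged :class:`QualityRead`, or a :class:`Rejection` when
    no candidate overlap reaches ``max_mismatch_density``.
    """
    if not r1.seq or not r2.seq:
        raise ValueError("empty read")
    s2 = reverse_complement(r2.seq)
    q2 = list(r2.quals)[::-1]
    n1, n2 = len(r1), len(r2)

    a1 = np.frombuffer(r1.seq.encode(), dtype="S1")
    a2 = np.frombuffer(s2.encode(), dtype="S1")

    best: tuple[float, int] | None = None  # (mismatch fraction, overlap)
    for ov in range(p.min_overlap, min(n1, n2) + 1):
        mism = int((a1[n1 - ov:] != a2[:ov]).sum())
        frac = mism / ov
        if best is None or frac < best[0] or (frac == best[0] and ov > best[1]):
            best = (frac, ov)
    if best is None or best[0] > p.max_mismatch_density:
        return Rejection(r1.id, "merge", "no_overlap")

    ov = best[1]
    seq = list(r1.seq[: n1 - ov])
    quals = list(r1.quals[: n1 - ov])
    for i in range(ov):
        b1, p1 = r1.seq[n1 - ov + i], r1.quals[n1 - ov + i]
        b2, p2 = s2[i], q2[i]
        if p2 > p1:
            seq.append(b2)
            quals.append(p2)
        else:
            seq.append(b1)
            quals.append(p1)
    seq += list(s2[ov:])
    quals += list(q2[ov:])
    return QualityRead(r1.id, "".join(seq), quals)


# --------------------------------------------------------------------------
# Windowed quality filter
# --------------------------------------------------------------------------

def window_quality_filter(read: QualityRead, p: QCParams = QCParams()) -> bool:
    """Return True (keep) unless some contiguous window has mean phred
    strictly below the threshold.  Reads shorter than the window are
    evaluated as a single full-length window."""
    if not read.seq:
        raise ValueError("empty read")
    q = np.asarray(read.quals, dtype=float)
    w = min(p.window, len(q))
    csum = np.concatenate(([0.0], np.cumsum(q)))
    means = (csum[w:] - csum[:-w]) / w
    return bool(means.min() >= p.min_mean_phred)


# --------------------------------------------------------------------------
# Primer trimming
# --------------------------------------------------------------------------

def trim_primers(
    read: QualityRead, fwd: PrimerSpec, rev: PrimerSpec
) -> QualityRead | Rejection:
    """Remove the forward primer from the 5' end and the reverse primer
    (reverse-complemented) from the 3' end of a merged read.

    Matching is anchored at the read ends under IUPAC degeneracy with at
    most ``max_mismatches`` per primer; a read lacking either site is
    rejected with a reason naming the missing site.
    """
    nf, nr = len(fwd.iupac), len(rev.iupac)
    if len(read) < nf + nr:
        return Rejection(read.id, "trim", "too_short")
    if iupac_mismatches(fwd.iupac, read.seq[:nf]) > fwd.max_mismatches:
        return Rejection(read.id, "trim", "no_forward_primer")
    rc = reverse_complement(rev.iupac)
    if iupac_mismatches(rc, read.seq[-nr:]) > rev.max_mismatches:
        return Rejection(read.id, "trim", "no_reverse_primer")
    return QualityRead(read.id, read.seq[nf: len(read) - nr],
                       read.quals[nf: len(read) - nr])


# --------------------------------------------------------------------------
# Pipeline driver + FASTQ I/O
# --------------------------------------------------------------------------

@dataclass
class ProcessResult:
    kept: list[QualityRead]
    rejections: list[Rejection] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejections)


def process_read_pairs(
    pairs: Iterable[tuple[QualityRead, QualityRead]],
    fwd: PrimerSpec,
    rev: PrimerSpec,
    merge_params: MergeParams = MergeParams(),
    qc_params: QCParams = QCParams(),
) -> ProcessResult:
    """Run merge -> window filter -> primer trim over read pairs."""
    kept: list[QualityRead] = []
    rejections: list[Rejection] = []
    for r1, r2 in pairs:
        merged = merge_pair(r1, r2, merge_params)
        if isinstance(merged, Rejection):
            rejections.append(merged)
            continue
        if not window_quality_filter(merged, qc_params):
            rejections.append(Rejection(merged.id, "quality", "low_quality_window"))
            continue
        trimmed = trim_primers(merged, fwd, rev)
        if isinstance(trimmed, Rejection):
            rejections.append(trimmed)
            continue
        kept.append(trimmed)
    return ProcessResult(kept, rejections)


def read_fastq(path) -> Iterator[QualityRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield QualityRead(rec.id, str(rec.seq).upper(),
                          rec.letter_annotations["phred_quality"])


def write_fastq(reads: Iterable[QualityRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{quals}\n")


def write_rejection_log(rejections: Iterable[Rejection], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstage\treason\n")
        for rej in rejections:
            fh.write(f"{rej.read_id}\t{rej.stage}\t{rej.reason}\n")
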