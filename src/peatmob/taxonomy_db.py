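"""Reference databases and best-global-alignment taxonomy assignment.

A reference collection (a curated pmoA set, or a SILVA-like 16S set) is
trimmed to the amplified region with the study primers, dereplicated, and
used to assign each OTU the taxonomy of its best-scoring global:global
alignment.  Alignment is affine-gap Needleman-Wunsch via biopython's
PairwiseAligner; scoring defaults to +5/-4 with gap open -10 and extend
-1, the common nucleotide defaults of global search tools.

When several reference entries tie (identical sequences after trimming,
or equal best alignment scores) the assigned path is their lowest common
ancestor: the longest common prefix of the semicolon-delimited paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio import Align

from .read_processing import PrimerSpec, iupac_mismatches, reverse_complement


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RefEntry:
    id: str
    taxonomy: str  # semicolon-delimited, root first
    seq: str


@dataclass
class ReferenceDB:
    entries: list[RefEntry]
    source: str = "pmoA"

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("need gap_open <= gap_extend <= 0")


@dataclass(frozen=True)
class Assignment:
    otu_id: str
    best_ref_id: str
    identity: float  # percent over alignment columns
    taxonomy: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")


# --------------------------------------------------------------------------
# Database construction
# --------------------------------------------------------------------------

def _find_site(seq: str, pattern: str, max_mm: int, from_end: bool) -> int:
    """Position of the best primer site scanning from one end; -1 if none
    within max_mm mismatches."""
    lp = len(pattern)
    positions = range(len(seq) - lp, -1, -1) if from_end else range(len(seq) - lp + 1)
    for pos in positions:
        if iupac_mismatches(pattern, seq[pos:pos + lp]) <= max_mm:
            return pos
    return -1


def trim_database_to_primers(
    raw: Iterable[RefEntry], fwd: PrimerSpec, rev: PrimerSpec
) -> tuple[ReferenceDB, list[str]]:
    """Trim each entry to the region between the primer sites.

    The forward primer is searched from the 5' end and the
    reverse-complemented reverse primer from the 3' end, both under IUPAC
    matching with each primer's ``max_mismatches``.  Entries lacking
    either site are dropped; their ids are returned as the second element.
    """
    rc_rev = reverse_complement(rev.iupac)
    kept: list[RefEntry] = []
    dropped: list[str] = []
    for entry in raw:
        fpos = _find_site(entry.seq, fwd.iupac, fwd.max_mismatches, from_end=False)
        rpos = _find_site(entry.seq, rc_rev, rev.max_mismatches, from_end=True)
        start = fpos + len(fwd.iupac)
        if fpos < 0 or rpos < 0 or rpos <= start:
            dropped.append(entry.id)
            continue
        kept.append(RefEntry(entry.id, entry.taxonomy, entry.seq[start:rpos]))
    return ReferenceDB(kept), dropped


def lowest_common_ancestor(paths: Sequence[str]) -> str:
    """Longest common prefix of semicolon-delimited taxonomy paths."""
    if not paths:
        return ""
    split = [p.split(";") for p in paths]
    common: list[str] = []
    for ranks in zip(*split):
        if all(r == ranks[0] for r in ranks):
            common.append(ranks[0])
        else:
            break
    return ";".join(common)


def dereplicate_database(db: ReferenceDB) -> ReferenceDB:
    """Collapse identical trimmed sequences to one entry.

    Conflicting taxonomies collapse to their lowest common ancestor; the
    kept id is the lexicographically smallest of the collapsed ids.
    """
    groups: dict[str, list[RefEntry]] = {}
    order: list[str] = []
    for e in db.entries:
        if e.seq not in groups:
            order.append(e.seq)
        groups.setdefault(e.seq, []).append(e)
    entries = []
    for seq in order:
        grp = groups[seq]
        tax = lowest_common_ancestor([e.taxonomy for e in grp])
        entries.append(RefEntry(min(e.id for e in grp), tax, seq))
    return ReferenceDB(entries, db.source)


# --------------------------------------------------------------------------
# Alignment and assignment
# --------------------------------------------------------------------------

def _make_aligner(p: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    aligner.open_gap_score = p.gap_open
    aligner.extend_gap_score = p.gap_extend
    return aligner


def global_align(
    a: str, b: str, p: AlignmentParams = AlignmentParams()
) -> tuple[float, float]:
    """End-to-end affine-gap alignment score and percent identity.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Identity
    is matches divided by alignment columns, in percent.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(p)
    alns = aligner.align(a, b)
    aln = alns[0]  # all co-optimal alignments share the optimal score
    identity = 100.0 * aln.counts().identities / aln.length
    return float(aln.score), identity


def assign_taxonomy(
    otus: Sequence["OTU"],  # noqa: F821 - otu_inference.OTU
    db: ReferenceDB,
    p: AlignmentParams = AlignmentParams(),
    min_identity: Optional[float] = None,
) -> list[Assignment]:
    """Assign each OTU the taxonomy of its best-scoring reference entry.

    Ties on the best alignment score resolve to the lowest common ancestor
    of the tied entries' taxonomies (the reported ref id is the
    lexicographically smallest tied id).  With ``min_identity`` set,
    assignments below that percent identity get an empty taxonomy.
    """
    if not db.entries:
        raise ValueError("empty reference database")
    aligner = _make_aligner(p)
    out: list[Assignment] = []
    for otu in otus:
        best_score = None
        hits: list[tuple[RefEntry, float]] = []
        for entry in db.entries:
            alns = aligner.align(otu.representative, entry.seq)
            aln = alns[0]
            ident = 100.0 * aln.counts().identities / aln.length
            if best_score is None or aln.score > best_score + 1e-9:
                best_score = float(aln.score)
                hits = [(entry, ident)]
            elif abs(aln.score - best_score) <= 1e-9:
                hits.append((entry, ident))
        tax = lowest_common_ancestor([e.taxonomy for e, _ in hits])
        ref = min(e.id for e, _ in hits)
        ident = max(i for _, i in hits)
        if min_identity is not None and ident < min_identity:
            tax = ""
        out.append(Assignment(otu.id, ref, ident, tax))
        otu.taxonomy = tax
    return out


# --------------------------------------------------------------------------
# I/O — reference FASTA with tab-separated taxonomy in the header
# --------------------------------------------------------------------------

def write_reference_fasta(db: ReferenceDB, path) -> None:
    with open(path, "w") as fh:
        for e in db.entries:
            fh.write(f">{e.id}\t{e.taxonomy}\n{e.seq}\n")


def read_reference_fasta(path, source: str = "pmoA") -> ReferenceDB:
    entries: list[RefEntry] = []
    header: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    entries.append(_entry_from(header, chunks))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        entries.append(_entry_from(header, chunks))
    return ReferenceDB(entries, source)


def _entry_from(header: str, chunks: list[str]) -> RefEntry:
    ident, _, tax = header.partition("\t")
    return RefEntry(ident, tax, "".join(chunks).upper())


def write_assignments(assignments: Iterable[Assignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tref_id\tidentity\ttaxonomy\n")
        for a in assignments:
            fh.write(f"{a.otu_id}\t{a.best_ref_id}\t{a.identity:.2f}\t{a.taxonomy}\n")
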