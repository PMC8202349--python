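"""OTU inference for functional-gene and 16S amplicons.

The processing chain mirrors a standard functional-gene pipeline:
dereplication, de novo / reference chimera removal, reading-frame
validation for protein-coding amplicons (pmoA), single-linkage clustering
at edit distance d (swarm, d=1 by default), then OTU-level length and
taxonomy filters.

Frame validation is anchored at the first base of the primer-trimmed
amplicon.  The gene-numbering codon coordinates carried by
:class:`FrameSpec` (e.g. 188-190 for the expected TCG serine start) are
metadata describing where the amplicon sits on the gene; they do not set
the reading frame, which always starts at amplicon position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class Amplicon:
    """A dereplicated sequence with per-sample counts."""

    seq: str
    per_sample_counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.per_sample_counts.values())


@dataclass(frozen=True)
class SwarmParams:
    d: int = 1

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")


@dataclass(frozen=True)
class ChimeraParams:
    min_parent_skew: float = 2.0
    min_improvement: float = 0.05
    mode: str = "denovo"  # or "reference"

    def __post_init__(self) -> None:
        if self.min_parent_skew < 1:
            raise ValueError("min_parent_skew must be >= 1")
        if self.min_improvement < 0:
            raise ValueError("min_improvement must be >= 0")
        if self.mode not in ("denovo", "reference"):
            raise ValueError("mode must be 'denovo' or 'reference'")


@dataclass(frozen=True)
class FrameSpec:
    """Expected structure of a primer-trimmed amplicon class.

    For protein-coding amplicons (``frame_checked``) the trimmed sequence
    must be divisible by three, start with ``required_first_codon``, end
    with one of ``required_last_codons`` and contain no in-frame stop.
    ``gene_start_codon_coords`` / ``gene_end_codon_coords`` record the
    1-based positions of those codons on the full gene.
    """

    name: str
    length_window: tuple[int, int]
    frame_checked: bool = True
    required_first_codon: Optional[str] = None
    required_last_codons: frozenset[str] = frozenset()
    gene_start_codon_coords: Optional[tuple[int, int]] = None
    gene_end_codon_coords: Optional[tuple[int, int]] = None
    stop_codons: frozenset[str] = STOP_CODONS

    def __post_init__(self) -> None:
        lo, hi = self.length_window
        if lo > hi:
            raise ValueError("empty length window")
        if self.frame_checked:
            if self.required_first_codon is None or len(self.required_first_codon) != 3:
                raise ValueError("required_first_codon must be a 3-nt codon")
            if not all(len(c) == 3 for c in self.required_last_codons):
                raise ValueError("last codons must be 3 nt")
            if not any(lo <= n <= hi and n % 3 == 0 for n in range(lo, hi + 1)):
                raise ValueError("length window contains no multiple of 3")


#: pmoA amplicon from the A189F/mb661R primer pair: expected serine start
#: codon at gene positions 188-190 and tyrosine end codon at 658-660.
MB661 = FrameSpec(
    name="mb661", length_window=(465, 474), frame_checked=True,
    required_first_codon="TCG", required_last_codons=frozenset({"TAT"}),
    gene_start_codon_coords=(188, 190), gene_end_codon_coords=(658, 660),
)

#: pmoA amplicon from the A189F/A682R primer pair: serine end codon at 679-681.
A682 = FrameSpec(
    name="A682", length_window=(492, 495), frame_checked=True,
    required_first_codon="TCG", required_last_codons=frozenset({"TCG"}),
    gene_start_codon_coords=(188, 190), gene_end_codon_coords=(679, 681),
)

#: 16S rRNA V3-V4 amplicon: not protein-coding, length filter only.
V3V4 = FrameSpec(name="V3V4", length_window=(370, 435), frame_checked=False)

FRAME_SPECS: dict[str, FrameSpec] = {"mb661": MB661, "A682": A682, "V3V4": V3V4}


@dataclass
class OTU:
    id: str
    representative: str
    members: list[Amplicon]
    taxonomy: str = ""

    @property
    def per_sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.members:
            for s, c in a.per_sample_counts.items():
                counts[s] = counts.get(s, 0) + c
        return counts

    @property
    def total(self) -> int:
        return sum(a.total for a in self.members)


# --------------------------------------------------------------------------
# Dereplication
# --------------------------------------------------------------------------

def dereplicate(reads: Iterable[tuple[str, str]]) -> list[Amplicon]:
    """Collapse identical sequences into amplicons with per-sample counts.

    ``reads`` yields ``(sequence, sample)`` pairs.  The result is ordered
    by decreasing total abundance, ties broken lexicographically by
    sequence.
    """
    table: dict[str, dict[str, int]] = {}
    for seq, sample in reads:
        per = table.setdefault(seq, {})
        per[sample] = per.get(sample, 0) + 1
    amplicons = [Amplicon(seq, per) for seq, per in table.items()]
    amplicons.sort(key=lambda a: (-a.total, a.seq))
    return amplicons


# --------------------------------------------------------------------------
# Chimera detection
# --------------------------------------------------------------------------

def _prefix_suffix_matches(query: str, parent: str) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative left-anchored and right-anchored match counts of query
    vs parent, both indexed 0..len(query) on the query coordinate."""
    lq, lp = len(query), len(parent)
    n = min(lq, lp)
    q = np.frombuffer(query.encode(), dtype="S1")
    p = np.frombuffer(parent.encode(), dtype="S1")
    pre = np.zeros(lq + 1, dtype=np.int64)
    pre[1:n + 1] = np.cumsum(q[:n] == p[:n])
    pre[n + 1:] = pre[n]
    suf = np.zeros(lq + 1, dtype=np.int64)
    suf[1:n + 1] = np.cumsum((q[::-1][:n] == p[::-1][:n]))
    suf[n + 1:] = suf[n]
    return pre, suf


def _chimera_model_identities(
    query: str, parents: Sequence[str]
) -> tuple[float, float]:
    """Best single-parent and best two-parent (single crossover) identity
    of the query under ungapped end-anchored matching.

    Returns ``(best_single, best_two_parent)`` as fractions of query
    length.  The two-parent model is the best split b of the query into a
    prefix matched against one parent and a suffix matched against a
    *different* parent.
    """
    lq = len(query)
    pre = np.empty((len(parents), lq + 1), dtype=np.int64)
    suf = np.empty((len(parents), lq + 1), dtype=np.int64)
    for i, par in enumerate(parents):
        pre[i], suf[i] = _prefix_suffix_matches(query, par)
    best_single = max(float(max(pre[i, lq], suf[i, lq])) for i in range(len(parents))) / lq

    best_two = 0.0
    if len(parents) >= 2:
        for b in range(lq + 1):
            pcol = pre[:, b]
            scol = suf[:, lq - b]
            i1 = int(np.argmax(pcol))
            j1 = int(np.argmax(scol))
            if i1 != j1:
                score = pcol[i1] + scol[j1]
            else:
                p2 = np.partition(pcol, -2)[-2] if len(parents) > 1 else 0
                s2 = np.partition(scol, -2)[-2] if len(parents) > 1 else 0
                score = max(pcol[i1] + s2, p2 + scol[j1])
            best_two = max(best_two, score / lq)
    return best_single, best_two


def detect_chimeras(
    amplicons: Sequence[Amplicon],
    params: ChimeraParams = ChimeraParams(),
    db: Optional["ReferenceDB"] = None,  # noqa: F821 - forward ref to taxonomy_db
) -> set[int]:
    """Flag amplicons explained better by two parents than by one.

    A query is flagged iff a single-crossover combination of two distinct
    candidate parents matches it with identity at least ``min_improvement``
    above the best single-parent identity.  De novo candidates are the
    amplicons with abundance >= ``min_parent_skew`` times the query's (a
    chimera cannot be more abundant than its templates); reference
    candidates are all database entries.

    Returns the set of flagged indices into ``amplicons``.
    """
    if params.mode == "reference":
        if db is None:
            raise ValueError("reference mode requires a database")
        ref_seqs = [e.seq for e in db.entries]
    flagged: set[int] = set()
    for qi, query in enumerate(amplicons):
        if params.mode == "denovo":
            parents = [
                a.seq for i, a in enumerate(amplicons)
                if i != qi and i not in flagged
                and a.total >= params.min_parent_skew * query.total
            ]
        else:
            parents = ref_seqs
        if len(parents) < 2:
            continue
        single, two = _chimera_model_identities(query.seq, parents)
        if two >= single + params.min_improvement:
            flagged.add(qi)
    return flagged


# --------------------------------------------------------------------------
# Swarm clustering
# --------------------------------------------------------------------------

def _edit_distance_at_most(a: str, b: str, d: int) -> bool:
    if abs(len(a) - len(b)) > d:
        return False
    res = edlib.align(a, b, mode="NW", task="distance", k=d)
    return res["editDistance"] != -1


def cluster_swarm(
    amplicons: Sequence[Amplicon], params: SwarmParams = SwarmParams()
) -> list[OTU]:
    """Single-linkage clustering at Levenshtein distance <= d.

    OTUs are grown iteratively: the most abundant unclustered amplicon
    seeds a cluster, which absorbs every unclustered amplicon within
    distance d of any current member, until closure.  The representative
    is the most abundant member (ties to the lexicographically smallest
    sequence).  The resulting partition equals the connected components of
    the distance-<=d graph.
    """
    order = sorted(range(len(amplicons)), key=lambda i: (-amplicons[i].total, amplicons[i].seq))
    unclustered = set(order)
    otus: list[OTU] = []
    for seed in order:
        if seed not in unclustered:
            continue
        unclustered.discard(seed)
        members = [seed]
        frontier = [seed]
        while frontier:
            nxt: list[int] = []
            for m in frontier:
                hits = [j for j in unclustered
                        if _edit_distance_at_most(amplicons[m].seq, amplicons[j].seq, params.d)]
                for j in hits:
                    unclustered.discard(j)
                    nxt.append(j)
            members.extend(nxt)
            frontier = nxt
        member_amps = [amplicons[i] for i in members]
        rep = min(member_amps, key=lambda a: (-a.total, a.seq)).seq
        otus.append(OTU(id=f"OTU_{len(otus) + 1}", representative=rep, members=member_amps))
    return otus


# --------------------------------------------------------------------------
# Frame validation and OTU filters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameCheck:
    passed: bool
    reason: str = ""


def validate_reading_frame(seq: str, spec: FrameSpec) -> FrameCheck:
    """Check a primer-trimmed protein-coding amplicon for an intact ORF.

    Pass requires: only A/C/G/T symbols, length divisible by three, the
    expected first codon, a final codon from the expected set, and no
    in-frame stop codon.  The reason names the first violated rule.
    """
    if not spec.frame_checked:
        raise ValueError(f"frame validation not applicable to {spec.name}")
    if any(b not in "ACGT" for b in seq):
        return FrameCheck(False, "ambiguous")
    if len(seq) % 3 != 0:
        return FrameCheck(False, "not divisible by three")
    if seq[:3] != spec.required_first_codon:
        return FrameCheck(False, "first codon")
    if seq[-3:] not in spec.required_last_codons:
        return FrameCheck(False, "last codon")
    for i in range(0, len(seq) - 3, 3):
        if seq[i:i + 3] in spec.stop_codons:
            return FrameCheck(False, "stop codon")
    return FrameCheck(True)


def filter_otus(otus: Sequence[OTU], spec: FrameSpec) -> list[OTU]:
    """Retain OTUs whose representative length is inside the closed length
    window and whose taxonomy mentions none of Archaea, chloroplast or
    mitochondria (case-insensitive)."""
    lo, hi = spec.length_window
    banned = ("archaea", "chloroplast", "mitochondria")
    kept = []
    for otu in otus:
        if not lo <= len(otu.representative) <= hi:
            continue
        tax = otu.taxonomy.lower()
        if any(b in tax for b in banned):
            continue
        kept.append(otu)
    return kept


# --------------------------------------------------------------------------
# OTU table
# --------------------------------------------------------------------------

def build_otu_table(otus: Sequence[OTU], samples: Sequence[str]) -> pd.DataFrame:
    """Samples x OTUs count matrix (rows = samples, columns = OTU ids)."""
    data = np.zeros((len(samples), len(otus)), dtype=np.int64)
    sample_idx = {s: i for i, s in enumerate(samples)}
    for j, otu in enumerate(otus):
        for s, c in otu.per_sample_counts.items():
            if s in sample_idx:
                data[sample_idx[s], j] = c
    return pd.DataFrame(data, index=list(samples), columns=[o.id for o in otus])


def write_otu_table(table: pd.DataFrame, otus: Sequence[OTU], path) -> None:
    """TSV with one row per OTU: id, per-sample counts, taxonomy."""
    out = table.T.copy()
    out.insert(len(out.columns), "taxonomy", [o.taxonomy for o in otus])
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def write_representatives_fasta(otus: Sequence[OTU], path) -> None:
    with open(path, "w") as fh:
        for otu in otus:
            fh.write(f">{otu.id};size={otu.total}\n{otu.representative}\n")
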