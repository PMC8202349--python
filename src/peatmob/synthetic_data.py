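"""Synthetic inputs with known ground truth for the whole pipeline.

Every upstream artifact the pipeline consumes can be generated here with
a seed: a curated-collection-like reference database of frame-valid
pmoA-style amplicons, community count matrices with planted treatment
bioindicators, paired MiSeq-like reads carrying substitutions, chimeras
and single-nucleotide frameshifts (with a per-read truth table), and
closed-vial gas time series with a known consumption rate.

The generators emulate the study conditions: two sites x two treatments
(grazed / exclosed) x seasonal sampling dates, MiSeq paired reads that
begin at the amplification primers, and microcosms consuming CH4
linearly.  They do not model PCR bias, quality miscalibration, or
indel-rich error processes beyond single frameshifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gas_physics import CELSIUS_OFFSET, GasConstants, GasTimeSeries, MicrocosmSpec
from .otu_inference import MB661, STOP_CODONS, FrameSpec
from .read_processing import IUPAC_SETS, QualityRead, reverse_complement
from .taxonomy_db import RefEntry, ReferenceDB

_BASES = np.array(list("ACGT"))

#: pmoA amplification primers used throughout the defaults.
A189F = "GGNGACTGGGACTTCTGG"
MB661R = "CCGGMGCAACGTCYTTACC"

_GENUS_POOL = [
    "Methylobacter", "Methylomonas", "Methylosarcina", "Methylomicrobium",
    "Methylococcus", "Methylovulum", "Methylosoma", "Methyloglobulus",
]


def _concrete_primer(iupac: str, rng: np.random.Generator) -> str:
    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC_SETS[b])) for b in iupac
    )


# --------------------------------------------------------------------------
# Reference database
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticRefSpec:
    n_genera: int = 6
    n_per_genus: int = 3
    amplicon_frame: FrameSpec = MB661
    within_genus_divergence: float = 0.02  # substitutions per site
    fwd_primer: str = A189F
    rev_primer: str = MB661R
    flank: int = 40  # nt of random sequence outside each primer site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1 or self.n_per_genus < 1:
            raise ValueError("need >= 1 genus and >= 1 entry per genus")
        if not 0.0 <= self.within_genus_divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")


def _random_orf(spec: FrameSpec, rng: np.random.Generator) -> str:
    """A frame-valid amplicon: correct first/last codon, length a multiple
    of 3 inside the window, no in-frame stop codon."""
    lo, hi = spec.length_window
    lengths = [n for n in range(lo, hi + 1) if n % 3 == 0]
    if spec.frame_checked and not lengths:
        raise ValueError(f"length window {spec.length_window} has no multiple of 3")
    if not spec.frame_checked:
        n = int(rng.integers(lo, hi + 1))
        return "".join(rng.choice(_BASES, size=n))
    n = int(rng.choice(lengths))
    last = sorted(spec.required_last_codons)[int(rng.integers(len(spec.required_last_codons)))]
    codons = [spec.required_first_codon]
    for _ in range(n // 3 - 2):
        while True:
            c = "".join(rng.choice(_BASES, size=3))
            if c not in spec.stop_codons:
                codons.append(c)
                break
    codons.append(last)
    return "".join(codons)


def _diverge(seq: str, rate: float, spec: FrameSpec, rng: np.random.Generator) -> str:
    """Substitute sites at the given per-site rate without breaking the
    frame: anchor codons are left intact and substitutions creating an
    in-frame stop are re-drawn at codon level."""
    if rate <= 0:
        return seq
    s = list(seq)
    protected = set(range(3)) | set(range(len(seq) - 3, len(seq))) if spec.frame_checked else set()
    for i in range(len(s)):
        if i in protected or rng.random() >= rate:
            continue
        old = s[i]
        choices = [b for b in "ACGT" if b != old]
        for _ in range(8):
            b = choices[int(rng.integers(3))]
            s[i] = b
            if not spec.frame_checked:
                break
            cstart = (i // 3) * 3
            if "".join(s[cstart:cstart + 3]) not in spec.stop_codons:
                break
            s[i] = old
    return "".join(s)


def make_reference_db(
    spec: SyntheticRefSpec = SyntheticRefSpec(),
) -> tuple[ReferenceDB, list[RefEntry]]:
    """Generate a trimmed reference database plus full-length gene records.

    Returns ``(db, full_records)``: ``db`` holds the primer-trimmed,
    frame-valid amplicon of each entry with a hierarchical taxonomy path
    (domain;class;order;genus;strain); ``full_records`` carry the same
    entries embedded in flanking sequence with concrete primer sites, for
    exercising database trimming.  Identical spec and seed give identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    entries: list[RefEntry] = []
    full: list[RefEntry] = []
    for g in range(spec.n_genera):
        genus = (_GENUS_POOL[g] if g < len(_GENUS_POOL) else f"Methylogenus{g + 1}")
        base = _random_orf(spec.amplicon_frame, rng)
        for s in range(spec.n_per_genus):
            amplicon = base if s == 0 else _diverge(
                base, spec.within_genus_divergence, spec.amplicon_frame, rng)
            tax = (f"Bacteria;Gammaproteobacteria;Methylococcales;"
                   f"{genus};{genus}_strain_{s + 1}")
            rid = f"ref_{g + 1}_{s + 1}"
            entries.append(RefEntry(rid, tax, amplicon))
            up = "".join(rng.choice(_BASES, size=spec.flank))
            down = "".join(rng.choice(_BASES, size=spec.flank))
            gene = (up + _concrete_primer(spec.fwd_primer, rng) + amplicon
                    + reverse_complement(_concrete_primer(spec.rev_primer, rng)) + down)
            full.append(RefEntry(rid, tax, gene))
    return ReferenceDB(entries, source="pmoA"), full


# --------------------------------------------------------------------------
# Community counts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedIndicator:
    otu_index: int
    favored_treatment: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 1.0:
            raise ValueError("fold_change must be > 1")


@dataclass(frozen=True)
class CommunityDesign:
    """Crossed sampling design with planted treatment effects.

    Emulates the field layout: two sites, grazed vs exclosed treatment,
    seasonal sampling dates, with per-cell replication.  Baseline OTU
    abundances are log-normal; planted bioindicators have their expected
    abundance multiplied by ``fold_change`` in the favored treatment only.
    """

    sites: tuple[str, ...] = ("SV1", "SV2")
    treatments: tuple[str, ...] = ("grazed", "exclosed")
    dates: tuple[str, ...] = ("summer2015", "spring2016", "summer2016")
    replicates_per_cell: int = 2
    n_background_otus: int = 40
    planted_bioindicators: tuple[PlantedIndicator, ...] = ()
    sequencing_depth: int = 10_000
    overdispersion: float = 0.3    # sd of per-sample log-normal abundance jitter
    lognormal_sigma: float = 1.0   # spread of baseline abundances
    ch4_rate_means: dict[str, float] = field(
        default_factory=lambda: {"grazed": 200.0, "exclosed": 60.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 0 or self.sequencing_depth <= 0:
            raise ValueError("invalid replication or depth")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        n = self.n_otus
        for pl in self.planted_bioindicators:
            if not 0 <= pl.otu_index < n:
                raise ValueError(f"planted OTU index {pl.otu_index} out of range")
            if pl.favored_treatment not in self.treatments:
                raise ValueError(f"unknown treatment {pl.favored_treatment}")

    @property
    def n_otus(self) -> int:
        return self.n_background_otus + len(self.planted_bioindicators)


def simulate_community_counts(
    design: CommunityDesign = CommunityDesign(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample OTU counts and the matching sample metadata.

    Returns ``(counts, metadata)``.  ``counts`` is samples x OTUs with
    every row summing to ``sequencing_depth``; planted OTU columns are
    named ``planted_<i>`` and background columns ``otu_<i>``.
    ``metadata`` carries sample, site, treatment, date and a synthetic
    ch4_rate covariate whose mean depends on treatment.
    """
    rng = np.random.default_rng(design.seed)
    n_otus = design.n_otus
    base = rng.lognormal(mean=0.0, sigma=design.lognormal_sigma, size=n_otus)
    planted_idx = {pl.otu_index: pl for pl in design.planted_bioindicators}
    # planted indicators start from the background mean abundance, so their
    # detectability reflects the planted fold change rather than the luck of
    # the log-normal draw (an extreme draw would also shift every background
    # OTU's relative abundance between treatments)
    for i in planted_idx:
        base[i] = float(np.exp(0.5 * design.lognormal_sigma ** 2))

    names = []
    for i in range(n_otus):
        names.append(f"planted_{i}" if i in planted_idx else f"otu_{i}")

    rows, meta = [], []
    for site in design.sites:
        for treatment in design.treatments:
            for date in design.dates:
                for rep in range(design.replicates_per_cell):
                    expected = base.copy()
                    for i, pl in planted_idx.items():
                        if treatment == pl.favored_treatment:
                            expected[i] *= pl.fold_change
                    if design.overdispersion > 0:
                        expected = expected * rng.lognormal(
                            0.0, design.overdispersion, size=n_otus)
                    probs = expected / expected.sum()
                    counts = rng.multinomial(design.sequencing_depth, probs)
                    sample = f"{site}_{treatment}_{date}_r{rep + 1}"
                    rows.append(counts)
                    mu = design.ch4_rate_means.get(treatment, 100.0)
                    meta.append({
                        "sample": sample, "site": site, "treatment": treatment,
                        "date": date,
                        "ch4_rate": float(rng.normal(mu, 0.15 * mu)),
                    })
    samples = [m["sample"] for m in meta]
    counts_df = pd.DataFrame(np.array(rows).reshape(len(rows), n_otus) if rows
                             else np.empty((0, n_otus), dtype=np.int64),
                             index=samples, columns=names, dtype=np.int64)
    meta_df = pd.DataFrame(meta).set_index("sample") if meta else pd.DataFrame(
        columns=["site", "treatment", "date", "ch4_rate"])
    return counts_df, meta_df


# --------------------------------------------------------------------------
# Paired-read simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 300
    target_overlap: int = 20
    substitution_rate: float = 0.0
    quality_profile: Optional[Sequence[float]] = None  # per-position mean phred
    quality_jitter_sd: float = 3.0
    chimera_rate: float = 0.0
    frameshift_rate: float = 0.0
    forward_primer: str = A189F
    reverse_primer: str = MB661R
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.chimera_rate, self.frameshift_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not self.read_length > self.target_overlap > 0:
            raise ValueError("need read_length > target_overlap > 0")

    def mean_phred(self) -> np.ndarray:
        """MiSeq-like profile: high and flat, decaying over the last 60 nt."""
        if self.quality_profile is not None:
            prof = np.asarray(self.quality_profile, dtype=float)
            if prof.size < self.read_length:
                raise ValueError("quality profile shorter than read length")
            return prof[: self.read_length]
        pos = np.arange(self.read_length)
        prof = np.full(self.read_length, 37.0)
        tail = pos > self.read_length - 60
        prof[tail] -= (pos[tail] - (self.read_length - 60)) * 0.15
        return prof


def _qualities(n: int, params: ReadSimParams, rng: np.random.Generator) -> np.ndarray:
    q = params.mean_phred()[:n] + rng.normal(0.0, params.quality_jitter_sd, size=n)
    return np.clip(np.rint(q), 2, 40).astype(int)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def simulate_paired_reads(
    counts: pd.DataFrame,
    db: ReferenceDB,
    params: ReadSimParams = ReadSimParams(),
) -> tuple[dict[str, list[tuple[QualityRead, QualityRead]]], pd.DataFrame]:
    """Simulate primer-carrying paired reads from per-sample counts.

    ``counts`` columns must correspond positionally to ``db.entries``.
    Each fragment is forward primer + amplicon + reverse-complemented
    reverse primer; mates are the two fragment ends read inward, so they
    overlap by at least ``target_overlap`` (shorter fragments raise a
    configuration error).  A fraction of fragments are two-parent
    single-crossover chimeras; an independent fraction carry a 1-nt indel
    (frameshift).  Per-base substitutions are applied to each mate.

    Returns ``(reads_by_sample, truth)`` where ``truth`` has one row per
    pair: read_id, sample, ref_id, ref_id2 (chimeras), artifact in
    {none, chimera, frameshift}.
    """
    if counts.shape[1] != len(db.entries):
        raise ValueError("counts columns must correspond to database entries")
    rng = np.random.default_rng(params.seed)
    reads: dict[str, list[tuple[QualityRead, QualityRead]]] = {}
    truth_rows = []
    rl = params.read_length
    for sample in counts.index:
        sample_counts = counts.loc[sample].to_numpy()
        pool = np.repeat(np.arange(len(db.entries)), sample_counts)
        weights = sample_counts / sample_counts.sum() if sample_counts.sum() else None
        pairs: list[tuple[QualityRead, QualityRead]] = []
        for k, ref_i in enumerate(pool):
            entry = db.entries[ref_i]
            amplicon = entry.seq
            artifact, ref2 = "none", ""
            u = rng.random()
            if u < params.chimera_rate and len(db.entries) > 1:
                others = [i for i in range(len(db.entries))
                          if i != ref_i and sample_counts[i] > 0]
                if others:
                    w = sample_counts[others] / sample_counts[others].sum()
                    ref_j = int(rng.choice(others, p=w))
                    other = db.entries[ref_j].seq
                    # breakpoint in the central 80%: a crossover in the outer
                    # tenth leaves a sequence essentially identical to one
                    # parent, i.e. not a meaningful chimera
                    L = min(len(amplicon), len(other))
                    lo, hi = max(1, int(0.1 * L)), max(2, int(0.9 * L))
                    bp = int(rng.integers(lo, hi))
                    amplicon = amplicon[:bp] + other[bp:]
                    artifact, ref2 = "chimera", db.entries[ref_j].id
            elif u < params.chimera_rate + params.frameshift_rate:
                pos = int(rng.integers(1, len(amplicon) - 1))
                if rng.random() < 0.5:
                    amplicon = amplicon[:pos] + amplicon[pos + 1:]   # deletion
                else:
                    ins = str(rng.choice(_BASES))
                    amplicon = amplicon[:pos] + ins + amplicon[pos:]  # insertion
                artifact = "frameshift"
            fwd = _concrete_primer(params.forward_primer, rng)
            rev = _concrete_primer(params.reverse_primer, rng)
            fragment = fwd + amplicon + reverse_complement(rev)
            if rl > len(fragment):
                raise ValueError("read_length exceeds fragment length")
            if 2 * rl - len(fragment) < params.target_overlap:
                raise ValueError(
                    f"fragment of {len(fragment)} nt cannot give "
                    f"{params.target_overlap} nt of mate overlap at read length {rl}"
                )
            r1_seq = _mutate(fragment[:rl], params.substitution_rate, rng)
            r2_seq = _mutate(reverse_complement(fragment[-rl:]),
                             params.substitution_rate, rng)
            rid = f"{sample}_read{k + 1}"
            r1 = QualityRead(rid, r1_seq, _qualities(rl, params, rng))
            r2 = QualityRead(rid, r2_seq, _qualities(rl, params, rng))
            pairs.append((r1, r2))
            truth_rows.append({
                "read_id": rid, "sample": sample, "ref_id": entry.id,
                "ref_id2": ref2, "artifact": artifact,
            })
        reads[sample] = pairs
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample", "ref_id", "ref_id2", "artifact"])
    return reads, truth


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Gas time series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GasSimParams:
    """Linear CH4 consumption in a closed microcosm.

    The default timepoints are an initial measurement right after
    injection and four subsequent points at regular intervals within 45 h.
    """

    initial_mass: float = 660.0       # ug CH4
    consumption_rate: float = 6.0     # ug per hour
    timepoints: tuple[float, ...] = (0.0, 11.0, 22.0, 33.0, 44.0)  # hours
    noise_sd: float = 0.0             # ug
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints)
        if t.size < 2 or not (np.diff(t) > 0).all():
            raise ValueError("timepoints must be strictly increasing, >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_gas_series(
    params: GasSimParams = GasSimParams(),
    m: MicrocosmSpec = MicrocosmSpec(),
    c: GasConstants = GasConstants(),
) -> GasTimeSeries:
    """Headspace fractions for mass(t) = initial - rate * t + noise, clipped at 0."""
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.timepoints, dtype=float)
    mass = params.initial_mass - params.consumption_rate * t
    if params.noise_sd > 0:
        mass = mass + rng.normal(0.0, params.noise_sd, size=t.size)
    mass = np.clip(mass, 0.0, None)
    # invert the ideal gas law: fraction = m R T / (M 1e6 p V)
    v_l = m.headspace_volume_ml / 1000.0
    t_k = m.measurement_temp + CELSIUS_OFFSET
    frac = mass * c.R * t_k / (c.M_CH4 * 1e6 * m.pressure * v_l)
    return GasTimeSeries(timepoints=t, ch4_fraction=frac)
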