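"""Generators: determinism, planted ground truth, and pipeline recovery."""

import numpy as np
import pandas as pd
import pytest

from peatmob.otu_inference import (
    MB661,
    FrameSpec,
    cluster_swarm,
    dereplicate,
    detect_chimeras,
    validate_reading_frame,
)
from peatmob.read_processing import PrimerSpec, merge_pair, process_read_pairs, trim_primers
from peatmob.synthetic_data import (
    A189F,
    MB661R,
    CommunityDesign,
    GasSimParams,
    PlantedIndicator,
    ReadSimParams,
    SyntheticRefSpec,
    make_reference_db,
    simulate_community_counts,
    simulate_gas_series,
    simulate_paired_reads,
)
from peatmob.taxonomy_db import dereplicate_database

FWD = PrimerSpec("A189F", A189F, 0, "five-prime")
REV = PrimerSpec("mb661R", MB661R, 0, "three-prime")


def processed_sequences(reads):
    """Run merge + trim per sample, return {read_id: trimmed seq} and labels."""
    by_read, labeled = {}, []
    for sample, pairs in reads.items():
        result = process_read_pairs(pairs, FWD, REV)
        for q in result.kept:
            by_read[q.id] = q.seq
            labeled.append((q.seq, sample))
    return by_read, labeled


class TestReferenceDB:
    def test_entry_count_and_frame_validity(self):
        db, full = make_reference_db(SyntheticRefSpec(n_genera=3, n_per_genus=2, seed=7))
        assert len(db.entries) == 6 and len(full) == 6
        for e in db.entries:
            assert validate_reading_frame(e.seq, MB661).passed
            assert len(e.taxonomy.split(";")) == 5

    def test_seed_determinism_byte_identical(self):
        spec = SyntheticRefSpec(n_genera=3, n_per_genus=2, seed=7)
        db1, full1 = make_reference_db(spec)
        db2, full2 = make_reference_db(spec)
        assert [(e.id, e.taxonomy, e.seq) for e in db1.entries] == \
            [(e.id, e.taxonomy, e.seq) for e in db2.entries]
        assert [e.seq for e in full1] == [e.seq for e in full2]

    def test_zero_divergence_collapses_per_genus(self):
        db, _ = make_reference_db(
            SyntheticRefSpec(n_genera=4, n_per_genus=3, within_genus_divergence=0.0, seed=1))
        derep = dereplicate_database(db)
        assert len(derep) == 4
        # brute-force distinct-sequence count agrees
        assert len({e.seq for e in db.entries}) == 4

    def test_impossible_frame_window_rejected(self):
        with pytest.raises(ValueError):
            FrameSpec(name="bad", length_window=(466, 467), frame_checked=True,
                      required_first_codon="TCG",
                      required_last_codons=frozenset({"TAT"}))


class TestCommunityCounts:
    def test_row_sums_equal_depth(self):
        counts, meta = simulate_community_counts(CommunityDesign(seed=2))
        assert (counts.sum(axis=1) == 10_000).all()
        assert list(meta.index) == list(counts.index)

    def test_zero_replicates_empty_matrix(self):
        counts, meta = simulate_community_counts(CommunityDesign(replicates_per_cell=0))
        assert counts.shape[0] == 0

    def test_planted_fold_change_raises_favored_mean(self):
        design = CommunityDesign(
            replicates_per_cell=4,
            planted_bioindicators=(PlantedIndicator(0, "grazed", 8.0),), seed=3)
        counts, meta = simulate_community_counts(design)
        rel = counts.div(counts.sum(axis=1), axis=0)
        grazed = rel.loc[meta["treatment"] == "grazed", "planted_0"].mean()
        excl = rel.loc[meta["treatment"] == "exclosed", "planted_0"].mean()
        assert grazed > 3 * excl

    def test_invalid_planted_index_rejected(self):
        with pytest.raises(ValueError):
            CommunityDesign(n_background_otus=2,
                            planted_bioindicators=(PlantedIndicator(5, "grazed", 8.0),))

    def test_seed_determinism(self):
        d = CommunityDesign(seed=9)
        c1, m1 = simulate_community_counts(d)
        c2, m2 = simulate_community_counts(d)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(m1, m2)


class TestPairedReads:
    def _counts(self, db, rng, n=40):
        return pd.DataFrame(rng.integers(5, n, size=(2, len(db.entries))),
                            index=["s1", "s2"], columns=[e.id for e in db.entries])

    def test_count_conservation_with_truth_table(self, rng):
        db, _ = make_reference_db(SyntheticRefSpec(n_genera=3, n_per_genus=1, seed=4))
        counts = self._counts(db, rng)
        reads, truth = simulate_paired_reads(counts, db, ReadSimParams(seed=5))
        assert len(truth) == counts.values.sum()
        assert sum(len(v) for v in reads.values()) == counts.values.sum()

    def test_clean_reads_round_trip_to_exact_amplicons(self, rng):
        db, _ = make_reference_db(SyntheticRefSpec(n_genera=4, n_per_genus=1, seed=6))
        counts = self._counts(db, rng)
        reads, truth = simulate_paired_reads(counts, db, ReadSimParams(seed=7))
        by_read, labeled = processed_sequences(reads)
        assert len(by_read) == len(truth)  # nothing rejected without noise
        amps = dereplicate(labeled)
        assert {a.seq for a in amps} == {e.seq for e in db.entries}
        otus = cluster_swarm(amps)
        assert {o.representative for o in otus} == {e.seq for e in db.entries}
        # per-entry totals survive exactly
        for e, col in zip(db.entries, counts.columns):
            amp = next(a for a in amps if a.seq == e.seq)
            assert amp.total == counts[col].sum()

    def test_frameshift_fraction_fails_frame_validation(self, rng):
        db, _ = make_reference_db(SyntheticRefSpec(n_genera=3, n_per_genus=1, seed=8))
        counts = self._counts(db, rng, n=80)
        reads, truth = simulate_paired_reads(
            counts, db, ReadSimParams(frameshift_rate=0.1, seed=9))
        by_read, _ = processed_sequences(reads)
        truth = truth.set_index("read_id")
        failed = {rid for rid, seq in by_read.items()
                  if not validate_reading_frame(seq, MB661).passed}
        planted = set(truth[truth["artifact"] == "frameshift"].index)
        assert failed == planted  # every 1-nt indel breaks the frame; no others
        frac = len(planted) / len(truth)
        assert 0.05 < frac < 0.15  # ~10% planted

    def test_chimeras_flagged_clean_reads_not(self, rng):
        db, _ = make_reference_db(SyntheticRefSpec(n_genera=5, n_per_genus=1, seed=10))
        counts = self._counts(db, rng, n=60)
        reads, truth = simulate_paired_reads(
            counts, db, ReadSimParams(chimera_rate=0.05, seed=11))
        by_read, labeled = processed_sequences(reads)
        amps = dereplicate(labeled)
        flagged_seqs = {amps[i].seq for i in detect_chimeras(amps)}
        truth = truth.set_index("read_id")
        chimeric = truth["artifact"] == "chimera"
        caught = sum(by_read[r] in flagged_seqs for r in truth[chimeric].index)
        clean_flagged = sum(by_read[r] in flagged_seqs for r in truth[~chimeric].index)
        assert clean_flagged == 0
        assert caught >= 0.8 * chimeric.sum()

    def test_read_length_exceeding_fragment_errors(self, rng):
        db, _ = make_reference_db(SyntheticRefSpec(n_genera=2, n_per_genus=1, seed=12))
        counts = self._counts(db, rng)
        with pytest.raises(ValueError):
            simulate_paired_reads(counts, db, ReadSimParams(read_length=600,
                                                            target_overlap=20))

    def test_insufficient_overlap_errors(self, rng):
        db, _ = make_reference_db(SyntheticRefSpec(n_genera=2, n_per_genus=1, seed=12))
        counts = self._counts(db, rng)
        with pytest.raises(ValueError, match="overlap"):
            simulate_paired_reads(counts, db, ReadSimParams(read_length=230,
                                                            target_overlap=40))

    def test_seed_determinism(self, rng):
        db, _ = make_reference_db(SyntheticRefSpec(n_genera=2, n_per_genus=1, seed=13))
        counts = self._counts(db, rng)
        r1, t1 = simulate_paired_reads(counts, db, ReadSimParams(seed=14))
        r2, t2 = simulate_paired_reads(counts, db, ReadSimParams(seed=14))
        pd.testing.assert_frame_equal(t1, t2)
        for s in r1:
            assert [(a.seq, b.seq, a.quals, b.quals) for a, b in r1[s]] == \
                [(a.seq, b.seq, a.quals, b.quals) for a, b in r2[s]]


class TestGasSeries:
    def test_noiseless_linear_masses(self):
        series = simulate_gas_series(GasSimParams(noise_sd=0.0))
        assert len(series.timepoints) == 5
        d = np.diff(series.ch4_fraction)
        assert np.allclose(d, d[0])  # linear decay

    def test_clipped_at_zero(self):
        params = GasSimParams(initial_mass=50.0, consumption_rate=6.0,
                              timepoints=(0.0, 5.0, 10.0, 20.0), noise_sd=0.0)
        series = simulate_gas_series(params)
        assert series.ch4_fraction[-1] == 0.0

    def test_invalid_timepoints(self):
        with pytest.raises(ValueError):
            GasSimParams(timepoints=(0.0, 2.0, 1.0))
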