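"""Mapping, filtering, folding, duplex evaluation and the locus caller."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wheatmir.config import PipelineConfig
from wheatmir.discovery import (DuplexRejection, GenomeHit, call_mirna_loci,
                                compute_read_dominance, evaluate_duplex,
                                extract_candidate_windows, filter_tags,
                                fold_rna, map_tags_exact, pair_table)
from wheatmir.preprocess import ReadTag
from wheatmir.seqio import revcomp
from wheatmir import synthetic


def brute_force_hits(tag, genome):
    """Independent sliding-window scan of both strands."""
    out = []
    rc = revcomp(tag)
    for seq_id in sorted(genome):
        chrom = genome[seq_id]
        for i in range(len(chrom) - len(tag) + 1):
            if chrom[i:i + len(tag)] == tag:
                out.append((seq_id, i, "+"))
            if chrom[i:i + len(tag)] == rc:
                out.append((seq_id, i, "-"))
    return sorted(out)


class TestMapping:
    def test_known_occurrences_both_strands(self):
        genome = {"g": "AAGGTTCCAAGG"}
        hits = map_tags_exact(["AAGG"], genome)["AAGG"]
        assert [(h.start, h.strand) for h in hits if h.strand == "+"] == \
            [(0, "+"), (8, "+")]
        # the reverse complement CCTT occurs nowhere in this genome
        assert not [h for h in hits if h.strand == "-"]

    def test_absent_tag_has_zero_hits(self):
        assert map_tags_exact(["ACGTACGT"], {"g": "A" * 50})["ACGTACGT"] == []

    def test_single_mismatch_is_not_a_hit(self):
        genome = {"g": "TTTTTGGAGCTCCCTTCATTCCAATTTTT"}
        tag = "TGGAGCTCCCTTCATTCCAAT"
        variant = "AGGAGCTCCCTTCATTCCAAT"
        hits = map_tags_exact([tag, variant], genome)
        assert len(hits[tag]) == 1 and hits[variant] == []

    def test_matches_brute_force_scan(self, rng):
        genome = {"c1": "".join("ACGT"[i] for i in rng.integers(0, 4, 300)),
                  "c2": "".join("ACGT"[i] for i in rng.integers(0, 4, 200))}
        tags = [genome["c1"][37:58], revcomp(genome["c2"][100:121]), "ACGT" * 5]
        hits = map_tags_exact(tags, genome)
        for tag in tags:
            got = sorted((h.seq_id, h.start, h.strand) for h in hits[tag])
            assert got == brute_force_hits(tag, genome)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            map_tags_exact(["ACGN"], {"g": "ACGT"})


class TestFiltering:
    def _tag(self, seq):
        return ReadTag(sequence=seq, counts={"L": 30})

    def test_high_copy_threshold_is_strict(self, config):
        unit = "GCTAGCTAGGATCCGGTACCAA"[:21]
        tag = self._tag(unit)
        hits_501 = {unit: [GenomeHit("g", i, i + 21, "+") for i in range(501)]}
        hits_500 = {unit: [GenomeHit("g", i, i + 21, "+") for i in range(500)]}
        _, dropped = filter_tags([tag], hits_501, None, config)
        assert dropped == {unit: "high_copy"}
        kept, dropped = filter_tags([tag], hits_500, None, config)
        assert kept and not dropped

    def test_decoy_substring_dropped(self, config, rng):
        decoy = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        tag = self._tag(decoy[40:61])
        rc_tag = self._tag(revcomp(decoy[10:31]))
        other = self._tag("GCTAGCTAGGATCCGGTACCA")
        hits = {t.sequence: [GenomeHit("g", 0, 21, "+")]
                for t in (tag, rc_tag, other)}
        kept, dropped = filter_tags([tag, rc_tag, other], hits, [decoy], config)
        assert dropped == {tag.sequence: "annotated", rc_tag.sequence: "annotated"}
        assert [t.sequence for t in kept] == [other.sequence]


class TestWindows:
    def test_window_arithmetic(self, config):
        genome = {"g": "A" * 5000}
        hit = GenomeHit("g", 1000, 1021, "+")
        w = extract_candidate_windows(hit, genome, config)[1]   # flank 100
        assert (w.genome_start, w.genome_end) == (900, 1121)
        assert w.mature_offset == 100

    def test_window_clipped_at_sequence_start(self, config):
        genome = {"g": "A" * 5000}
        hit = GenomeHit("g", 10, 31, "+")
        w = extract_candidate_windows(hit, genome, config)[1]
        assert (w.genome_start, w.genome_end) == (0, 131)
        assert w.mature_offset == 10

    def test_minus_strand_window_contains_mature_verbatim(self, config, rng):
        chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        genome = {"g": chrom}
        tag = revcomp(chrom[300:321])
        hit = GenomeHit("g", 300, 321, "-")
        for w in extract_candidate_windows(hit, genome, config):
            assert w.sequence[w.mature_offset:w.mature_offset + 21] == tag


def enumerate_max_pairs(seq, min_loop=3):
    """Exhaustive maximum base-pair count over nested structures (tiny n)."""
    from functools import lru_cache
    from wheatmir.discovery import can_pair

    @lru_cache(maxsize=None)
    def best(i, j):
        if j - i <= min_loop:
            return 0
        score = best(i, j - 1)
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j]):
                left = best(i, k - 1) if k > i else 0
                score = max(score, left + best(k + 1, j - 1) + 1)
        return score

    return best(0, len(seq) - 1)


class TestFolding:
    def test_unpairable_sequence_is_unpaired(self):
        assert fold_rna("AAAAAAA", engine="nussinov")[0] == "......."

    def test_simple_stem(self):
        struct, energy = fold_rna("GGGGAAAACCCC", engine="nussinov")
        assert struct == "((((....))))"
        assert energy == -4.0

    @given(st.text(alphabet="ACGU", min_size=5, max_size=24))
    def test_nussinov_structure_valid_and_optimal(self, seq):
        struct, energy = fold_rna(seq, engine="nussinov")
        pt = pair_table(struct)             # raises if unbalanced
        assert len(struct) == len(seq)
        n_pairs = struct.count("(")
        assert -energy == n_pairs == enumerate_max_pairs(
            seq.replace("U", "T"))
        # minimum hairpin loop of 3 nt
        for i in range(1, len(pt)):
            if pt[i] > i:
                assert pt[i] - i > 3

    def test_vienna_engine_balanced(self):
        struct, energy = fold_rna("GGGGGGAAAAAACCCCCC", engine="vienna")
        pair_table(struct)
        assert len(struct) == 18

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            fold_rna("ACGX")


class TestDuplex:
    def test_star_span_follows_overhang_geometry(self):
        # perfect 6-bp stem with the mature filling the 5' arm: the star
        # span is [partner(mature_end-2), partner(mature_start)+2]
        struct = "((((((......)))))).."
        star, stats = evaluate_duplex(struct, (1, 6))
        assert star == (15, 20)
        assert stats.mismatches == 0 and stats.bulge_events == 0
        # a fully paired mature has no 3' overhang (blunt duplex)
        assert stats.overhang_3p == 0

    def test_fully_unpaired_mature_rejected(self):
        with pytest.raises(DuplexRejection) as exc:
            evaluate_duplex("......((((....))))..", (1, 6))
        assert exc.value.reason == "no_hairpin"

    def test_mature_spanning_loop_rejected(self):
        with pytest.raises(DuplexRejection):
            evaluate_duplex("((((((......))))))..", (4, 15))

    def test_planted_canonical_duplex_yields_2nt_overhang(self, rng):
        spec = synthetic.HairpinSpec(mature_len=21, mismatches=0,
                                     bulge_events=0, overhang=2)
        h = synthetic.make_hairpin_locus(spec, rng)
        struct, _ = fold_rna(h.precursor, engine="vienna")
        span = (h.mature_offset + 1, h.mature_offset + 21)
        star, stats = evaluate_duplex(struct, span)
        assert (stats.mismatches, stats.bulge_events, stats.overhang_3p) == (0, 0, 2)

    @pytest.mark.parametrize("mm", [0, 1, 2, 3])
    def test_planted_mismatches_counted_exactly(self, rng, mm):
        spec = synthetic.HairpinSpec(mature_len=22, mismatches=mm)
        h = synthetic.make_hairpin_locus(spec, rng)
        struct, _ = fold_rna(h.precursor, engine="vienna")
        span = (h.mature_offset + 1, h.mature_offset + 22)
        _, stats = evaluate_duplex(struct, span)
        assert stats.mismatches == mm


class TestDominance:
    def test_at_threshold_fraction(self, config):
        stack = [("M" * 21, 100, 70), ("X" * 21, 105, 30)]
        assert compute_read_dominance(stack, "M" * 21, 100, config) == 0.70

    def test_below_threshold_fraction(self, config):
        stack = [("M" * 21, 100, 69), ("X" * 21, 110, 31)]
        assert compute_read_dominance(stack, "M" * 21, 100, config) == 0.69

    def test_single_tag_dominates(self, config):
        assert compute_read_dominance(
            [("M" * 21, 100, 5)], "M" * 21, 100, config) == 1.0

    def test_reads_outside_window_ignored(self, config):
        stack = [("M" * 21, 100, 10), ("X" * 21, 121, 99), ("Y" * 21, 79, 99)]
        assert compute_read_dominance(stack, "M" * 21, 100, config) == 1.0

    def test_empty_window_rejected(self, config):
        with pytest.raises(DuplexRejection):
            compute_read_dominance([("X" * 21, 500, 9)], "M" * 21, 100, config)


def _small_sim(seed=21):
    return synthetic.SimulationSpec(
        seed=seed, n_pass_loci=6,
        n_fail_loci={"mismatches": 2, "dominance": 2},
        genome_length=32_000, repeat_copies=0, rrna_len=0)


@pytest.fixture(scope="module")
def small_run(config):
    sim = _small_sim()
    genome, truths, decoys, libraries = synthetic.simulate(sim, None, config)
    raw = {lib: synthetic.raw_reads_from_counts(c, sim.adapter, sim.read_len)
           for lib, c in libraries.items()}
    from wheatmir.preprocess import preprocess_reads
    tags, _ = preprocess_reads(raw, sim.adapter)
    return genome, truths, decoys, tags


class TestCaller:
    def test_accepts_planted_and_rejects_violations(self, small_run, config):
        genome, truths, decoys, tags = small_run
        cands = call_mirna_loci(tags, genome, config, decoys)
        accepted = {c.mature_seq for c in cands if c.accepted}
        for t in truths:
            if t.kind != "mirna_locus":
                continue
            if t.expected_pass:
                assert t.mature_seq in accepted
            else:
                assert t.mature_seq not in accepted

    def test_stricter_thresholds_never_enlarge_accepted_set(self, small_run):
        genome, truths, decoys, tags = small_run
        base = PipelineConfig()
        accepted = {c.mature_seq for c in
                    call_mirna_loci(tags, genome, base, decoys) if c.accepted}
        for strict in (base.replace(dominance_min=0.9),
                       base.replace(max_duplex_mismatch=0)):
            tighter = {c.mature_seq for c in
                       call_mirna_loci(tags, genome, strict, decoys)
                       if c.accepted}
            assert tighter <= accepted

    def test_strand_symmetry(self, small_run):
        genome, truths, decoys, tags = small_run
        cfg = PipelineConfig()
        fwd = {c.mature_seq for c in call_mirna_loci(tags, genome, cfg, decoys)
               if c.accepted}
        flipped = {k: revcomp(v) for k, v in genome.items()}
        rev = {c.mature_seq for c in call_mirna_loci(tags, flipped, cfg, decoys)
               if c.accepted}
        assert fwd == rev
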