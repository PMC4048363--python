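"""Target alignment scoring, degradome profiles, events and regions."""

import pytest

from wheatmir.config import PipelineConfig
from wheatmir import degradome
from wheatmir.degradome import (CleavageEvent, build_degradome_profile,
                                call_cleavage_events, find_orfs,
                                find_orfs_and_classify_region,
                                score_target_alignment,
                                summarize_target_results, targets_per_family)
from wheatmir.seqio import revcomp
from wheatmir.synthetic import _rand_seq

MIR = "TGGAGCTCCCTTCATTCCAAT"            # 21 nt


def penalty_oracle(mirna: str, opposite: str) -> float:
    """Independent per-position penalty table (miRNA 5'->3' vs the bases
    opposite each position, i.e. the binding window read 3'->5')."""
    score = 0.0
    for p, (m, t) in enumerate(zip(mirna, opposite), start=1):
        if (m, t) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
            pen = 0.0
        elif (m, t) in {("G", "T"), ("T", "G")}:
            pen = 0.5
        else:
            pen = 1.0
        score += pen * (2.0 if 2 <= p <= 13 else 1.0)
    return score


def embed(site_seq: str, rng) -> str:
    return _rand_seq(rng, 60) + site_seq + _rand_seq(rng, 60)


def best_score(mirna, transcript, config=None):
    alns = score_target_alignment(mirna, transcript, config)
    return min(a.score for a in alns) if alns else None


class TestScoring:
    def test_perfect_complement_scores_zero(self, rng):
        tx = embed(revcomp(MIR), rng)
        alns = score_target_alignment(MIR, tx)
        assert min(a.score for a in alns) == 0.0

    def test_gu_wobble_in_core_costs_one(self, rng):
        # G:U opposite miRNA position 5 (inside the doubled 2-13 region)
        window = list(revcomp(MIR))
        p = 5
        assert MIR[p - 1] == "G"
        window[len(MIR) - p] = "T"
        assert best_score(MIR, embed("".join(window), rng)) == 1.0

    def test_mismatch_outside_core_costs_one(self, rng):
        window = list(revcomp(MIR))
        p = 16
        window[len(MIR) - p] = MIR[p - 1]       # same base never pairs
        assert best_score(MIR, embed("".join(window), rng)) == 1.0

    def test_penalties_are_additive(self, rng):
        window = list(revcomp(MIR))
        window[len(MIR) - 5] = "T"              # wobble at 5 -> 1.0
        window[len(MIR) - 16] = MIR[15]         # mismatch at 16 -> 1.0
        assert best_score(MIR, embed("".join(window), rng)) == 2.0

    def _score_at_window(self, window, rng):
        """Gapless score of the planted window at its exact span, if kept."""
        cfg = PipelineConfig(max_target_gaps=0)
        tx = embed(window, rng)
        alns = [a for a in score_target_alignment(MIR, tx, cfg)
                if (a.t_start, a.t_end) == (61, 81)]
        return alns[0].score if alns else None

    def test_threshold_boundary(self, rng):
        window = list(revcomp(MIR))
        for p in (14, 16, 17, 21):              # four outer mismatches: 4.0
            window[len(MIR) - p] = MIR[p - 1]   # identical bases never pair
        assert MIR[14] == "T"                   # position 15 can wobble
        window[len(MIR) - 15] = "G"             # T:G wobble, outer: +0.5
        assert self._score_at_window("".join(window), rng) == 4.5
        assert MIR[20] == "T"
        window[len(MIR) - 21] = "G"             # swap the 21 mismatch ...
        window[len(MIR) - 1] = MIR[0]           # ... for wobble + mismatch: 5.0
        assert self._score_at_window("".join(window), rng) is None

    def test_single_edit_sweep_matches_penalty_oracle(self, rng):
        """Every substitution in a perfect 21-nt duplex scores exactly the
        penalty-table value (doubled in the 2-13 core)."""
        perfect = revcomp(MIR)
        cfg = PipelineConfig(target_score_max=10.0, max_target_gaps=0)
        for p in range(1, 22):
            for b in "ACGT":
                window = list(perfect)
                if window[21 - p] == b:
                    continue
                window[21 - p] = b
                window = "".join(window)
                opposite = window[::-1]
                tx = embed(window, rng)
                alns = [a for a in score_target_alignment(MIR, tx, cfg)
                        if tx[a.t_start - 1:a.t_end] == window]
                assert alns, (p, b)
                assert min(a.score for a in alns) == penalty_oracle(MIR, opposite)

    def test_transcript_shorter_than_mirna_yields_nothing(self):
        assert score_target_alignment(MIR, "ACGT") == []

    def test_single_transcript_bulge_found_and_penalised(self, rng):
        window = revcomp(MIR)
        bulged = window[:10] + "A" + window[10:]     # extra transcript base
        cfg = PipelineConfig()
        tx = embed(bulged, rng)
        alns = [a for a in score_target_alignment(MIR, tx, cfg)
                if a.gap == "transcript_bulge"]
        assert alns and min(a.score for a in alns) == 2.0   # gap in 2-13 core

    def test_duplex_states_symmetric_under_strand_swap(self, rng):
        """Pair states (match / wobble / mismatch) are the same whichever
        strand is treated as the guide."""
        cfg = PipelineConfig(target_score_max=30.0, max_target_gaps=0)
        guide = MIR
        window = list(revcomp(MIR))
        window[3] = "A"
        window[10] = "T"
        window = "".join(window)
        a = [x for x in score_target_alignment(guide, window, cfg)
             if (x.t_start, x.t_end) == (1, 21)][0]
        b = [x for x in score_target_alignment(window, guide, cfg)
             if (x.t_start, x.t_end) == (1, 21)][0]
        assert a.states == b.states[::-1]


class TestProfiles:
    def test_reads_counted_at_their_positions(self, rng):
        tx = _rand_seq(rng, 300)
        reads = [(tx[110:130], 6), (tx[40:60], 2)]
        profile = build_degradome_profile(reads, tx)
        assert profile[110] == 6 and profile[40] == 2

    def test_no_mapped_reads_all_zero(self, rng):
        profile = build_degradome_profile([("A" * 20, 5)], _rand_seq(rng, 200))
        assert profile.sum() == 0

    def test_multi_occurrence_read_counted_per_mapping(self, rng):
        core = _rand_seq(rng, 20)
        tx = _rand_seq(rng, 50) + core + _rand_seq(rng, 30) + core + \
            _rand_seq(rng, 40)
        profile = build_degradome_profile([(core, 3)], tx)
        assert profile[50] == 3 and profile[100] == 3

    def test_profile_mass_equals_mapped_reads(self, rng):
        tx = _rand_seq(rng, 300)
        reads = [(tx[10:30], 4), (tx[200:220], 9), ("G" * 20, 7)]
        profile = build_degradome_profile(reads, tx)
        mapped = sum(n for seq, n in reads if seq in tx)
        assert profile.sum() == mapped


class TestEvents:
    def _setup(self, rng, peak):
        tx = embed(revcomp(MIR), rng)
        aln = score_target_alignment(MIR, tx, mirna_id="m", transcript_id="t")[0]
        reads = [(tx[aln.site - 1:aln.site + 19], peak)]
        profiles = {"t": build_degradome_profile(reads, tx)}
        return aln, profiles

    def test_five_reads_call_an_event(self, rng):
        aln, profiles = self._setup(rng, 6)
        events = call_cleavage_events([aln], profiles)
        assert len(events) == 1 and events[0].read_count == 6

    def test_four_reads_do_not(self, rng):
        aln, profiles = self._setup(rng, 4)
        assert call_cleavage_events([aln], profiles) == []

    def test_peak_away_from_site_ignored(self, rng):
        tx = embed(revcomp(MIR), rng)
        aln = score_target_alignment(MIR, tx, mirna_id="m", transcript_id="t")[0]
        far = aln.site + 30
        reads = [(tx[far - 1:far + 19], 50)]
        profiles = {"t": build_degradome_profile(reads, tx)}
        assert call_cleavage_events([aln], profiles) == []

    def test_site_paired_with_mirna_position_ten(self, rng):
        # the binding span's 3' end pairs miRNA position 1; the site is
        # nine bases 5' of it on the transcript
        tx = embed(revcomp(MIR), rng)
        aln = score_target_alignment(MIR, tx)[0]
        assert aln.site == aln.t_end - 9


class TestRegions:
    def _orf_transcript(self, rng, n_codons=75, utr5=100, utr3=120):
        from wheatmir.synthetic import _random_orf, _strip_atg
        return (_strip_atg(_rand_seq(rng, utr5)) + _random_orf(rng, n_codons) +
                _strip_atg(_rand_seq(rng, utr3)))

    def _event(self, site):
        return CleavageEvent("m", "t", site, 10, 0.0)

    def test_site_before_orf_is_five_utr(self, rng):
        tx = self._orf_transcript(rng)
        ev = self._event(50)
        find_orfs_and_classify_region(tx, [ev])
        assert ev.region == "FIVE_UTR"

    def test_site_inside_orf(self, rng):
        tx = self._orf_transcript(rng)
        ev = self._event(200)
        find_orfs_and_classify_region(tx, [ev])
        assert ev.region == "ORF"

    def test_site_after_orf_is_three_utr(self, rng):
        tx = self._orf_transcript(rng)
        orf = find_orfs(tx)[0]
        ev = self._event(orf.end + 10)
        find_orfs_and_classify_region(tx, [ev])
        assert ev.region == "THREE_UTR"

    def test_transcript_without_orf_is_unknown(self):
        tx = "TAATAGTGA" * 30
        ev = self._event(50)
        find_orfs_and_classify_region(tx, [ev])
        assert ev.region == "UNKNOWN"

    def test_orf_finder_respects_minimum_length(self, rng):
        # _random_orf(n) emits ATG + n codons + stop = n + 1 coding codons
        tx = self._orf_transcript(rng, n_codons=68)
        assert find_orfs(tx, min_aa=70) == []
        assert find_orfs(tx, min_aa=69)


class TestSummaries:
    def test_published_targets_per_family_ratios(self):
        assert targets_per_family(524, 124) == 4.2
        assert round(targets_per_family(122, 17)) == 7
        assert round(targets_per_family(71, 17)) == 4

    def test_region_fractions(self):
        events = [CleavageEvent("m1", f"t{i}", 10, 9, 0.0) for i in range(5)]
        for ev, region in zip(events, ["ORF", "ORF", "THREE_UTR",
                                       "THREE_UTR", "FIVE_UTR"]):
            ev.region = region
        out = summarize_target_results(events)
        assert out["region_fractions"] == {
            "FIVE_UTR": 0.2, "ORF": 0.4, "THREE_UTR": 0.4}

    def test_targets_are_unique_family_transcript_pairs(self):
        events = [CleavageEvent("m1", "t1", 10, 9, 0.0),
                  CleavageEvent("m2", "t1", 40, 9, 0.0),
                  CleavageEvent("m3", "t2", 10, 9, 0.0)]
        out = summarize_target_results(events, families={"m1": "F", "m2": "F"})
        assert out["n_targets"] == 2 and out["n_families"] == 2
        assert out["targets_per_family"] == 1.0
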