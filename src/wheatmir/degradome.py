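"""Degradome (PARE) target calling.

A plant miRNA guides cleavage of its mRNA target between the bases
paired to miRNA positions 10 and 11, leaving an uncapped 5' end that
degradome sequencing captures.  Target calling therefore combines two
signals: a good miRNA:mRNA duplex (alignment score <= 4.5 under the
Allen-style penalty scheme: mismatch or gap 1, G:U wobble 0.5, all
penalties doubled at miRNA positions 2-13) and a degradome 5'-end peak
of at least 5 reads at the transcript position opposite miRNA
position 10.  Called cleavage sites are localised to the 5' UTR, ORF or
3' UTR of the transcript using ATG-initiated open reading frames of at
least 70 codons (the longest such ORF is the reference).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import PipelineConfig

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

# penalty[mirna_base, transcript_base]: 0 pair, 0.5 G:U wobble, 1 mismatch
_PENALTY = np.ones((4, 4))
for _m, _t in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _PENALTY[_BASE_IDX[_m], _BASE_IDX[_t]] = 0.0
for _m, _t in (("G", "T"), ("T", "G")):
    _PENALTY[_BASE_IDX[_m], _BASE_IDX[_t]] = 0.5


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_IDX[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base in sequence: {exc}") from exc


def position_weights(n: int) -> np.ndarray:
    """Penalty multipliers by miRNA position (doubled at 2-13)."""
    w = np.ones(n)
    w[1:13] = 2.0
    return w


@dataclass
class TargetAlignment:
    mirna_id: str
    transcript_id: str
    t_start: int        # 1-based inclusive binding span on the transcript
    t_end: int
    score: float
    site: int           # 1-based transcript position opposite miRNA pos 10
    gap: str = "none"   # none | transcript_bulge | mirna_bulge
    states: str = ""    # per-miRNA-position: M match, U wobble, X mismatch, G gap


def _states_gapless(mir: str, window: str) -> str:
    L = len(mir)
    out = []
    for p in range(1, L + 1):
        pen = _PENALTY[_BASE_IDX[mir[p - 1]], _BASE_IDX[window[L - p]]]
        out.append("M" if pen == 0 else ("U" if pen == 0.5 else "X"))
    return "".join(out)


def score_target_alignment(
    mirna: str,
    transcript: str,
    config: PipelineConfig | None = None,
    mirna_id: str = "mirna",
    transcript_id: str = "transcript",
) -> list[TargetAlignment]:
    """All binding windows with alignment score <= ``target_score_max``.

    The miRNA binds antisense: miRNA position 1 (5' end) pairs the
    highest transcript coordinate of the binding span.  Gapless windows
    and, when ``max_target_gaps`` >= 1, single 1-nt bulges on either
    strand are scored; a gap costs 1 (doubled inside positions 2-13).
    Results are sorted by (score, transcript position).
    """
    config = config or PipelineConfig()
    mir = mirna.upper().replace("U", "T")
    tx = transcript.upper().replace("U", "T")
    L = len(mir)
    if not 18 <= L <= 26:
        raise ValueError("miRNA length outside the plausible 18-26 nt range")
    n = len(tx)
    if n < L:
        return []
    m_idx = _encode(mir)
    t_idx = _encode(tx)
    w = position_weights(L)

    # M[e, p-1] = weighted penalty of miRNA position p when the base
    # opposite miRNA position 1 sits at 0-based transcript index e
    # (that base is tx[e - p + 1])
    results: list[TargetAlignment] = []
    es = np.arange(L - 1, n)                       # valid gapless end indexes
    # windows matrix: row e -> tx[e-L+1 .. e] reversed = opposite pos 1..L
    win = np.lib.stride_tricks.sliding_window_view(t_idx, L)[:, ::-1]
    pen = _PENALTY[m_idx[None, :], win] * w[None, :]          # (n-L+1, L)
    gapless = pen.sum(axis=1)
    for row in np.where(gapless <= config.target_score_max)[0]:
        e = int(row + L - 1)
        t_start, t_end = e - L + 2, e + 1          # 1-based
        window = tx[e - L + 1:e + 1]
        results.append(TargetAlignment(
            mirna_id=mirna_id, transcript_id=transcript_id,
            t_start=t_start, t_end=t_end, score=float(gapless[row]),
            site=e - 8, states=_states_gapless(mir, window)))

    if config.max_target_gaps >= 1:
        results.extend(_single_gap_alignments(
            mir, tx, pen, config, mirna_id, transcript_id))
    results.sort(key=lambda a: (a.score, a.t_start, a.gap))
    return results


def _single_gap_alignments(mir, tx, pen, config,
                           mirna_id, transcript_id) -> list[TargetAlignment]:
    """Exhaustive single 1-nt bulge variants via prefix-sum decomposition.

    ``pen`` is the gapless weighted penalty matrix with row ``r``
    covering end index ``e = r + L - 1``; a bulged alignment's score is a
    prefix of one row plus a suffix of an adjacent row plus the gap
    penalty, so the whole sweep is a handful of vector operations per
    bulge position.  Alignments are restricted to windows fully inside
    the transcript.
    """
    L, n = len(mir), len(tx)
    R = pen.shape[0]                       # rows: e = L-1 .. n-1
    if R < 2:
        return []
    out: list[TargetAlignment] = []
    thr = config.target_score_max
    cum = np.cumsum(pen, axis=1)           # cum[r, k-1] = positions 1..k
    tot = cum[:, -1]

    def prefix(r, k):                      # sum over miRNA positions 1..k
        return cum[r, k - 1] if k >= 1 else np.zeros_like(cum[r, 0])

    # transcript bulge between miRNA positions p0 and p0+1: positions
    # 1..p0 pair tx[e-p+1] (row r), positions p0+1..L pair tx[e-p]
    # (row r-1); one extra transcript base sits opposite no miRNA base
    for p0 in range(1, L):
        gap_pen = 2.0 if 2 <= p0 + 1 <= 13 else 1.0
        scores = prefix(slice(1, R), p0) + \
            (tot[:-1] - prefix(slice(0, R - 1), p0)) + gap_pen
        for r1 in np.where(scores <= thr)[0]:
            e = int(r1 + 1 + L - 1)
            site = e - 8 if 10 <= p0 else e - 9
            out.append(TargetAlignment(
                mirna_id=mirna_id, transcript_id=transcript_id,
                t_start=e - L + 1, t_end=e + 1, score=float(scores[r1]),
                site=site, gap="transcript_bulge",
                states=_gap_states(mir, tx, e, p0, "tb")))
    # miRNA bulge at position p0 (no transcript base opposite it):
    # positions 1..p0-1 pair tx[e-p+1] (row r), positions p0+1..L pair
    # tx[e-p+2] (row r+1)
    for p0 in range(2, L):
        gap_pen = 2.0 if 2 <= p0 <= 13 else 1.0
        scores = prefix(slice(0, R - 1), p0 - 1) + \
            (tot[1:] - prefix(slice(1, R), p0)) + gap_pen
        for r in np.where(scores <= thr)[0]:
            e = int(r + L - 1)
            if p0 < 10:
                site = e - 7
            else:
                site = e - 8
            out.append(TargetAlignment(
                mirna_id=mirna_id, transcript_id=transcript_id,
                t_start=e - L + 3, t_end=e + 1, score=float(scores[r]),
                site=site, gap="mirna_bulge",
                states=_gap_states(mir, tx, e, p0, "mb")))
    return out


def _gap_states(mir: str, tx: str, e: int, p0: int, kind: str) -> str:
    L = len(mir)
    out = []
    for p in range(1, L + 1):
        if kind == "mb" and p == p0:
            out.append("G")
            continue
        if kind == "tb":
            i = e - p + 1 if p <= p0 else e - p
        else:
            i = e - p + 1 if p < p0 else e - p + 2
        if i < 0 or i >= len(tx):
            out.append("X")
            continue
        pen = _PENALTY[_BASE_IDX[mir[p - 1]], _BASE_IDX[tx[i]]]
        out.append("M" if pen == 0 else ("U" if pen == 0.5 else "X"))
    return "".join(out)


# ---------------------------------------------------------------------------
# degradome profiles and event calling


def build_degradome_profile(reads: Iterable[tuple[str, int] | str],
                            transcript: str) -> np.ndarray:
    """Per-position degradome 5'-end counts (t-plot vector).

    Entry ``i`` (0-based) counts reads whose 5' end maps at transcript
    position ``i`` by exact match; a read occurring several times in the
    transcript increments every occurrence.
    """
    tx = transcript.upper().replace("U", "T")
    profile = np.zeros(len(tx), dtype=int)
    for item in reads:
        seq, count = (item, 1) if isinstance(item, str) else item
        seq = seq.upper().replace("U", "T")
        i = tx.find(seq)
        while i != -1:
            profile[i] += count
            i = tx.find(seq, i + 1)
    return profile


@dataclass
class CleavageEvent:
    mirna_id: str
    transcript_id: str
    site: int                  # 1-based
    read_count: int
    score: float
    region: str = ""
    alignment: TargetAlignment | None = None


def call_cleavage_events(
    alignments: Sequence[TargetAlignment],
    profiles: Mapping[str, np.ndarray],
    config: PipelineConfig | None = None,
    site_tolerance: int = 0,
) -> list[CleavageEvent]:
    """Emit an event per alignment whose cleavage site carries >= 5 reads.

    The site is the transcript position opposite miRNA position 10; with
    ``site_tolerance`` = 1 the maximum of the +-1 nt neighbourhood is
    used.  Alignments whose site falls outside the transcript are
    skipped.  One event is kept per (miRNA, transcript, site), at the
    best alignment score.
    """
    config = config or PipelineConfig()
    seen: dict[tuple[str, str, int], CleavageEvent] = {}
    for aln in alignments:
        profile = profiles.get(aln.transcript_id)
        if profile is None:
            continue
        if not 1 <= aln.site <= len(profile):
            continue
        lo = max(0, aln.site - 1 - site_tolerance)
        hi = min(len(profile), aln.site + site_tolerance)
        count = int(profile[lo:hi].max())
        if count < config.min_degradome_reads:
            continue
        key = (aln.mirna_id, aln.transcript_id, aln.site)
        if key not in seen or aln.score < seen[key].score:
            seen[key] = CleavageEvent(
                mirna_id=aln.mirna_id, transcript_id=aln.transcript_id,
                site=aln.site, read_count=count, score=aln.score,
                alignment=aln)
    return sorted(seen.values(),
                  key=lambda ev: (ev.mirna_id, ev.transcript_id, ev.site))


# ---------------------------------------------------------------------------
# ORF finding and region classification

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class Orf:
    start: int     # 1-based, position of the A of ATG
    end: int       # 1-based, last base of the stop codon
    n_codons: int  # excluding the stop


def find_orfs(transcript: str, min_aa: int = 70) -> list[Orf]:
    """ATG-initiated, stop-terminated ORFs of >= ``min_aa`` codons in the
    three forward frames, sorted by length (desc) then position."""
    tx = transcript.upper().replace("U", "T")
    orfs: list[Orf] = []
    for frame in range(3):
        i = frame
        open_starts: list[int] = []
        while i + 3 <= len(tx):
            codon = tx[i:i + 3]
            if codon == "ATG":
                open_starts.append(i)
            elif codon in _STOPS:
                for s in open_starts:
                    n_codons = (i - s) // 3
                    if n_codons >= min_aa:
                        orfs.append(Orf(start=s + 1, end=i + 3, n_codons=n_codons))
                open_starts = []
            i += 3
    orfs.sort(key=lambda o: (-o.n_codons, o.start))
    return orfs


def find_orfs_and_classify_region(
    transcript: str,
    events: Sequence[CleavageEvent],
    config: PipelineConfig | None = None,
) -> list[CleavageEvent]:
    """Label each event FIVE_UTR / ORF / THREE_UTR relative to the longest
    qualifying ORF; UNKNOWN when the transcript has none."""
    config = config or PipelineConfig()
    orfs = find_orfs(transcript, min_aa=config.orf_min_aa)
    ref = orfs[0] if orfs else None
    for ev in events:
        if ref is None:
            ev.region = "UNKNOWN"
        elif ev.site < ref.start:
            ev.region = "FIVE_UTR"
        elif ev.site <= ref.end:
            ev.region = "ORF"
        else:
            ev.region = "THREE_UTR"
    return list(events)


# ---------------------------------------------------------------------------
# summaries


def targets_per_family(n_targets: int, n_families: int) -> float:
    """Predicted targets per miRNA family, to one decimal place."""
    if n_families <= 0:
        raise ValueError("n_families must be positive")
    return round(n_targets / n_families, 1)


def summarize_target_results(
    events: Sequence[CleavageEvent],
    families: Mapping[str, str] | None = None,
) -> dict:
    """Per-family target counts, the targets-per-family ratio and region
    fractions.

    A target is a unique (family, transcript) pair; ``families`` maps
    miRNA ids to family names (identity when omitted).  The ratio is
    total targets over families with at least one target, reported to
    one decimal.
    """
    if not events:
        raise ValueError("no events to summarize")
    fam = families or {}
    pairs = {(fam.get(ev.mirna_id, ev.mirna_id), ev.transcript_id)
             for ev in events}
    per_family: dict[str, int] = defaultdict(int)
    for family, _tx in pairs:
        per_family[family] += 1
    n_targets = len(pairs)
    n_families = len(per_family)
    labelled = [ev for ev in events if ev.region and ev.region != "UNKNOWN"]
    region_fractions = {}
    if labelled:
        for region in ("FIVE_UTR", "ORF", "THREE_UTR"):
            region_fractions[region] = sum(
                1 for ev in labelled if ev.region == region) / len(labelled)
    return {
        "n_targets": n_targets,
        "n_families": n_families,
        "targets_per_family": targets_per_family(n_targets, n_families),
        "per_family": dict(sorted(per_family.items())),
        "region_fractions": region_fractions,
    }
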