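"""miRNA locus discovery from mapped small-RNA tags.

The discovery pipeline mirrors the classical plant miRNA annotation
workflow:

1. map unique tags to the genome by exact match on both strands;
2. drop high-copy tags (repeat-associated; > ``max_genome_hits`` perfect
   hits) and tags contained in an annotated ncRNA/repeat decoy set;
3. for each remaining tag-locus, extract candidate precursor windows at
   several flank lengths, fold them, and locate the miRNA* partner from
   the pairing table assuming Dicer's 2-nt 3'-overhang duplex geometry;
4. accept the locus when the mature length, read support, duplex
   statistics (overhang / mismatches / bulges) and read-stack dominance
   all meet their thresholds.

Rejected candidates carry the first failed criterion in the fixed order
``length -> count -> no_hairpin -> overhang -> mismatches -> bulge ->
dominance``; when several flank windows were folded, the reason comes
from the window that progressed furthest through that order.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import PipelineConfig
from .preprocess import ReadTag
from .seqio import revcomp

REASON_ORDER = ("length", "count", "no_hairpin", "overhang",
                "mismatches", "bulge", "dominance")

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or G:U wobble pair (DNA alphabet, T for U)."""
    return (a, b) in _PAIRS


# ---------------------------------------------------------------------------
# mapping and tag filtering


@dataclass(frozen=True)
class GenomeHit:
    seq_id: str
    start: int      # 0-based
    end: int        # exclusive
    strand: str     # "+" or "-"

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def map_tags_exact(tags: Sequence[ReadTag | str],
                   genome: Mapping[str, str]) -> dict[str, list[GenomeHit]]:
    """All perfect occurrences of each tag on both genome strands.

    Minus-strand hits are reported in plus-strand coordinates: the tag
    equals the reverse complement of ``genome[seq_id][start:end]``.
    """
    hits: dict[str, list[GenomeHit]] = {}
    for tag in tags:
        seq = tag.sequence if isinstance(tag, ReadTag) else tag
        if set(seq) - set("ACGT"):
            raise ValueError(f"tag {seq!r} contains non-ACGT characters")
        found: list[GenomeHit] = []
        rc = revcomp(seq)
        for seq_id in sorted(genome):
            chrom = genome[seq_id]
            for i in _find_all(chrom, seq):
                found.append(GenomeHit(seq_id, i, i + len(seq), "+"))
            for i in _find_all(chrom, rc):
                found.append(GenomeHit(seq_id, i, i + len(seq), "-"))
        hits[seq] = found
    return hits


def filter_tags(
    tags: Sequence[ReadTag],
    hits: Mapping[str, list[GenomeHit]],
    decoys: Sequence[str] | None,
    config: PipelineConfig,
) -> tuple[list[ReadTag], dict[str, str]]:
    """Apply the copy-number and annotation filters.

    Returns retained tags and a ``{sequence: reason}`` map for dropped
    tags, reason "high_copy" (more than ``max_genome_hits`` perfect hits)
    or "annotated" (tag or its reverse complement is a substring of a
    decoy ncRNA/repeat entry).
    """
    decoys = [d.upper().replace("U", "T") for d in (decoys or [])]
    retained: list[ReadTag] = []
    dropped: dict[str, str] = {}
    for tag in tags:
        n_hits = len(hits.get(tag.sequence, []))
        if n_hits > config.max_genome_hits:
            dropped[tag.sequence] = "high_copy"
            continue
        rc = revcomp(tag.sequence)
        if any(tag.sequence in d or rc in d for d in decoys):
            dropped[tag.sequence] = "annotated"
            continue
        retained.append(tag)
    return retained, dropped


# ---------------------------------------------------------------------------
# candidate windows and folding


@dataclass
class CandidateWindow:
    """A strand-resolved precursor candidate around one genomic hit."""

    sequence: str          # 5'->3', mature tag appears verbatim
    mature_offset: int     # 0-based offset of the mature tag in `sequence`
    flank: int
    genome_start: int      # 0-based window span in plus-strand coordinates
    genome_end: int


def extract_candidate_windows(hit: GenomeHit, genome: Mapping[str, str],
                              config: PipelineConfig) -> list[CandidateWindow]:
    """One window per configured flank length, clipped at sequence ends.

    Minus-strand windows are reverse complemented so the mature tag reads
    5'->3' within the returned sequence.
    """
    chrom = genome[hit.seq_id]
    windows = []
    for flank in config.flank_lengths:
        w0 = max(0, hit.start - flank)
        w1 = min(len(chrom), hit.end + flank)
        seq = chrom[w0:w1]
        if hit.strand == "+":
            offset = hit.start - w0
        else:
            seq = revcomp(seq)
            offset = w1 - hit.end
        windows.append(CandidateWindow(seq, offset, flank, w0, w1))
    return windows


def _nussinov(seq: str, min_loop: int = 3) -> tuple[str, float]:
    """Base-pair maximisation folding with a deterministic traceback.

    Surrogate energy is minus the pair count.  Intended as the pluggable
    fallback engine and as a small-scale oracle; O(n^3).
    """
    n = len(seq)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if can_pair(seq[k], seq[j]):
                    left = dp[i][k - 1] if k > i else 0
                    cand = left + dp[k + 1][j - 1] + 1
                    if cand > best:
                        best = cand
            dp[i][j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if dp[i][j] == dp[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j]):
                left = dp[i][k - 1] if k > i else 0
                if left + dp[k + 1][j - 1] + 1 == dp[i][j]:
                    structure[k] = "("
                    structure[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    pairs = structure.count("(")
    return "".join(structure), float(-pairs)


def _vienna_available() -> bool:
    try:
        import RNA  # noqa: F401
        return True
    except ImportError:
        return False


def fold_rna(sequence: str, engine: str = "auto",
             max_len: int = 1000) -> tuple[str, float]:
    """Fold a sequence, returning (dot-bracket structure, energy).

    ``engine`` is "vienna" (thermodynamic MFE), "nussinov" (base-pair
    maximisation, surrogate energy = -pairs) or "auto" (vienna when the
    bindings import, else nussinov).
    """
    seq = sequence.upper().replace("U", "T")
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains invalid characters")
    if len(seq) > max_len:
        raise ValueError(f"sequence longer than {max_len} nt")
    if engine == "auto":
        engine = "vienna" if _vienna_available() else "nussinov"
    if engine == "vienna":
        import RNA
        struct, mfe = RNA.fold(seq.replace("T", "U"))
        return struct, float(mfe)
    if engine == "nussinov":
        return _nussinov(seq)
    raise ValueError(f"unknown folding engine {engine!r}")


def pair_table(structure: str) -> list[int]:
    """1-based pairing table; index 0 unused, 0 means unpaired."""
    pt = [0] * (len(structure) + 1)
    stack: list[int] = []
    for i, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pt


# ---------------------------------------------------------------------------
# duplex evaluation


@dataclass
class DuplexStats:
    mismatches: int
    bulge_events: int
    max_bulge_len: int
    overhang_3p: int


@dataclass
class HairpinLocus:
    precursor_seq: str
    structure: str
    energy: float
    mature_span: tuple[int, int]   # 1-based inclusive on the precursor
    star_span: tuple[int, int]
    mature_arm: str                # "5p" or "3p"


class DuplexRejection(Exception):
    """Raised when a mature span cannot form a miRNA/miRNA* duplex."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def evaluate_duplex(structure: str,
                    mature_span: tuple[int, int]) -> tuple[tuple[int, int], DuplexStats]:
    """Locate the miRNA* span and score the duplex from the pairing table.

    With mature span ``[s, e]`` (1-based inclusive), the star span follows
    Dicer's 2-nt 3'-overhang geometry: the star 5' end pairs with mature
    position ``e - 2`` and the star 3' end extends two nucleotides past
    the partner of ``s``.  Unpaired span anchors are extrapolated from the
    nearest paired mature position.

    Statistics:

    * ``mismatches`` -- mature positions in ``[s, e-2]`` unpaired or
      paired within the mature span itself;
    * ``bulge_events`` / ``max_bulge_len`` -- asymmetric loops between
      consecutive paired mature positions in ``[s, e-2]``;
    * ``overhang_3p`` -- number of unpaired mature 3'-terminal bases
      (2 for a canonical duplex).

    Raises :class:`DuplexRejection` ("no_hairpin") when the mature span
    is entirely unpaired, spans the terminal loop (partners on both
    sides or inside the mature), or its star span would overlap it.
    """
    n = len(structure)
    pt = pair_table(structure)
    s, e = mature_span
    if not (1 <= s < e <= n):
        raise ValueError("mature span outside structure")

    paired = [i for i in range(s, e + 1) if pt[i]]
    if not paired or all(i > e - 2 for i in paired):
        raise DuplexRejection("no_hairpin")
    partners = [pt[i] for i in paired]
    if any(s <= p <= e for p in partners):
        raise DuplexRejection("no_hairpin")       # pairs within the mature
    if min(partners) < s and max(partners) > e:
        raise DuplexRejection("no_hairpin")       # spans the terminal loop

    # star span from the 2-nt 3'-overhang geometry (partners decrease as
    # the mature position increases, on either arm)
    core = [i for i in paired if i <= e - 2]
    a = max(core)                      # anchor for the star 5' end
    b = min(core)                      # anchor for the star 3' end
    star_start = pt[a] - ((e - 2) - a)
    star_end = pt[b] + (b - s) + 2
    star_start = max(1, star_start)
    star_end = min(n, star_end)
    if star_start > star_end or not (star_end < s or star_start > e):
        raise DuplexRejection("no_hairpin")   # degenerate or overlapping star

    mismatches = sum(1 for i in range(s, e - 1)
                     if pt[i] == 0 or s <= pt[i] <= e)

    bulge_events = 0
    max_bulge = 0
    for i, j in zip(core, core[1:]):
        gap_m = j - i - 1
        gap_s = abs(pt[i] - pt[j]) - 1
        if gap_m != gap_s:
            bulge_events += 1
            max_bulge = max(max_bulge, abs(gap_m - gap_s))

    overhang = e - max(paired)
    stats = DuplexStats(mismatches=mismatches, bulge_events=bulge_events,
                        max_bulge_len=max_bulge, overhang_3p=overhang)
    return (star_start, star_end), stats


# ---------------------------------------------------------------------------
# read-stack dominance


def compute_read_dominance(
    stack: Sequence[tuple[str, int, int]],
    mature_seq: str,
    mature_five_prime: int,
    config: PipelineConfig,
) -> float:
    """Fraction of in-window reads contributed by the mature tag.

    ``stack`` holds ``(tag_sequence, five_prime_position, count)`` for
    reads on the locus strand; reads whose 5' ends lie within
    ``+-dominance_window`` nt of the mature 5' end form the denominator.
    """
    w = config.dominance_window
    total = 0
    mature = 0
    for seq, pos, count in stack:
        if abs(pos - mature_five_prime) <= w:
            total += count
            if seq == mature_seq and pos == mature_five_prime:
                mature += count
    if total == 0:
        raise DuplexRejection("dominance")
    return mature / total


# ---------------------------------------------------------------------------
# the locus caller


@dataclass
class MiRNACandidate:
    mature_seq: str
    locus: GenomeHit
    status: str                      # "accepted" or "rejected"
    reason: str | None = None        # first failed criterion when rejected
    counts: dict[str, int] = field(default_factory=dict)
    star_seq: str | None = None
    hairpin: HairpinLocus | None = None
    duplex: DuplexStats | None = None
    dominance: float | None = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def _structure_check(stats: DuplexStats, config: PipelineConfig) -> str | None:
    """First failed duplex criterion in evaluation order, or None."""
    if stats.overhang_3p != config.overhang:
        return "overhang"
    if stats.mismatches > config.max_duplex_mismatch:
        return "mismatches"
    if stats.bulge_events > config.max_bulge_events or \
            stats.max_bulge_len > config.max_bulge_len:
        return "bulge"
    return None


def evaluate_windows(tag_seq: str, hit: GenomeHit, genome: Mapping[str, str],
                      config: PipelineConfig):
    """Fold every flank window; return the accepted hairpin or best failure.

    The smallest window yielding a criteria-passing duplex wins (ties on
    window size broken by lower folding energy are moot here because
    windows are tried smallest-first).  On failure, the reported reason is
    the one furthest along the evaluation order across windows.
    """
    best_fail = "no_hairpin"
    accepted: tuple[HairpinLocus, DuplexStats] | None = None
    for window in extract_candidate_windows(hit, genome, config):
        struct, energy = fold_rna(window.sequence, engine=config.fold_engine,
                                  max_len=config.max_fold_len)
        span = (window.mature_offset + 1, window.mature_offset + len(tag_seq))
        try:
            star_span, stats = evaluate_duplex(struct, span)
        except DuplexRejection:
            continue
        fail = _structure_check(stats, config)
        if fail is None:
            arm = "5p" if star_span[0] > span[1] else "3p"
            hairpin = HairpinLocus(
                precursor_seq=window.sequence, structure=struct, energy=energy,
                mature_span=span, star_span=star_span, mature_arm=arm)
            accepted = (hairpin, stats)
            break
        if REASON_ORDER.index(fail) > REASON_ORDER.index(best_fail):
            best_fail = fail
    if accepted is not None:
        return accepted
    return best_fail


def call_mirna_loci(
    tags: Sequence[ReadTag],
    genome: Mapping[str, str],
    config: PipelineConfig | None = None,
    decoys: Sequence[str] | None = None,
    hits: Mapping[str, list[GenomeHit]] | None = None,
) -> list[MiRNACandidate]:
    """Run the full candidate evaluation over every retained tag-locus.

    A candidate is accepted iff its mature length is within
    ``mature_len``, its read count strictly exceeds ``min_reads_one_lib``
    in some library, some flank window folds into a hairpin passing the
    duplex criteria, the mature tag dominates the local read stack, and
    its count strictly exceeds ``min_reads_either`` in some library.
    """
    config = config or PipelineConfig()
    lo_map, hi_map = config.map_len
    mappable = [t for t in tags if lo_map <= t.length <= hi_map]
    if hits is None:
        hits = map_tags_exact(mappable, genome)
    retained, _dropped = filter_tags(mappable, hits, decoys, config)

    # read stacks keyed by (seq_id, strand) for dominance computation,
    # built from all mapped tags (dropped tags still contribute reads)
    stacks: dict[tuple[str, str], list[tuple[str, int, int]]] = defaultdict(list)
    for tag in mappable:
        for hit in hits.get(tag.sequence, []):
            stacks[(hit.seq_id, hit.strand)].append(
                (tag.sequence, hit.five_prime, tag.total))

    lo, hi = config.mature_len
    candidates: list[MiRNACandidate] = []
    for tag in retained:
        for hit in hits[tag.sequence]:
            cand = MiRNACandidate(mature_seq=tag.sequence, locus=hit,
                                  status="rejected", counts=dict(tag.counts))
            candidates.append(cand)
            if not lo <= tag.length <= hi:
                cand.reason = "length"
                continue
            if max(tag.counts.values(), default=0) <= config.min_reads_one_lib:
                cand.reason = "count"
                continue
            outcome = evaluate_windows(tag.sequence, hit, genome, config)
            if isinstance(outcome, str):
                cand.reason = outcome
                continue
            hairpin, stats = outcome
            cand.hairpin, cand.duplex = hairpin, stats
            ss, se = hairpin.star_span
            cand.star_seq = hairpin.precursor_seq[ss - 1:se]
            try:
                dom = compute_read_dominance(
                    stacks[(hit.seq_id, hit.strand)], tag.sequence,
                    hit.five_prime, config)
            except DuplexRejection:
                cand.reason = "dominance"
                continue
            cand.dominance = dom
            if dom < config.dominance_min:
                cand.reason = "dominance"
                continue
            if max(tag.counts.values(), default=0) <= config.min_reads_either:
                cand.reason = "count"
                continue
            cand.status = "accepted"
            cand.reason = None
    return candidates
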