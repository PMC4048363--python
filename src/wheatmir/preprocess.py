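"""Small-RNA library preprocessing.

Raw reads from each library are 3'-adapter trimmed, length filtered and
collapsed into unique sequence tags with per-library counts.  Library
summaries report the standard bookkeeping for an sRNA sequencing study:
distinct vs total reads, the singleton fraction (unique sequences seen
exactly once), the fraction of reads in the 20-24 nt Dicer-product size
range, and a full per-length histogram.

Trimming is exact: the insert is the prefix of the read before the
leftmost match of the adapter's prefix.  A match needs at least
``adapter_min_overlap`` (default 8) adapter nucleotides, or the full
adapter if it is shorter than that; matches may run off the read end.
Reads containing N are discarded and counted in the trimming log.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


@dataclass
class ReadTag:
    """A unique small-RNA sequence with per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count_in(self, library_id: str) -> int:
        return self.counts.get(library_id, 0)


@dataclass
class TrimLog:
    """Per-library accounting of what trimming kept and discarded."""

    library_id: str
    input_reads: int = 0
    kept_reads: int = 0
    discarded_length: int = 0
    discarded_n: int = 0


@dataclass
class LibrarySummary:
    library_id: str
    distinct: int
    total: int
    singleton_fraction: float
    frac_20_24: float
    size_histogram: dict[int, tuple[int, int]]  # length -> (distinct, total)


def find_adapter(read: str, adapter: str, min_overlap: int = 8) -> int:
    """0-based position of the leftmost adapter match, or len(read).

    A position ``i`` matches when ``read[i:i+k] == adapter[:k]`` with
    ``k = min(len(adapter), len(read) - i)`` and ``k >= min(min_overlap,
    len(adapter))`` -- i.e. at least ``min_overlap`` adapter bases must be
    seen unless the adapter itself is shorter.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    need = min(min_overlap, len(adapter))
    n = len(read)
    for i in range(0, n - need + 1):
        k = min(len(adapter), n - i)
        if read[i:i + k] == adapter[:k]:
            return i
    return n


def preprocess_reads(
    raw_libraries: Mapping[str, Iterable[tuple[str, int] | str]],
    adapter: str,
    length_bounds: tuple[int, int] = (18, 30),
    min_overlap: int = 8,
) -> tuple[list[ReadTag], dict[str, TrimLog]]:
    """Trim, length-filter and collapse reads from one or more libraries.

    ``raw_libraries`` maps library id to an iterable of read sequences or
    (sequence, count) pairs.  Returns the collapsed tags (one ReadTag per
    unique insert, counts keyed by library) and per-library trim logs.
    """
    lo, hi = length_bounds
    if not (15 <= lo <= hi <= 35):
        raise ValueError("length bounds must lie within [15, 35]")
    if not adapter:
        raise ValueError("adapter must be non-empty")

    per_seq: dict[str, dict[str, int]] = defaultdict(dict)
    logs: dict[str, TrimLog] = {}
    for lib_id, reads in raw_libraries.items():
        log = TrimLog(library_id=lib_id)
        counter: Counter[str] = Counter()
        n_reads = 0
        for item in reads:
            seq, count = (item, 1) if isinstance(item, str) else item
            n_reads += count
            seq = seq.upper().replace("U", "T")
            if set(seq) - set("ACGT"):
                if set(seq) - set("ACGTN"):
                    raise ValueError(f"read with invalid characters: {seq!r}")
                log.discarded_n += count
                continue
            insert = seq[:find_adapter(seq, adapter, min_overlap)]
            if not lo <= len(insert) <= hi:
                log.discarded_length += count
                continue
            counter[insert] += count
        if n_reads == 0:
            raise ValueError(f"library {lib_id!r} has no reads")
        log.input_reads = n_reads
        log.kept_reads = sum(counter.values())
        logs[lib_id] = log
        for insert, count in counter.items():
            per_seq[insert][lib_id] = count

    tags = [ReadTag(sequence=seq, counts=dict(sorted(counts.items())))
            for seq, counts in sorted(per_seq.items())]
    return tags, logs


def _summarize_one(lib_id: str, counts: Mapping[str, int]) -> LibrarySummary:
    distinct = len(counts)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"library {lib_id!r} has zero reads")
    singletons = sum(1 for c in counts.values() if c == 1)
    hist: dict[int, list[int]] = defaultdict(lambda: [0, 0])
    for seq, c in counts.items():
        hist[len(seq)][0] += 1
        hist[len(seq)][1] += c
    in_20_24 = sum(c for seq, c in counts.items() if 20 <= len(seq) <= 24)
    return LibrarySummary(
        library_id=lib_id,
        distinct=distinct,
        total=total,
        singleton_fraction=singletons / distinct,
        frac_20_24=in_20_24 / total,
        size_histogram={k: (v[0], v[1]) for k, v in sorted(hist.items())},
    )


def summarize_libraries(tags: Sequence[ReadTag]) -> tuple[list[LibrarySummary], LibrarySummary]:
    """Per-library summaries plus a cross-library grand-total summary.

    The grand total sums reads over all libraries; grand distinct counts
    unique sequences across the union; the grand singleton fraction uses
    sequences whose summed count across libraries is one.
    """
    if not tags:
        raise ValueError("no tags to summarize")
    per_lib: dict[str, dict[str, int]] = defaultdict(dict)
    union: dict[str, int] = {}
    for tag in tags:
        union[tag.sequence] = union.get(tag.sequence, 0) + tag.total
        for lib_id, c in tag.counts.items():
            per_lib[lib_id][tag.sequence] = per_lib[lib_id].get(tag.sequence, 0) + c
    summaries = [_summarize_one(lib, counts) for lib, counts in sorted(per_lib.items())]
    grand = _summarize_one("Total", union)
    return summaries, grand


def grand_total_reads(library_totals: Iterable[int]) -> int:
    """Exact integer sum of per-library total-read counts."""
    total = 0
    for t in library_totals:
        total += int(t)
    return total


def size_class_profile(tags: Sequence[ReadTag],
                       length_bounds: tuple[int, int] = (18, 30)
                       ) -> dict[str, dict[str, dict[int, float]]]:
    """Per-library distinct-fraction and abundance-fraction by read length.

    Returns ``{library_id: {"distinct": {len: frac}, "abundance": {len: frac}}}``
    with each distribution summing to 1 over the lengths present.
    """
    if not tags:
        raise ValueError("no tags")
    lo, hi = length_bounds
    per_lib_d: dict[str, Counter] = defaultdict(Counter)
    per_lib_a: dict[str, Counter] = defaultdict(Counter)
    for tag in tags:
        if not lo <= tag.length <= hi:
            continue
        for lib_id, c in tag.counts.items():
            per_lib_d[lib_id][tag.length] += 1
            per_lib_a[lib_id][tag.length] += c
    out: dict[str, dict[str, dict[int, float]]] = {}
    for lib_id in sorted(per_lib_d):
        nd = sum(per_lib_d[lib_id].values())
        na = sum(per_lib_a[lib_id].values())
        out[lib_id] = {
            "distinct": {L: per_lib_d[lib_id][L] / nd for L in sorted(per_lib_d[lib_id])},
            "abundance": {L: per_lib_a[lib_id][L] / na for L in sorted(per_lib_a[lib_id])},
        }
    return out
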