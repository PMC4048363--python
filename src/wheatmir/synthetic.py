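"""Synthetic genomes, read libraries, transcripts and degradome reads.

The generator plants hairpin miRNA loci with controlled duplex geometry
into a random background genome, together with decoy repeat/rRNA loci
and, optionally, loci that deliberately violate exactly one annotation
criterion (length, read count, 3' overhang, duplex mismatches, bulge
size/frequency, or read-stack dominance).  Every planted feature carries
a :class:`TruthRecord` with the intended pass/fail label, so discovery,
degradome and expression results can be scored against ground truth.

Precursors are built stem-outward from the desired miRNA/miRNA* duplex:
the star arm is the (reverse) complement of the mature core with
non-pairing substitutions at requested mismatch positions and insertions
for bulges, framed by perfectly pairing lower/upper stems.  Each planted
locus is verified in genomic context by folding its candidate windows
through the discovery module, and redrawn (still under the run's seeded
RNG) in the rare case thermodynamic folding deviates from the intended
configuration, so truth labels hold exactly.

Background sequence is i.i.d. uniform over {A,C,G,T}: at the lengths
used here such sequence essentially never folds into a qualifying
hairpin with a read-supported mature tag, making it a clean null.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import discovery
from .config import PipelineConfig
from .seqio import (Gff3Feature, revcomp, write_collapsed_fasta, write_fasta,
                    write_fastq, write_gff3, write_tsv)

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
VIOLATIONS = ("length", "count", "overhang", "mismatches", "bulge", "dominance")

DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"   # Illumina-style 3' sRNA adapter


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _nonpairing(base: str) -> str:
    """A base that forms neither a Watson-Crick nor a G:U pair with `base`.

    The identical base always qualifies under the {WC, GU} pairing rule.
    """
    return base


def _safe_insert_base(left: str, right: str) -> str | None:
    """A base pairing with neither flanking mature base, if one exists."""
    partners = {"A": "T", "C": "G", "G": "CT", "T": "AG"}
    for cand in "CAGT":
        if left not in partners[cand] and right not in partners[cand]:
            return cand
    return None


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class TruthRecord:
    """A planted feature with its intended evaluation outcome."""

    locus_id: str
    kind: str                       # mirna_locus | decoy_repeat | decoy_rrna | target_site
    seq_id: str
    start: int                      # 0-based half-open genomic span
    end: int
    strand: str
    mature_seq: str
    violated_criterion: str = "none"
    expected_pass: bool = True
    mature_start: int = -1          # genomic span of the mature tag
    mature_end: int = -1
    arm: str = "5p"
    dominance: float = 0.85
    site: int = -1                  # degradome cleavage site (1-based)
    peak_reads: int = 0
    region: str = ""

    def __post_init__(self) -> None:
        if self.expected_pass != (self.violated_criterion == "none"):
            raise ValueError("expected_pass must mirror violated_criterion")


# ---------------------------------------------------------------------------
# hairpin construction


@dataclass
class HairpinSpec:
    """Structural parameters for one planted precursor."""

    mature_len: int = 21
    mismatches: int = 0
    bulge_events: int = 0
    bulge_len: int = 1
    overhang: int = 2
    arm: str = "5p"
    lower_stem: int = 10
    upper_stem: int = 8
    loop_len: int = 6
    violated_criterion: str = "none"
    dominance: float = 0.85


@dataclass
class PlantedHairpin:
    precursor: str
    mature_offset: int      # 0-based within the precursor
    mature_seq: str
    star_offset: int
    star_seq: str
    spec: HairpinSpec


def make_hairpin_locus(spec: HairpinSpec, rng: np.random.Generator,
                       verify: bool = True,
                       engine: str = "auto") -> PlantedHairpin:
    """Build a precursor realising exactly the requested duplex geometry.

    The mature core (all but the 3'-overhang bases) pairs the star arm;
    requested mismatches become symmetric 1x1 internal loops and bulges
    become star-side insertions, so the discovery module's duplex
    statistics reproduce the spec by construction.  With ``verify`` the
    bare precursor is folded and re-drawn (under the same seeded RNG) in
    the rare case thermodynamic folding deviates from the intent, so the
    returned locus always evaluates to the requested configuration.

    Raises ``ValueError`` for infeasible requests (e.g. more spaced
    mismatches than the stem can host).
    """
    for _attempt in range(20):
        planted = _construct_hairpin(spec, rng)
        if not verify or _verify_bare(planted, engine):
            return planted
    raise RuntimeError(f"could not realise hairpin spec {spec}")


def _verify_bare(planted: PlantedHairpin, engine: str = "auto") -> bool:
    """Fold the bare precursor and check it evaluates to the spec's intent.

    Canonical loci must reproduce the requested duplex statistics
    exactly; structure-violating loci must fail the (default-threshold)
    criterion check on precisely the criterion they were built to
    violate -- thermodynamic folding may realise e.g. a 6-mismatch
    request as 5 mismatches plus a slid pair, which still reads as a
    "mismatches" control.
    """
    struct, _ = discovery.fold_rna(planted.precursor, engine=engine)
    span = (planted.mature_offset + 1,
            planted.mature_offset + len(planted.mature_seq))
    spec = planted.spec
    try:
        _, stats = discovery.evaluate_duplex(struct, span)
    except discovery.DuplexRejection:
        return False
    if spec.violated_criterion in _STRUCTURAL_REASONS:
        return discovery._structure_check(stats, PipelineConfig()) == \
            spec.violated_criterion
    if stats.overhang_3p != spec.overhang:
        return False
    if stats.mismatches != spec.mismatches:
        return False
    if stats.bulge_events != spec.bulge_events:
        return False
    if spec.bulge_events and stats.max_bulge_len != spec.bulge_len:
        return False
    return True


def _construct_hairpin(spec: HairpinSpec, rng: np.random.Generator) -> PlantedHairpin:
    L = spec.mature_len
    if not 18 <= L <= 26:
        raise ValueError(f"mature length {L} outside 18-26")
    if spec.overhang < 0 or spec.overhang > 3:
        raise ValueError("overhang must be in 0-3")
    core_len = L - spec.overhang
    if core_len < 12:
        raise ValueError("mature core too short for a stable duplex")

    # candidate mismatch positions: interior core indices, spaced >= 2
    slots = list(range(3, core_len - 3, 2))
    if spec.mismatches > len(slots):
        raise ValueError(
            f"infeasible spec: {spec.mismatches} mismatches do not fit in a "
            f"{core_len}-bp stem with 2-nt spacing")
    mm_pos = sorted(rng.choice(len(slots), size=spec.mismatches, replace=False))
    mm_pos = [slots[i] for i in mm_pos]

    # mature: random core closed by strong C/G pairs at both ends, with
    # non-pairing A's as the 3' overhang -- pinning the duplex register
    # so thermodynamic folding reproduces the planted geometry
    core = list(_rand_seq(rng, core_len))
    core[0] = str(rng.choice(["C", "G"]))
    core[-1] = str(rng.choice(["C", "G"]))
    mature = "".join(core) + "A" * spec.overhang

    star = [b.translate(_COMP) for b in reversed(core)]
    # star[i] pairs core[core_len-1-i]; break pairs at mismatch positions
    for k in mm_pos:
        star[core_len - 1 - k] = _nonpairing(core[k])

    # star-side bulge insertions between paired positions, away from
    # mismatches and stem ends
    if spec.bulge_events:
        junctions = [k for k in range(4, core_len - 4)
                     if all(abs(k - m) > 2 and abs(k + 1 - m) > 2 for m in mm_pos)]
        chosen: list[int] = []
        for k in junctions:
            if all(abs(k - c) > 3 for c in chosen):
                if _safe_insert_base(core[k], core[k + 1]) is not None:
                    chosen.append(k)
            if len(chosen) == spec.bulge_events:
                break
        if len(chosen) < spec.bulge_events:
            raise ValueError("infeasible spec: cannot place requested bulges")
        # insert from the 3' side of the star so indices stay valid
        for k in sorted(chosen, reverse=False):
            ins = _safe_insert_base(core[k], core[k + 1]) * spec.bulge_len
            # star index opposite the junction between core k and k+1
            idx = core_len - 1 - k
            star[idx:idx] = list(ins)

    if spec.upper_stem < 4 or spec.lower_stem < 4:
        raise ValueError("upper/lower stems must be at least 4 bp")
    # helper stems capped with C/G so the unpaired A's at the junctions
    # (overhang, star overhang, loop) cannot slip into them
    upper5 = "CC" + _rand_seq(rng, spec.upper_stem - 3) + "C"
    upper3 = revcomp(upper5)
    lower5 = _rand_seq(rng, spec.lower_stem - 2) + "CC"
    lower3 = revcomp(lower5)
    loop = "A" * spec.loop_len
    star_seq = "".join(star)
    star_over = "AA"

    if spec.arm == "5p":
        parts = [lower5, mature, upper5, loop, upper3, star_seq, star_over, lower3]
        mature_offset = len(lower5)
        star_offset = sum(len(p) for p in parts[:5])
    elif spec.arm == "3p":
        parts = [lower5, star_seq, star_over, upper5, loop, upper3, mature, lower3]
        star_offset = len(lower5)
        mature_offset = sum(len(p) for p in parts[:6])
    else:
        raise ValueError("arm must be '5p' or '3p'")
    precursor = "".join(parts)
    return PlantedHairpin(precursor=precursor, mature_offset=mature_offset,
                          mature_seq=mature, star_offset=star_offset,
                          star_seq=star_seq + star_over, spec=spec)


# ---------------------------------------------------------------------------
# simulation spec


@dataclass
class LibrarySpec:
    library_id: str
    locus_depth: int = 120        # reads in the dominance window per locus
    background_reads: int = 150   # singleton reads from random positions
    size_mix: dict[int, float] = field(default_factory=lambda: {
        21: 0.30, 22: 0.15, 24: 0.40, 20: 0.05, 23: 0.05, 19: 0.03, 18: 0.02})


@dataclass
class DegradomeSiteSpec:
    transcript_id: str
    peak_reads: int
    region: str = "ORF"                       # FIVE_UTR | ORF | THREE_UTR
    edits: tuple[tuple[str, int], ...] = ()   # ("gu"|"mm", miRNA position)


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic run; the seed fixes everything."""

    n_pass_loci: int = 40
    n_fail_loci: dict[str, int] = field(default_factory=lambda: {
        v: 10 for v in VIOLATIONS})
    genome_length: int = 150_000
    libraries: list[LibrarySpec] = field(default_factory=lambda: [
        LibrarySpec("lib1"), LibrarySpec("lib2")])
    # 520 copies: every k-mer of the array (including copy-junction ones,
    # which occur once less than the copy number) exceeds the 500-hit filter
    repeat_copies: int = 520
    repeat_unit_len: int = 30
    rrna_len: int = 200
    seed: int = 1
    read_len: int = 36
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        if self.n_pass_loci < 0 or any(v < 0 for v in self.n_fail_loci.values()):
            raise ValueError("locus counts must be non-negative")


def default_locus_specs(sim: SimulationSpec,
                        rng: np.random.Generator) -> list[HairpinSpec]:
    """The per-locus structural specs realised by one simulation.

    Pass loci cycle through mature lengths 20-24 nt, 0-2 mismatches and
    the occasional single 1-nt bulge; each violation class perturbs
    exactly one criterion while keeping the rest canonical.
    """
    specs: list[HairpinSpec] = []
    pass_lens = [21, 20, 22, 21, 24, 23]
    for i in range(sim.n_pass_loci):
        specs.append(HairpinSpec(
            mature_len=pass_lens[i % len(pass_lens)],
            mismatches=i % 3,
            bulge_events=1 if i % 4 == 3 else 0,
            bulge_len=1,
            arm="5p" if i % 2 == 0 else "3p",
            dominance=0.80 + 0.05 * (i % 4),
        ))
    makers = {
        "length": lambda i: HairpinSpec(mature_len=19 if i % 2 == 0 else 25,
                                        violated_criterion="length"),
        "count": lambda i: HairpinSpec(violated_criterion="count"),
        "overhang": lambda i: HairpinSpec(overhang=[0, 3, 1][i % 3],
                                          violated_criterion="overhang"),
        "mismatches": lambda i: HairpinSpec(mismatches=5 + i % 2,
                                            violated_criterion="mismatches"),
        "bulge": lambda i: HairpinSpec(
            bulge_events=1 if i % 2 == 0 else 2,
            bulge_len=3 if i % 2 == 0 else 1,
            violated_criterion="bulge"),
        "dominance": lambda i: HairpinSpec(dominance=0.50,
                                           violated_criterion="dominance"),
    }
    for reason in VIOLATIONS:
        for i in range(sim.n_fail_loci.get(reason, 0)):
            spec = makers[reason](i)
            spec.arm = "5p" if (i + 1) % 2 == 0 else "3p"
            specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# genome assembly


_STRUCTURAL_REASONS = {"overhang", "mismatches", "bulge"}


def _expected_structure_outcome(spec: HairpinSpec) -> str:
    """What evaluate_windows should report for this spec: 'ok' or a reason."""
    if spec.violated_criterion in _STRUCTURAL_REASONS:
        return spec.violated_criterion
    return "ok"


def _verify_in_context(planted: PlantedHairpin, context: str, offset: int,
                       config: PipelineConfig) -> bool:
    """Fold the locus's candidate windows in genomic context and check that
    the structural outcome matches the spec's intent.

    ``context`` must be oriented so the precursor reads 5'->3' at
    ``offset``; minus-strand placements are verified on the reverse
    complement of their neighbourhood (equivalent by strand symmetry,
    which discovery exercises directly).
    """
    m0 = offset + planted.mature_offset
    m1 = m0 + len(planted.mature_seq)
    hit = discovery.GenomeHit("ctx", m0, m1, "+")
    outcome = discovery.evaluate_windows(
        planted.mature_seq, hit, {"ctx": context}, config)
    want = _expected_structure_outcome(planted.spec)
    if want == "ok":
        return not isinstance(outcome, str)
    return outcome == want


def make_synthetic_genome(
    sim: SimulationSpec,
    config: PipelineConfig | None = None,
    locus_specs: Sequence[HairpinSpec] | None = None,
) -> tuple[dict[str, str], list[TruthRecord], list[str]]:
    """Assemble the genome: planted loci, decoy repeat array, decoy rRNA.

    Returns (genome, truth records, decoy sequences).  Planted spans are
    mutually non-overlapping with >=`margin` of background between them;
    every locus is verified by folding in context and redrawn under the
    seeded RNG if thermodynamic folding disagrees with the intent.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(sim.seed)
    specs = list(locus_specs) if locus_specs is not None else \
        default_locus_specs(sim, rng)

    margin = max(config.flank_lengths) + 50
    repeat_block = sim.repeat_copies * sim.repeat_unit_len
    slot_width = 120 + 2 * margin          # precursor <= ~120 nt
    needed = len(specs) * slot_width + repeat_block + sim.rrna_len + 4 * margin
    if needed > sim.genome_length:
        raise ValueError(
            f"genome_length {sim.genome_length} too small; need >= {needed}")

    genome = list(_rand_seq(rng, sim.genome_length))
    truths: list[TruthRecord] = []

    # decoy repeat array at the tail, decoy rRNA just before it
    decoys: list[str] = []
    unit = ""
    if sim.repeat_copies > 0:
        unit = _rand_seq(rng, sim.repeat_unit_len)
        rep_start = sim.genome_length - margin - repeat_block
        genome[rep_start:rep_start + repeat_block] = list(unit * sim.repeat_copies)
        truths.append(TruthRecord(
            locus_id="decoy_repeat", kind="decoy_repeat", seq_id="chr1",
            start=rep_start, end=rep_start + repeat_block, strand="+",
            mature_seq=unit[:21], violated_criterion="count", expected_pass=False))
    else:
        rep_start = sim.genome_length - margin

    if sim.rrna_len > 0:
        rrna = _rand_seq(rng, sim.rrna_len)
        rrna_start = rep_start - margin - sim.rrna_len
        genome[rrna_start:rrna_start + sim.rrna_len] = list(rrna)
        decoys.append(rrna)
        truths.append(TruthRecord(
            locus_id="decoy_rrna", kind="decoy_rrna", seq_id="chr1",
            start=rrna_start, end=rrna_start + sim.rrna_len, strand="+",
            mature_seq=rrna[60:81], violated_criterion="count",
            expected_pass=False))

    for i, spec in enumerate(specs):
        slot = margin + i * slot_width
        strand = "+" if i % 2 == 0 else "-"
        planted = None
        for attempt in range(12):
            cand = make_hairpin_locus(spec, rng)
            insert = cand.precursor if strand == "+" else revcomp(cand.precursor)
            start = slot + margin // 2
            genome[start:start + len(insert)] = list(insert)
            ctx0 = max(0, start - margin)
            ctx1 = min(sim.genome_length, start + len(insert) + margin)
            context = "".join(genome[ctx0:ctx1])
            offset = start - ctx0 if strand == "+" else \
                len(context) - (start - ctx0) - len(insert)
            src = context if strand == "+" else revcomp(context)
            if _verify_in_context(cand, src, offset, config):
                planted = cand
                break
            if attempt >= 5:     # refresh the local background as well
                genome[ctx0:start] = list(_rand_seq(rng, start - ctx0))
                genome[start + len(insert):ctx1] = list(
                    _rand_seq(rng, ctx1 - start - len(insert)))
        if planted is None:
            raise RuntimeError(
                f"could not realise locus spec {spec} after bounded retries")
        plen = len(planted.precursor)
        if strand == "+":
            m_start = start + planted.mature_offset
        else:
            m_start = start + plen - planted.mature_offset - len(planted.mature_seq)
        m_end = m_start + len(planted.mature_seq)
        truths.append(TruthRecord(
            locus_id=f"mir{i + 1:04d}", kind="mirna_locus", seq_id="chr1",
            start=start, end=start + plen, strand=strand,
            mature_seq=planted.mature_seq,
            violated_criterion=spec.violated_criterion,
            expected_pass=spec.violated_criterion == "none",
            mature_start=m_start, mature_end=m_end, arm=spec.arm,
            dominance=spec.dominance))

    genome_str = "".join(genome)
    # the repeat tag must hit the configured copy number exactly; a random
    # background collision would change it (astronomically unlikely)
    if unit:
        n_rep = genome_str.count(unit[:21])
        if n_rep != sim.repeat_copies:
            raise RuntimeError("repeat decoy collided with background sequence")
    return {"chr1": genome_str}, truths, decoys


# ---------------------------------------------------------------------------
# read simulation


def _read_at(chrom: str, five_prime: int, length: int, strand: str) -> str:
    if strand == "+":
        return chrom[five_prime:five_prime + length]
    return revcomp(chrom[five_prime - length + 1:five_prime + 1])


def simulate_srna_libraries(
    truths: Sequence[TruthRecord],
    genome: Mapping[str, str],
    sim: SimulationSpec,
    rng: np.random.Generator,
    config: PipelineConfig | None = None,
) -> dict[str, dict[str, int]]:
    """Per-library collapsed read counts (insert sequence -> count).

    For every miRNA locus with dominance target ``d`` and per-locus depth
    ``n``, the mature tag receives ``round(n*d)`` reads and the remainder
    is split across three offset tags whose 5' ends fall inside the
    +-20 nt dominance window; star reads land outside the window on the
    other arm.  Count-violation loci receive exactly the threshold count
    so the strict > rule rejects them.  Decoy loci contribute abundant
    tags; background reads are singletons drawn from random positions
    with the library's size-class mix.
    """
    if not sim.libraries:
        raise ValueError("empty library specification")
    config = config or PipelineConfig()
    out: dict[str, dict[str, int]] = {}
    mirna_truths = [t for t in truths if t.kind == "mirna_locus"]
    for lib in sim.libraries:
        counts: dict[str, int] = {}

        def add(seq: str, n: int) -> None:
            if n > 0 and seq:
                counts[seq] = counts.get(seq, 0) + n

        for t in mirna_truths if lib.locus_depth > 0 else []:
            chrom = genome[t.seq_id]
            n = lib.locus_depth
            d = t.dominance
            if t.violated_criterion == "count":
                mature_n = config.min_reads_one_lib        # == threshold, fails >
                noise_n = max(3, round(mature_n * (1 - d) / d))
            else:
                mature_n = round(n * d)
                noise_n = n - mature_n
            add(t.mature_seq, mature_n)
            five = t.mature_start if t.strand == "+" else t.mature_end - 1
            sign = 1 if t.strand == "+" else -1
            offsets = rng.choice(
                [-18, -15, -12, -9, -6, -4, 4, 6, 9, 12, 15, 18],
                size=3, replace=False)
            share = noise_n // 3
            for j, off in enumerate(offsets):
                n_j = share if j < 2 else noise_n - 2 * share
                add(_read_at(chrom, five + sign * int(off), 21, t.strand), n_j)
            # star reads: opposite arm, outside the dominance window
            star_five = five + sign * (42 if t.arm == "5p" else -42)
            add(_read_at(chrom, star_five, 21, t.strand), max(2, mature_n // 12))

        if lib.locus_depth > 0:
            for t in truths:
                if t.kind == "decoy_repeat":
                    add(t.mature_seq, 60)
                elif t.kind == "decoy_rrna":
                    add(t.mature_seq, 40)

        chrom = genome[next(iter(sorted(genome)))]
        sizes = sorted(lib.size_mix)
        probs = np.array([lib.size_mix[s] for s in sizes], dtype=float)
        probs /= probs.sum()
        if lib.background_reads:
            lens = rng.choice(sizes, size=lib.background_reads, p=probs)
            starts = rng.integers(0, len(chrom) - 30, size=lib.background_reads)
            for L, s in zip(lens, starts):
                add(chrom[int(s):int(s) + int(L)], 1)
        out[lib.library_id] = counts
    return out


def raw_reads_from_counts(counts: Mapping[str, int], adapter: str,
                          read_len: int) -> list[tuple[str, int]]:
    """Ligate the 3' adapter and clip to the sequencer read length."""
    reads = []
    for insert, n in sorted(counts.items()):
        raw = (insert + adapter + adapter)[:read_len]
        reads.append((raw, n))
    return reads


# ---------------------------------------------------------------------------
# degradome / target simulation


def default_degradome_specs(n_pass: int = 30, n_control: int = 10
                            ) -> list[DegradomeSiteSpec]:
    """30 true sites (>=5-read peaks) and 10 controls with 4-read peaks."""
    specs = []
    regions = ["ORF", "THREE_UTR", "ORF", "THREE_UTR", "FIVE_UTR"]
    peaks = [6, 8, 12, 20, 30, 5]
    edit_cycle: list[tuple[tuple[str, int], ...]] = [
        (), (("gu", 16),), (), (("mm", 16),), (), (("gu", 5),)]
    for i in range(n_pass):
        specs.append(DegradomeSiteSpec(
            transcript_id=f"tx{i + 1:03d}", peak_reads=peaks[i % len(peaks)],
            region=regions[i % len(regions)], edits=edit_cycle[i % len(edit_cycle)]))
    for i in range(n_control):
        specs.append(DegradomeSiteSpec(
            transcript_id=f"ctl{i + 1:03d}", peak_reads=4,
            region=regions[i % len(regions)]))
    return specs


def _strip_atg(seq: str) -> str:
    """Remove every ATG trinucleotide occurrence (used for UTR background)."""
    while "ATG" in seq:
        i = seq.index("ATG")
        seq = seq[:i + 2] + "C" + seq[i + 3:]
    return seq


_STOPS = {"TAA", "TAG", "TGA"}


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        c = _rand_seq(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def simulate_degradome_truth(
    specs: Sequence[DegradomeSiteSpec],
    rng: np.random.Generator,
    orf_codons: int = 80,
    utr5_len: int = 120,
    utr3_len: int = 150,
    read_len: int = 20,
    background_reads: int = 8,
) -> tuple[dict[str, str], dict[str, str], list[tuple[str, int]], list[TruthRecord]]:
    """Transcripts with planted miRNA binding sites and degradome 5' peaks.

    Each transcript carries one ~80-codon ORF (its 5' UTR is scrubbed of
    ATG so the planted ORF is the reference one) and one binding site in
    the requested region.  Exactly ``peak_reads`` degradome reads start at
    the transcript position opposite miRNA position 10; background reads
    are scattered at other positions.

    Returns (transcripts, mirnas, degradome reads as (seq, count), truths).
    """
    transcripts: dict[str, str] = {}
    mirnas: dict[str, str] = {}
    reads: list[tuple[str, int]] = []
    truths: list[TruthRecord] = []
    for idx, spec in enumerate(specs):
        L = 21
        for _try in range(200):
            mir = _rand_seq(rng, L)
            seg = list(revcomp(mir))
            ok = True
            for kind, pos in spec.edits:
                if not 1 <= pos <= L:
                    raise ValueError("edit position outside the miRNA")
                i = L - pos
                if kind == "gu":
                    if mir[pos - 1] == "G":
                        seg[i] = "T"
                    elif mir[pos - 1] == "T":
                        seg[i] = "G"
                    else:
                        ok = False
                        break
                elif kind == "mm":
                    seg[i] = mir[pos - 1]
                else:
                    raise ValueError(f"unknown edit kind {kind!r}")
            segment = "".join(seg)
            if not ok or "ATG" in segment:
                continue

            utr5 = _strip_atg(_rand_seq(rng, utr5_len))
            orf = _random_orf(rng, orf_codons)
            utr3 = _strip_atg(_rand_seq(rng, utr3_len))
            tx = utr5 + orf + utr3
            orf_start = utr5_len + 1                       # 1-based
            orf_end = utr5_len + len(orf)
            # choose a binding end position t_e so the cleavage site
            # (t_e - 9) falls in the requested region
            if spec.region == "FIVE_UTR":
                t_e = utr5_len - 20
            elif spec.region == "ORF":
                t_e = orf_start + 3 + 3 * ((L + 12) // 3)  # inside the ORF
            elif spec.region == "THREE_UTR":
                t_e = orf_end + 40 + L
            else:
                raise ValueError(f"unknown region {spec.region!r}")
            t_s = t_e - L + 1
            if t_s < 1 or t_e > len(tx):
                raise ValueError("binding span outside transcript")
            tx = tx[:t_s - 1] + segment + tx[t_e:]
            if spec.region == "ORF":
                # re-check the reading frame survived the overwrite
                body = tx[orf_start - 1:orf_end]
                if any(body[k:k + 3] in _STOPS for k in range(3, len(body) - 3, 3)):
                    continue
            if "ATG" in tx[:orf_start - 1]:
                continue
            # the planted ORF must be the reference (longest) one; an
            # accidental out-of-frame ATG can otherwise seed a longer ORF
            # running through the 3' UTR and shift region labels
            from .degradome import find_orfs
            orfs = find_orfs(tx, min_aa=70)
            if not orfs or (orfs[0].start, orfs[0].end) != (orf_start, orf_end):
                continue
            break
        else:
            raise RuntimeError(f"could not realise degradome spec {spec}")

        site = t_e - 9
        transcripts[spec.transcript_id] = tx
        mir_id = f"smir{idx + 1:03d}"
        mirnas[mir_id] = mir
        reads.append((tx[site - 1:site - 1 + read_len], spec.peak_reads))
        n_bg = background_reads
        positions = rng.integers(1, len(tx) - read_len, size=n_bg * 2)
        used = 0
        for p in positions:
            p = int(p)
            if used >= n_bg or p == site:
                continue
            reads.append((tx[p - 1:p - 1 + read_len], 1))
            used += 1
        truths.append(TruthRecord(
            locus_id=mir_id, kind="target_site", seq_id=spec.transcript_id,
            start=t_s - 1, end=t_e, strand="+", mature_seq=mir,
            violated_criterion="none" if spec.peak_reads >= 5 else "count",
            expected_pass=spec.peak_reads >= 5,
            site=site, peak_reads=spec.peak_reads, region=spec.region))
    return transcripts, mirnas, reads, truths


# ---------------------------------------------------------------------------
# expression matrix simulation

TISSUE_PANEL = ("DG", "GSE", "SH", "SL", "SR", "SJ",
                "YS5", "YS15", "FL", "GRA8", "GRA15")
GRAIN_TISSUES = ("GRA8", "GRA15")


def simulate_expression_matrix(
    rng: np.random.Generator,
    n_mirna: int = 60,
    n_grain_specific: int = 8,
    libraries: Sequence[str] = TISSUE_PANEL,
    base_total: int = 5_000_000,
):
    """A tissue-structured count matrix with planted grain-specific rows.

    Returns (counts DataFrame, mapped totals Series, truth labels dict).
    Grain-specific miRNAs are strongly expressed in developing-grain
    libraries and at most background level elsewhere; the remaining rows
    get heavy-tailed broad expression.
    """
    import pandas as pd

    rows = [f"mir{i + 1:04d}" for i in range(n_mirna)]
    counts = np.maximum(
        0, rng.lognormal(mean=3.0, sigma=1.2, size=(n_mirna, len(libraries)))
    ).round().astype(int)
    labels: dict[str, str] = {}
    grain_idx = [libraries.index(t) for t in GRAIN_TISSUES if t in libraries]
    other_idx = [i for i in range(len(libraries)) if i not in grain_idx]
    for i in range(n_grain_specific):
        counts[i, :] = 0
        counts[i, grain_idx] = rng.integers(400, 4000, size=len(grain_idx))
        labels[rows[i]] = "grain_specific"
    df = pd.DataFrame(counts, index=rows, columns=list(libraries))
    totals = pd.Series(base_total, index=list(libraries)) + \
        rng.integers(-500_000, 500_000, size=len(libraries))
    return df, totals, labels


# ---------------------------------------------------------------------------
# file emission


def write_simulation(out_dir, genome: Mapping[str, str],
                     truths: Sequence[TruthRecord],
                     decoys: Sequence[str],
                     libraries: Mapping[str, Mapping[str, int]],
                     sim: SimulationSpec) -> None:
    """Write genome FASTA, truth GFF3+TSV, decoy FASTA and per-library reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fa", sorted(genome.items()))
    write_fasta(out / "decoys.fa",
                [(f"decoy{i + 1}", d) for i, d in enumerate(decoys)])
    feats = []
    for t in truths:
        if t.kind != "mirna_locus":
            ftype = "region"
        else:
            ftype = "miRNA_primary_transcript"
        feats.append(Gff3Feature(
            seq_id=t.seq_id, source="wheatmir_sim", type=ftype,
            start0=t.start, end0=t.end, strand=t.strand,
            attributes={"ID": t.locus_id, "kind": t.kind,
                        "violated": t.violated_criterion,
                        "expected_pass": str(t.expected_pass).lower()}))
        if t.kind == "mirna_locus":
            feats.append(Gff3Feature(
                seq_id=t.seq_id, source="wheatmir_sim", type="miRNA",
                start0=t.mature_start, end0=t.mature_end, strand=t.strand,
                attributes={"ID": t.locus_id + ".mature",
                            "Parent": t.locus_id}))
    write_gff3(out / "truth.gff3", feats)
    write_tsv(out / "truth.tsv",
              ["locus_id", "kind", "seq_id", "start", "end", "strand",
               "mature_seq", "violated_criterion", "expected_pass",
               "dominance", "arm"],
              [[t.locus_id, t.kind, t.seq_id, t.start, t.end, t.strand,
                t.mature_seq, t.violated_criterion, t.expected_pass,
                t.dominance, t.arm] for t in truths])
    for lib_id, counts in libraries.items():
        write_collapsed_fasta(out / f"{lib_id}.collapsed.fa",
                              sorted(counts.items()), prefix=f"{lib_id}_t")
        reads = raw_reads_from_counts(counts, sim.adapter, sim.read_len)
        records = []
        for i, (raw, n) in enumerate(reads):
            for j in range(n):
                records.append((f"{lib_id}.{i + 1}.{j + 1}", raw))
        write_fastq(out / f"{lib_id}.fastq", records)


def simulate(sim: SimulationSpec, out_dir=None,
             config: PipelineConfig | None = None):
    """Run the full simulation; optionally write all artifacts to a directory.

    Returns (genome, truths, decoys, per-library counts).
    """
    config = config or PipelineConfig()
    genome, truths, decoys = make_synthetic_genome(sim, config)
    rng = np.random.default_rng(sim.seed + 1)
    libraries = simulate_srna_libraries(truths, genome, sim, rng, config)
    if out_dir is not None:
        write_simulation(out_dir, genome, truths, decoys, libraries, sim)
        from . import __version__
        from .seqio import write_manifest
        write_manifest(
            Path(out_dir) / "manifest.json", config=config.to_dict(),
            inputs=[], seed=sim.seed, version=__version__,
            stage_counts={"truth_records": len(truths),
                          "libraries": len(libraries)})
    return genome, truths, decoys, libraries
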