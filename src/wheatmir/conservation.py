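"""Known-catalog classification and cross-species conservation.

A mature miRNA is *known* when it is identical to a catalog entry,
a *variant* when it has the same length and at most two mismatches to
some entry, and *novel* otherwise.  Cross-species presence asks whether
the mature sequence occurs perfectly in another genome AND some +-200 bp
window around a hit refolds into a hairpin passing the structural duplex
criteria -- read-count criteria are waived since no sRNA libraries exist
for the other species.  The presence pattern across a panel of genomes
is then collapsed into a lineage class (wheat-specific, wheat+barley,
BEP-clade, monocot-wide, or broadly conserved).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .config import PipelineConfig
from .discovery import (DuplexRejection, _structure_check, evaluate_duplex,
                        fold_rna, map_tags_exact)
from .seqio import revcomp

# default species panel: monocots and dicot outgroups
MONOCOTS = ("rice", "maize", "sorghum", "barley", "brachypodium")
DICOTS = ("arabidopsis", "soybean")
BEP_SET = ("barley", "brachypodium", "rice")   # Bambusoideae-Ehrhartoideae-Pooideae
SPECIES_PANEL = DICOTS + MONOCOTS

LINEAGE_CLASSES = ("wheat_specific", "wheat_barley", "bep_clade",
                   "monocot_wide", "broadly_conserved")


@dataclass
class SpeciesSets:
    monocots: tuple[str, ...] = MONOCOTS
    dicots: tuple[str, ...] = DICOTS
    bep: tuple[str, ...] = BEP_SET

    @property
    def panel(self) -> tuple[str, ...]:
        return self.dicots + self.monocots


@dataclass
class PresenceProfile:
    mirna_id: str
    presence: dict[str, bool]
    lineage_class: str = ""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(1 for x, y in zip(a, b) if x != y)


def classify_against_catalog(
    mature: str,
    catalog: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> tuple[str, int | None, str | None]:
    """Classify a mature sequence against a known-miRNA catalog.

    Returns ``(status, distance, best_id)`` with status "known" (exact
    match), "variant" (equal length, Hamming distance <=
    ``variant_max_mismatch``; the minimum distance and its entry are
    reported) or "novel".  An empty catalog yields "novel".
    """
    config = config or PipelineConfig()
    mature = mature.upper().replace("U", "T")
    best: tuple[int, str] | None = None
    for name, seq in catalog.items():
        seq = seq.upper().replace("U", "T")
        if seq == mature:
            return "known", 0, name
        if len(seq) == len(mature):
            d = hamming(mature, seq)
            if d <= config.variant_max_mismatch and (best is None or d < best[0]):
                best = (d, name)
    if best is not None:
        return "variant", best[0], best[1]
    return "novel", None, None


def assess_species_presence(
    mature: str,
    genome: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> bool:
    """Does this mature miRNA have a qualifying precursor in a genome?

    Present iff the sequence matches the genome perfectly (either strand)
    and some window of ``conservation_flank`` bp around a hit folds into
    a hairpin meeting the overhang/mismatch/bulge criteria.
    """
    config = config or PipelineConfig()
    mature = mature.upper().replace("U", "T")
    hits = map_tags_exact([mature], genome)[mature]
    flank = config.conservation_flank
    for hit in hits:
        chrom = genome[hit.seq_id]
        w0 = max(0, hit.start - flank)
        w1 = min(len(chrom), hit.end + flank)
        window = chrom[w0:w1]
        if hit.strand == "+":
            offset = hit.start - w0
        else:
            window = revcomp(window)
            offset = w1 - hit.end
        struct, _ = fold_rna(window, engine=config.fold_engine,
                             max_len=config.max_fold_len)
        span = (offset + 1, offset + len(mature))
        try:
            _, stats = evaluate_duplex(struct, span)
        except DuplexRejection:
            continue
        if _structure_check(stats, config) is None:
            return True
    return False


def classify_lineage(presence: Mapping[str, bool],
                     sets: SpeciesSets | None = None) -> str:
    """Collapse a species presence map into a lineage class.

    Precedence: any dicot -> broadly_conserved; all monocots ->
    monocot_wide; barley only -> wheat_barley; a non-empty subset of the
    BEP clade (barley/Brachypodium/rice) with no other species ->
    bep_clade; nothing -> wheat_specific.  Any remaining pattern involves
    a monocot outside the BEP clade without full monocot coverage and is
    classed monocot_wide.  Total and deterministic over all 2^n vectors.
    """
    sets = sets or SpeciesSets()
    unknown = set(presence) - set(sets.panel)
    if unknown:
        raise KeyError(f"unknown species ids: {sorted(unknown)}")
    present = {sp for sp, p in presence.items() if p}
    if any(sp in present for sp in sets.dicots):
        return "broadly_conserved"
    if all(presence.get(sp, False) for sp in sets.monocots):
        return "monocot_wide"
    if not present:
        return "wheat_specific"
    if present == {"barley"}:
        return "wheat_barley"
    if present <= set(sets.bep):
        return "bep_clade"
    return "monocot_wide"


def build_presence_profiles(
    mirnas: Mapping[str, str],
    species_genomes: Mapping[str, Mapping[str, str]],
    config: PipelineConfig | None = None,
    sets: SpeciesSets | None = None,
) -> list[PresenceProfile]:
    """Evaluate presence across a panel of genomes and assign lineages."""
    sets = sets or SpeciesSets()
    profiles = []
    for mir_id, seq in sorted(mirnas.items()):
        presence = {sp: assess_species_presence(seq, species_genomes[sp], config)
                    for sp in sets.panel if sp in species_genomes}
        full = {sp: presence.get(sp, False) for sp in sets.panel}
        profiles.append(PresenceProfile(
            mirna_id=mir_id, presence=full,
            lineage_class=classify_lineage(full, sets)))
    return profiles
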