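"""Result writers: GFF3, TSV, Vienna dot-bracket and Newick emission.

All writers are deterministic byte-wise given fixed inputs; coordinates
are 0-based half-open internally and 1-based inclusive in GFF3.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .degradome import CleavageEvent
from .discovery import MiRNACandidate
from .expression import ClusterResult, linkage_to_newick
from .preprocess import LibrarySummary
from .seqio import Gff3Feature, write_gff3, write_tsv, write_vienna


def write_discovery_outputs(candidates: Sequence[MiRNACandidate], out_dir) -> None:
    """GFF3 of accepted loci, Vienna structures and a full candidate TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    accepted = [c for c in candidates if c.accepted]
    feats = []
    vienna = []
    for i, cand in enumerate(accepted, start=1):
        name = f"miRNA{i:04d}"
        hp = cand.hairpin
        locus = cand.locus
        # precursor span in genome coordinates from the accepted window
        plen = len(hp.precursor_seq)
        lead = hp.mature_span[0] - 1          # precursor bases 5' of the mature
        if locus.strand == "+":
            p_start = locus.start - lead
        else:
            p_start = locus.end + lead - plen
        feats.append(Gff3Feature(
            seq_id=locus.seq_id, source="wheatmir",
            type="miRNA_primary_transcript",
            start0=p_start, end0=p_start + plen, strand=locus.strand,
            attributes={"ID": name, "dominance": f"{cand.dominance:.3f}"}))
        feats.append(Gff3Feature(
            seq_id=locus.seq_id, source="wheatmir", type="miRNA",
            start0=locus.start, end0=locus.end, strand=locus.strand,
            attributes={"ID": f"{name}.mature", "Parent": name,
                        "seq": cand.mature_seq}))
        vienna.append((name, hp.precursor_seq, hp.structure, hp.energy))
    write_gff3(out / "accepted_loci.gff3", feats)
    write_vienna(out / "accepted_hairpins.vienna", vienna)
    write_tsv(
        out / "candidates.tsv",
        ["mature_seq", "seq_id", "start", "end", "strand", "status", "reason",
         "dominance", "mismatches", "bulge_events", "max_bulge_len",
         "overhang_3p", "total_reads"],
        [[c.mature_seq, c.locus.seq_id, c.locus.start, c.locus.end,
          c.locus.strand, c.status, c.reason or ".",
          f"{c.dominance:.3f}" if c.dominance is not None else ".",
          c.duplex.mismatches if c.duplex else ".",
          c.duplex.bulge_events if c.duplex else ".",
          c.duplex.max_bulge_len if c.duplex else ".",
          c.duplex.overhang_3p if c.duplex else ".",
          sum(c.counts.values())] for c in candidates])


def write_summary_outputs(summaries: Sequence[LibrarySummary],
                          grand: LibrarySummary, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [[s.library_id, s.distinct, s.total,
             f"{100 * s.singleton_fraction:.2f}", f"{100 * s.frac_20_24:.2f}"]
            for s in [*summaries, grand]]
    write_tsv(out / "library_summary.tsv",
              ["library", "distinct_reads", "total_reads",
               "singleton_distinct_pct", "frac_20_24_pct"], rows)


def write_target_outputs(events: Sequence[CleavageEvent],
                         profiles: Mapping[str, "object"], out_dir) -> None:
    """Events TSV plus per-transcript t-plot tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(out / "cleavage_events.tsv",
              ["mirna", "transcript", "site", "reads", "score", "region"],
              [[ev.mirna_id, ev.transcript_id, ev.site, ev.read_count,
                f"{ev.score:.1f}", ev.region or "."] for ev in events])
    tplot_dir = out / "tplots"
    tplot_dir.mkdir(exist_ok=True)
    for tx_id in sorted(profiles):
        profile = profiles[tx_id]
        write_tsv(tplot_dir / f"{tx_id}.tsv", ["position", "reads"],
                  [[i + 1, int(v)] for i, v in enumerate(profile) if v > 0])


def write_expression_outputs(matrix, clusters: ClusterResult, out_dir) -> None:
    """RP10M matrix TSV (clustered order) and row/column Newick trees."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = matrix.loc[clusters.row_order, clusters.col_order]
    ordered.to_csv(out / "expression_rp10m.tsv", sep="\t",
                   index_label="mirna", float_format="%.4f")
    (out / "row_dendrogram.nwk").write_text(
        linkage_to_newick(clusters.row_linkage, list(matrix.index)) + "\n")
    (out / "col_dendrogram.nwk").write_text(
        linkage_to_newick(clusters.col_linkage, list(matrix.columns)) + "\n")
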