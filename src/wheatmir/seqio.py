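"""Sequence and annotation file I/O.

Readers are thin wrappers around Biopython's SeqIO that normalise records
to uppercase DNA (U -> T) and understand the collapsed-FASTA dialect used
for unique small-RNA tags, where the header encodes a read count::

    >tag0001_x153
    TGGACGAGGACGTGGCGGTTC

Writers cover the text formats the pipeline emits: FASTA, FASTQ
(Phred+33, constant quality), collapsed FASTA, GFF3 (1-based inclusive
coordinates), TSV tables, Vienna dot-bracket files and a JSON run
manifest.  All writers are deterministic given their inputs.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

_COLLAPSED_RE = re.compile(r"_x(\d+)$")
_VALID_SEQ_RE = re.compile(r"^[ACGTN]*$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecordLite:
    """A parsed sequence record: id, uppercase DNA sequence, read count."""

    id: str
    seq: str
    count: int = 1


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def sniff_format(path) -> str:
    """Guess FASTA vs FASTQ from the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c = line[0]
                if c == ">":
                    return "fasta"
                if c == "@":
                    return "fastq"
                raise ValueError(f"{path}: unrecognised format (starts with {c!r})")
    raise ValueError(f"{path}: empty file")


def parse_sequences(path, format: str | None = None) -> list[SeqRecordLite]:
    """Read FASTA/FASTQ records, honouring the collapsed ``_x<count>`` dialect.

    Sequences are uppercased with U converted to T.  A FASTQ record whose
    quality string length differs from its sequence length, or a sequence
    containing characters outside {A,C,G,T,N}, raises ``ValueError``.
    """
    path = Path(path)
    fmt = format or sniff_format(path)
    records: list[SeqRecordLite] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            seq = _normalise(str(rec.seq))
            if not _VALID_SEQ_RE.match(seq):
                raise ValueError(
                    f"{path}: record {rec.id!r} (#{i + 1}) has non-ACGTN characters")
            count = 1
            m = _COLLAPSED_RE.search(rec.id)
            if m:
                count = int(m.group(1))
            records.append(SeqRecordLite(id=rec.id, seq=seq, count=count))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed {fmt} record: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no records parsed")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_collapsed_fasta(path, tags: Iterable[tuple[str, int]],
                          prefix: str = "tag") -> None:
    """Write unique tags as collapsed FASTA (``>tag<serial>_x<count>``)."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(tags, start=1):
            fh.write(f">{prefix}{i:06d}_x{count}\n{seq}\n")


def write_fastq(path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


@dataclass
class Gff3Feature:
    seq_id: str
    source: str
    type: str
    start0: int            # 0-based inclusive start
    end0: int              # 0-based exclusive end
    strand: str
    attributes: dict = field(default_factory=dict)
    score: str = "."

    def line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        return "\t".join([
            self.seq_id, self.source, self.type,
            str(self.start0 + 1), str(self.end0), self.score,
            self.strand, ".", attrs,
        ])


def write_gff3(path, features: Iterable[Gff3Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write(feat.line() + "\n")


def read_gff3(path) -> list[Gff3Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = {}
            if f[8] != ".":
                for kv in f[8].split(";"):
                    k, _, v = kv.partition("=")
                    attrs[k] = v
            feats.append(Gff3Feature(
                seq_id=f[0], source=f[1], type=f[2],
                start0=int(f[3]) - 1, end0=int(f[4]),
                strand=f[6], attributes=attrs, score=f[5]))
    return feats


def write_vienna(path, entries: Iterable[tuple[str, str, str, float]]) -> None:
    """Write (name, sequence, dot-bracket, energy) as Vienna-format records."""
    with open(path, "w") as fh:
        for name, seq, struct, energy in entries:
            fh.write(f">{name}\n{seq}\n{struct} ({energy:.2f})\n")


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, config: dict, inputs: Sequence[str | Path],
                   seed: int | None, stage_counts: dict, version: str) -> None:
    """Emit a JSON run manifest: config snapshot, input digests, seed, counts."""
    manifest = {
        "tool_version": version,
        "seed": seed,
        "config": config,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "stage_counts": stage_counts,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
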