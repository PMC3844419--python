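"""Transcript models, base-context classification and codon-level translation.

Coordinates are 0-based half-open throughout the package; VCF I/O converts
to and from 1-based positions at the file boundary.

CpG context is evaluated on the coding-strand transcript sequence: a C is
``C_CPG`` iff the next coding base is G, a G is ``G_CPG`` iff the previous
coding base is C.  Terminal bases lacking the required neighbour are
non-CpG (no genomic flank is guaranteed to be available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from functools import lru_cache
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio.Seq import Seq
from pyfaidx import Fasta

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


class BaseCategory(IntEnum):
    """Context class of a reference base on the analyzed (coding) strand."""

    A = 0
    T = 1
    C_CPG = 2
    G_CPG = 3
    C_NONCPG = 4
    G_NONCPG = 5


@dataclass(frozen=True)
class TranscriptModel:
    """One protein-coding transcript with its spliced CDS sequence.

    ``cds_intervals`` are non-overlapping, sorted, 0-based half-open genomic
    intervals; ``cds_sequence`` is given in coding orientation (already
    reverse-complemented for minus-strand models) and must be a multiple of
    three bases long.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        prev_end = None
        for start, end in self.cds_intervals:
            if end <= start:
                raise ValueError(f"{self.transcript_id}: empty interval ({start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.transcript_id}: intervals overlap or are unsorted")
            prev_end = end
        total = sum(e - s for s, e in self.cds_intervals)
        if total != len(self.cds_sequence):
            raise ValueError(
                f"{self.transcript_id}: interval span {total} != sequence length "
                f"{len(self.cds_sequence)}"
            )
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    def contains(self, genomic_pos: int) -> bool:
        return any(s <= genomic_pos < e for s, e in self.cds_intervals)

    def genomic_to_coding(self, genomic_pos: int) -> int:
        """Map a genomic position inside the CDS to a 0-based coding index."""
        offset = 0
        for start, end in self.cds_intervals:
            if start <= genomic_pos < end:
                plus_offset = offset + (genomic_pos - start)
                if self.strand == "+":
                    return plus_offset
                return self.cds_length - 1 - plus_offset
            offset += end - start
        raise ValueError(
            f"position {self.chrom}:{genomic_pos} outside CDS of {self.transcript_id}"
        )

    def coding_to_genomic(self, coding_pos: int) -> int:
        if not 0 <= coding_pos < self.cds_length:
            raise ValueError(f"coding position {coding_pos} out of range")
        plus_offset = coding_pos if self.strand == "+" else self.cds_length - 1 - coding_pos
        offset = 0
        for start, end in self.cds_intervals:
            if plus_offset < offset + (end - start):
                return start + (plus_offset - offset)
            offset += end - start
        raise AssertionError("unreachable")

    def genomic_positions(self) -> Iterator[int]:
        """All genomic CDS positions in ascending genomic order."""
        for start, end in self.cds_intervals:
            yield from range(start, end)

    def translate(self) -> str:
        return str(Seq(self.cds_sequence).translate())


def classify_base(seq: str, pos: int) -> BaseCategory:
    """Classify the base at ``pos`` of ``seq`` into one of six context classes."""
    if not 0 <= pos < len(seq):
        raise IndexError(f"position {pos} out of range for sequence of length {len(seq)}")
    base = seq[pos]
    if base not in _VALID_BASES:
        raise ValueError(f"ambiguous or invalid base {base!r} at position {pos}")
    if base == "A":
        return BaseCategory.A
    if base == "T":
        return BaseCategory.T
    if base == "C":
        if pos + 1 < len(seq) and seq[pos + 1] == "G":
            return BaseCategory.C_CPG
        return BaseCategory.C_NONCPG
    # base == "G"
    if pos - 1 >= 0 and seq[pos - 1] == "C":
        return BaseCategory.G_CPG
    return BaseCategory.G_NONCPG


@lru_cache(maxsize=65536)
def classify_sequence(seq: str) -> np.ndarray:
    """Vectorised per-base :class:`BaseCategory` codes for a whole sequence."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    is_a = arr == ord("A")
    is_t = arr == ord("T")
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    if not np.all(is_a | is_t | is_c | is_g):
        bad = int(np.nonzero(~(is_a | is_t | is_c | is_g))[0][0])
        raise ValueError(f"ambiguous or invalid base {seq[bad]!r} at position {bad}")
    out[is_a] = BaseCategory.A
    out[is_t] = BaseCategory.T
    next_is_g = np.zeros(arr.shape, dtype=bool)
    next_is_g[:-1] = is_g[1:]
    prev_is_c = np.zeros(arr.shape, dtype=bool)
    prev_is_c[1:] = is_c[:-1]
    out[is_c & next_is_g] = BaseCategory.C_CPG
    out[is_c & ~next_is_g] = BaseCategory.C_NONCPG
    out[is_g & prev_is_c] = BaseCategory.G_CPG
    out[is_g & ~prev_is_c] = BaseCategory.G_NONCPG
    out.setflags(write=False)
    return out


def codon_at(model: TranscriptModel, genomic_pos: int) -> tuple[str, int, str]:
    """Return (codon, offset-within-codon, amino acid) at a genomic CDS position."""
    coding = model.genomic_to_coding(genomic_pos)
    codon_start = (coding // 3) * 3
    codon = model.cds_sequence[codon_start : codon_start + 3]
    aa = str(Seq(codon).translate())
    return codon, coding % 3, aa


def _parse_bed12(path: Path) -> list[dict]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(fields)}")
            chrom, start, _end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: blockCount does not match block lists")
            intervals = tuple(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            if "|" in name:
                gene_id, transcript_id = name.split("|", 1)
            else:
                gene_id = transcript_id = name
            records.append(
                dict(
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    chrom=chrom,
                    strand=strand,
                    intervals=intervals,
                )
            )
    return records


def _parse_gff3(path: Path) -> list[dict]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    records = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        gene = mrna.attributes.get("gene_id", mrna.attributes.get("Parent", [mrna.id]))[0]
        intervals = tuple((f.start - 1, f.end) for f in cds)  # GFF3 is 1-based inclusive
        records.append(
            dict(
                gene_id=gene,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                intervals=intervals,
            )
        )
    return records


def load_transcripts(fasta_path: Path | str, annotation_path: Path | str) -> list[TranscriptModel]:
    """Load transcript models from a FASTA and a BED12 or GFF3 annotation.

    Missing sequence for an annotated chrom is a hard error; a record whose
    spliced CDS length is not a multiple of three is skipped with a warning.
    """
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    suffix = annotation_path.suffix.lower()
    if suffix == ".bed":
        raw = _parse_bed12(annotation_path)
    elif suffix in (".gff", ".gff3"):
        raw = _parse_gff3(annotation_path)
    else:
        raise ValueError(f"unsupported annotation format: {annotation_path}")

    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    models: list[TranscriptModel] = []
    for rec in raw:
        if rec["chrom"] not in fasta:
            raise ValueError(
                f"no FASTA record {rec['chrom']!r} for transcript {rec['transcript_id']}"
            )
        chrom_seq = fasta[rec["chrom"]]
        spliced = "".join(str(chrom_seq[s:e]) for s, e in rec["intervals"])
        if len(spliced) % 3 != 0:
            log.warning(
                "skipping %s: CDS length %d is not a multiple of 3",
                rec["transcript_id"],
                len(spliced),
            )
            continue
        if rec["strand"] == "-":
            spliced = reverse_complement(spliced)
        models.append(
            TranscriptModel(
                gene_id=rec["gene_id"],
                transcript_id=rec["transcript_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                cds_intervals=rec["intervals"],
                cds_sequence=spliced,
            )
        )
    return models


def pick_representative(models: Sequence[TranscriptModel]) -> dict[str, TranscriptModel]:
    """One designated transcript per gene: the longest CDS (ties by id)."""
    best: dict[str, TranscriptModel] = {}
    for m in sorted(models, key=lambda m: (-m.cds_length, m.transcript_id)):
        best.setdefault(m.gene_id, m)
    return best
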