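"""Gene annotations, GFF3/FASTA I/O, 3' extensions and promoter extraction.

Internally every coordinate is 0-based half-open; GFF3 (1-based inclusive)
is converted at the I/O boundary.  A promoter is the window upstream of a
gene's 5' end (the start codon for gene-level annotations), by default
700 bp, clipped at the scaffold edge; its sequence is stored reading toward
the start codon (minus-strand promoters are reverse-complemented).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import reverse_complement

PROMOTER_LENGTH = 700
THREE_PRIME_EXTENSION = 400


@dataclass(frozen=True, order=True)
class GeneModel:
    """One gene: scaffold interval plus strand, 0-based half-open."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        """0-based coordinate of the first transcribed base (5' end)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    sequence: str
    clipped: bool

    @property
    def length(self) -> int:
        return len(self.sequence)


class GFF3ParseError(ValueError):
    pass


def read_annotation(path) -> List[GeneModel]:
    """Parse gene features from a GFF3 file.

    Only ``gene`` features are read; each must carry an ``ID`` attribute.
    Malformed records raise :class:`GFF3ParseError` naming the line number.
    """
    models = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start), int(end)
            except ValueError:
                raise GFF3ParseError(f"line {lineno}: non-integer coordinates") from None
            if start1 < 1 or start1 > end1:
                raise GFF3ParseError(f"line {lineno}: start > end or start < 1")
            if strand not in ("+", "-"):
                raise GFF3ParseError(f"line {lineno}: unknown strand {strand!r}")
            attr_map = {}
            for item in attrs.split(";"):
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = attr_map.get("ID")
            if not gene_id:
                raise GFF3ParseError(f"line {lineno}: gene feature without ID attribute")
            if gene_id in seen:
                raise GFF3ParseError(f"line {lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            models.append(GeneModel(gene_id, seqid, start1 - 1, end1, strand))
    return models


def write_annotation(models: Iterable[GeneModel], path) -> None:
    """Write gene models as GFF3 (1-based inclusive), sorted by position."""
    ordered = sorted(models, key=lambda m: (m.scaffold, m.start, m.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in ordered:
            fh.write(
                "\t".join(
                    [
                        m.scaffold,
                        "ohnodiv",
                        "gene",
                        str(m.start + 1),
                        str(m.end),
                        ".",
                        m.strand,
                        ".",
                        f"ID={m.gene_id}",
                    ]
                )
                + "\n"
            )


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def extend_three_prime(
    models: Iterable[GeneModel],
    scaffold_lengths: Mapping[str, int],
    extension: int = THREE_PRIME_EXTENSION,
) -> List[GeneModel]:
    """Extend each gene's 3' end by ``extension`` bp, clipped at scaffold edges.

    Emulates adding an estimated 3' UTR to gene-level annotations whose
    models end at the stop codon.  Plus-strand genes grow rightward, minus
    strand leftward.  Note the operation is additive: applying it twice to
    an unclipped gene extends by twice the amount.
    """
    out = []
    for m in models:
        length = scaffold_lengths[m.scaffold]
        if m.end > length:
            raise ValueError(f"gene {m.gene_id} exceeds scaffold {m.scaffold} length")
        if m.strand == "+":
            out.append(GeneModel(m.gene_id, m.scaffold, m.start, min(m.end + extension, length), "+"))
        else:
            out.append(GeneModel(m.gene_id, m.scaffold, max(m.start - extension, 0), m.end, "-"))
    return out


def extract_promoter(model: GeneModel, scaffold_seq: str, length: int = PROMOTER_LENGTH) -> Promoter:
    """The up-to-``length`` bp window upstream of the gene's 5' end.

    The sequence reads toward the start codon and abuts it with no offset;
    it is clipped (flagged) when the scaffold provides fewer than ``length``
    upstream bases.  A gene flush with the scaffold edge yields an empty,
    clipped promoter.
    """
    n = len(scaffold_seq)
    if model.end > n:
        raise ValueError(f"gene {model.gene_id} exceeds scaffold bounds")
    if model.strand == "+":
        lo = max(model.start - length, 0)
        seq = scaffold_seq[lo : model.start]
    else:
        hi = min(model.end + length, n)
        seq = reverse_complement(scaffold_seq[model.end : hi])
    return Promoter(model.gene_id, seq, clipped=len(seq) < length)


def extract_promoters(
    models: Iterable[GeneModel],
    sequences: Mapping[str, str],
    length: int = PROMOTER_LENGTH,
) -> Dict[str, Promoter]:
    return {
        m.gene_id: extract_promoter(m, sequences[m.scaffold], length) for m in models
    }


def write_promoters(promoters: Mapping[str, Promoter], path) -> None:
    write_fasta({p.gene_id: p.sequence for p in promoters.values() if p.sequence}, path)
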