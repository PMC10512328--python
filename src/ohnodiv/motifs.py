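"""Exact-match promoter motif scanning.

Motifs are short degenerate patterns (one allowed-nucleotide set per
position).  The two patterns of interest are the stress response element
(STRE, ``CCCCT``, the Msn2/Msn4 binding site) and the degenerate TATA box
``TATA(A/T)A(A/T)(A/G)``.  Scanning is exact: a position matches iff the
promoter nucleotide is in the allowed set; ``N`` matches nothing.  All
(possibly overlapping) occurrences are reported.

Promoters are scanned in the orientation they are stored in (reading toward
the start codon); no reverse-complement matching unless requested.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A fixed-length degenerate nucleotide pattern."""

    name: str
    positions: Tuple[frozenset, ...]

    def __post_init__(self):
        if not self.positions:
            raise ValueError("pattern must have at least one position")
        for i, allowed in enumerate(self.positions):
            if not allowed or not set(allowed) <= set("ACGT"):
                raise ValueError(
                    f"pattern {self.name!r} position {i}: allowed set must be a "
                    "non-empty subset of ACGT"
                )

    @property
    def length(self) -> int:
        return len(self.positions)

    @classmethod
    def from_iupac(cls, name: str, iupac: str) -> "MotifPattern":
        try:
            positions = tuple(frozenset(IUPAC[c]) for c in iupac.upper())
        except KeyError as exc:
            raise ValueError(f"invalid IUPAC code {exc} in pattern {name!r}") from None
        return cls(name, positions)

    def expansions(self) -> List[str]:
        """All concrete sequences matching the pattern."""
        return ["".join(p) for p in product(*(sorted(s) for s in self.positions))]


STRE = MotifPattern.from_iupac("STRE", "CCCCT")
TATA = MotifPattern.from_iupac("TATA", "TATAWAWR")

DEFAULT_PATTERNS = (STRE, TATA)


def _compiled(positions: Tuple[frozenset, ...]):
    # overlapping matches via a lookahead group
    body = "".join("[" + "".join(sorted(s)) + "]" for s in positions)
    return re.compile(f"(?=({body}))")


def _reverse_complement_pattern(pattern: MotifPattern) -> MotifPattern:
    return MotifPattern(
        pattern.name,
        tuple(
            frozenset(c.translate(_COMPLEMENT) for c in allowed)
            for allowed in reversed(pattern.positions)
        ),
    )


def scan(sequence: str, pattern: MotifPattern, both_strands: bool = False) -> List[int]:
    """0-based start offsets of all exact matches of ``pattern`` in ``sequence``.

    Offsets are measured from the sequence 5' end; overlapping matches are
    all reported.  ``N`` (or any non-ACGT character) matches nothing.  With
    ``both_strands`` the reverse complement of the pattern is also scanned
    and offsets are merged (deduplicated, sorted).
    """
    seq = sequence.upper()
    hits = [m.start() for m in _compiled(pattern.positions).finditer(seq)]
    if both_strands:
        rc = _reverse_complement_pattern(pattern)
        extra = [m.start() for m in _compiled(rc.positions).finditer(seq)]
        hits = sorted(set(hits) | set(extra))
    return hits


def build_motif_table(
    promoters: Mapping[str, str],
    patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Per-promoter match counts and offsets for each pattern.

    Returns a tidy frame with one row per (gene_id, pattern): columns
    ``gene_id``, ``pattern``, ``count``, ``offsets`` (semicolon-joined).
    """
    rows = []
    for gene_id in promoters:
        seq = promoters[gene_id]
        for pat in patterns:
            offs = scan(seq, pat, both_strands=both_strands)
            rows.append(
                {
                    "gene_id": gene_id,
                    "pattern": pat.name,
                    "count": len(offs),
                    "offsets": ";".join(map(str, offs)),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "pattern", "count", "offsets"])


def counts_for(table: pd.DataFrame, pattern_name: str) -> pd.Series:
    """gene_id -> count series for one pattern from a motif table."""
    sub = table[table["pattern"] == pattern_name]
    return sub.set_index("gene_id")["count"]


def set_summary(
    table: pd.DataFrame, gene_set: Iterable[str], pattern_name: str = "STRE"
) -> dict:
    """Summarize motif content over a gene set.

    Returns the fraction of promoters with >= 1 match, the mean matches per
    promoter, and a count histogram.  Genes absent from the table are
    reported under ``missing`` and excluded from the statistics.
    """
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        raise ValueError("empty gene set")
    counts = counts_for(table, pattern_name)
    present = [g for g in genes if g in counts.index]
    missing = [g for g in genes if g not in counts.index]
    if not present:
        raise ValueError("no gene of the set is present in the motif table")
    c = counts.loc[present].to_numpy()
    hist = {int(k): int(v) for k, v in zip(*np.unique(c, return_counts=True))}
    return {
        "n": len(present),
        "fraction_with_match": float(np.mean(c >= 1)),
        "mean_per_promoter": float(c.mean()),
        "histogram": hist,
        "missing": missing,
    }


def write_patterns(patterns: Sequence[MotifPattern], path) -> None:
    """Write pattern definitions as ``name<TAB>IUPAC`` lines."""
    rev = {frozenset(v): k for k, v in IUPAC.items()}
    with open(path, "w") as fh:
        fh.write("name\tiupac\n")
        for pat in patterns:
            fh.write(pat.name + "\t" + "".join(rev[s] for s in pat.positions) + "\n")


def read_patterns(path) -> List[MotifPattern]:
    pats = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            name, iupac = line.rstrip("\n").split("\t")
            pats.append(MotifPattern.from_iupac(name, iupac))
    return pats
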