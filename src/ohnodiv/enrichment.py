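"""Fisher exact tests, BH-FDR, GO-slim and motif enrichment.

All enrichment questions here reduce to a 2x2 table: membership in a gene
set against possession of a property (a GO term, an STRE-bearing promoter,
being an ohnolog).  One-sided p-values are exact hypergeometric tail sums;
multiplicity is controlled per analysis family with the Benjamini-Hochberg
step-up procedure at 5% by default.

By default the background *includes* the test set (the test compares the
property rate within the set to its rate in the whole background); the
exclusive mode is available via ``set_in_background=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable:
    """Disjoint 2x2 counts: set x property.

    ``a`` in-set with property, ``b`` in-set without, ``c`` background-only
    with, ``d`` background-only without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in contingency table")

    @classmethod
    def from_sets(
        cls,
        gene_set: Set[str],
        background: Set[str],
        with_property: Set[str],
        set_in_background: bool = True,
    ) -> "ContingencyTable":
        """Build the table from gene sets.

        With ``set_in_background`` (default) the background may contain the
        set; the complement rows are background minus set either way.
        """
        if set_in_background:
            if not gene_set <= background:
                raise ValueError("gene set must be a subset of the background")
            rest = background - gene_set
        else:
            rest = background - gene_set
        a = len(gene_set & with_property)
        b = len(gene_set - with_property)
        c = len(rest & with_property)
        d = len(rest - with_property)
        return cls(a, b, c, d)


def fisher_one_sided(table: ContingencyTable, direction: str = "greater") -> float:
    """Exact one-sided Fisher p-value.

    ``greater`` tests over-representation of the property in the set (upper
    hypergeometric tail at the observed count), ``less`` under-representation.
    A zero margin makes the table degenerate; p = 1 with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_set = a + b
    n_prop = a + c
    total = a + b + c + d
    if n_set == 0 or n_prop == 0 or (b + d) == 0 or (c + d) == 0:
        warnings.warn("degenerate contingency table (zero margin); p = 1")
        return 1.0
    hg = stats.hypergeom(total, n_prop, n_set)
    if direction == "greater":
        return float(min(1.0, hg.sf(a - 1)))
    if direction == "less":
        return float(min(1.0, hg.cdf(a)))
    raise ValueError(f"unknown direction {direction!r}")


def bh_adjust(pvalues: Sequence[float], alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (q-values, rejection flags at ``alpha``).  q_i is the minimum
    over ranks >= rank(i) of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    counts: ContingencyTable
    direction: str
    p: float
    q: float = np.nan
    significant: bool = False


def transfer_go(
    genes: Iterable[str],
    ortholog_map: Mapping[str, Sequence[str]],
    reference_go: Mapping[str, Set[str]],
) -> Dict[str, Set[str]]:
    """Assign GO terms to genes via their reference-species orthologs.

    Each gene receives the union of its orthologs' term sets (a gene with two
    orthologs gets both); genes without any ortholog are absent from the
    returned universe.
    """
    out: Dict[str, Set[str]] = {}
    for g in genes:
        orthologs = ortholog_map.get(g, ())
        if not orthologs:
            continue
        terms: Set[str] = set()
        for o in orthologs:
            terms |= reference_go.get(o, set())
        out[g] = terms
    return out


def go_enrichment(
    gene_set: Set[str],
    background: Set[str],
    go_map: Mapping[str, Set[str]],
    alpha: float = 0.05,
    directions: Sequence[str] = ("greater", "less"),
    set_in_background: bool = True,
) -> pd.DataFrame:
    """Per-term Fisher enrichment of a gene set against a background.

    One test per (term, direction); BH adjustment is applied within each
    direction family.  Terms absent from both the set and the background are
    skipped; an empty term universe yields an empty frame.
    """
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    terms = sorted({t for g in background for t in go_map.get(g, ())})
    rows = []
    for direction in directions:
        dir_rows = []
        for term in terms:
            withp = {g for g in background if term in go_map.get(g, ())}
            table = ContingencyTable.from_sets(
                gene_set, background, withp, set_in_background=set_in_background
            )
            dir_rows.append(
                {
                    "term": term,
                    "direction": direction,
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "p": fisher_one_sided(table, direction),
                }
            )
        if dir_rows:
            q, rej = bh_adjust([r["p"] for r in dir_rows], alpha)
            for r, qi, ri in zip(dir_rows, q, rej):
                r["q"] = float(qi)
                r["significant"] = bool(ri)
        rows.extend(dir_rows)
    return pd.DataFrame(
        rows, columns=["term", "direction", "a", "b", "c", "d", "p", "q", "significant"]
    )


def ohnolog_enrichment(
    gene_set: Set[str],
    background: Set[str],
    ohnolog_genes: Set[str],
    direction: str = "greater",
    set_in_background: bool = True,
) -> Tuple[float, ContingencyTable]:
    """Is the set enriched for ohnologs relative to the background?"""
    table = ContingencyTable.from_sets(
        gene_set, background, ohnolog_genes & background, set_in_background=set_in_background
    )
    return fisher_one_sided(table, direction), table


def significance_tier(p: float) -> str:
    """The reporting tiers used for per-species STRE enrichment."""
    if p < 1e-3:
        return "p<1e-3"
    if p < 0.05:
        return "p<0.05"
    return "n.s."


def stre_enrichment_by_species(
    stre_counts_by_species: Mapping[str, Mapping[str, int]],
    stress_by_species: Mapping[str, pd.DataFrame],
    lfc_min: float = 2.5,
) -> pd.DataFrame:
    """STRE enrichment in stress-activated genes, per species and condition.

    For each species and stress condition the activated set is the genes
    with normalized LFC above ``lfc_min``; the property is a promoter with at
    least one STRE; the background is all genes of the species with both a
    promoter scan and stress data.  Conditions with an empty activated set
    are flagged and not tested.
    """
    rows = []
    for species, stress in stress_by_species.items():
        counts = stre_counts_by_species[species]
        genes = [g for g in stress.index if g in counts]
        background = set(genes)
        with_stre = {g for g in genes if counts[g] >= 1}
        for cond in stress.columns:
            col = stress.loc[genes, cond]
            activated = set(col.index[col > lfc_min])
            row = {
                "species": species,
                "condition": cond,
                "n_activated": len(activated),
                "n_background": len(background),
            }
            if not activated:
                row.update({"p": np.nan, "tier": "empty", "fraction_activated": np.nan,
                            "fraction_background": np.nan})
            else:
                table = ContingencyTable.from_sets(activated, background, with_stre)
                p = fisher_one_sided(table, "greater")
                row.update(
                    {
                        "p": p,
                        "tier": significance_tier(p),
                        "fraction_activated": table.a / max(table.a + table.b, 1),
                        "fraction_background": len(with_stre) / max(len(background), 1),
                    }
                )
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "condition",
            "n_activated",
            "n_background",
            "fraction_activated",
            "fraction_background",
            "p",
            "tier",
        ],
    )


def read_go_map(path) -> Dict[str, Set[str]]:
    """Read a ``gene<TAB>term`` (one pair per line, header) mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: Dict[str, Set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(gene, set()).add(term)
    return out


def write_go_map(go_map: Mapping[str, Set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm\n")
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")
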