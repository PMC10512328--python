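"""Ohnolog pairs, pillar tables, name mapping and synteny assignment.

A *pillar* is one ancestral locus of a pre-duplication genome: for the
post-WGH focal species it lists up to two descendant paralogs (an ohnolog
pair when both survive), and up to one ortholog slot per non-WGH species
(duplicate entries within a slot are comma-separated).

Gene-name mapping between annotation sources uses global protein alignment
(match +1, mismatch -1, gap open -0.5, gap extend -0.1 per additional
position) with a species-specific score threshold, keeping the top five
candidates and retaining consecutive candidates until the score drops by
ten points or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd
from Bio import Align

from .annotation import GeneModel


@dataclass(frozen=True)
class OhnologPair:
    """Two same-species paralogs descended from one pillar."""

    pillar_id: str
    member_a: str
    member_b: str
    orthologs: Mapping[str, Tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.member_a == self.member_b:
            raise ValueError(f"pillar {self.pillar_id}: identical pair members")


@dataclass(frozen=True)
class Singleton:
    pillar_id: str
    gene_id: str
    orthologs: Mapping[str, Tuple[str, ...]] = field(default_factory=dict)


class PillarFormatError(ValueError):
    pass


def focal_columns(species: str) -> Tuple[str, str]:
    return f"{species}_1", f"{species}_2"


def load_pillars(path, focal_species: str) -> Tuple[List[OhnologPair], List[Singleton]]:
    """Read a pillar TSV into ohnolog pairs and singletons.

    The focal post-WGH species occupies two slot columns ``<sp>_1`` and
    ``<sp>_2``; every other column is one species slot whose cell may hold a
    comma-separated list of duplicate orthologs.  Empty cells mean the locus
    was lost in that species.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    col_a, col_b = focal_columns(focal_species)
    if col_a not in df.columns or col_b not in df.columns:
        raise PillarFormatError(
            f"pillar table lacks focal slot columns {col_a!r}/{col_b!r}"
        )
    other_cols = [c for c in df.columns if c not in ("pillar_id", col_a, col_b)]
    pairs: List[OhnologPair] = []
    singles: List[Singleton] = []
    for _, row in df.iterrows():
        pid = row["pillar_id"]
        focal = [g for cell in (row[col_a], row[col_b]) for g in _split_cell(cell)]
        if len(focal) > 2:
            raise PillarFormatError(
                f"pillar {pid}: {len(focal)} focal-species entries (max 2)"
            )
        orthologs = {
            sp: tuple(_split_cell(row[sp])) for sp in other_cols if _split_cell(row[sp])
        }
        if len(focal) == 2:
            pairs.append(OhnologPair(pid, focal[0], focal[1], orthologs))
        elif len(focal) == 1:
            singles.append(Singleton(pid, focal[0], orthologs))
    return pairs, singles


def write_pillars(
    pairs: Sequence[OhnologPair],
    singletons: Sequence[Singleton],
    species: Sequence[str],
    focal_species: str,
    path,
) -> None:
    col_a, col_b = focal_columns(focal_species)
    other = [sp for sp in species if sp != focal_species]
    rows = []
    for p in pairs:
        row = {"pillar_id": p.pillar_id, col_a: p.member_a, col_b: p.member_b}
        for sp in other:
            row[sp] = ",".join(p.orthologs.get(sp, ()))
        rows.append(row)
    for s in singletons:
        row = {"pillar_id": s.pillar_id, col_a: s.gene_id, col_b: ""}
        for sp in other:
            row[sp] = ",".join(s.orthologs.get(sp, ()))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["pillar_id", col_a, col_b, *other])
    df = df.sort_values("pillar_id", kind="stable")
    df.to_csv(path, sep="\t", index=False)


def _split_cell(cell: str) -> List[str]:
    return [g.strip() for g in str(cell).split(",") if g.strip()]


# ---------------------------------------------------------------------------
# protein-similarity gene-name mapping


@dataclass(frozen=True)
class NameMapParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -0.5
    gap_extend: float = -0.1
    score_threshold: float = 100.0
    top_k: int = 5
    drop_cutoff: float = 10.0
    drop_from: str = "previous"  # or "top": compare drops to the best candidate

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


def align_score(seq1: str, seq2: str, params: NameMapParams = NameMapParams()) -> float:
    """Optimal global alignment score of two protein sequences.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``; terminal gaps
    are penalized like internal ones.
    """
    if not seq1 or not seq2:
        raise ValueError("cannot align an empty sequence")
    return float(params.aligner().score(seq1, seq2))


def map_gene_names(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    params: NameMapParams,
) -> Dict[str, dict]:
    """Map query genes onto target genes by protein similarity.

    For each query: candidates are the ``top_k`` targets scoring at or above
    ``score_threshold`` (descending score, ties broken by target id); the
    retained list keeps the top candidate and every following candidate whose
    score drop (from the previously retained candidate, or from the top with
    ``drop_from='top'``) is smaller than ``drop_cutoff``.
    """
    if params.top_k < 1:
        raise ValueError("top_k must be >= 1")
    aligner = params.aligner()
    out: Dict[str, dict] = {}
    for qid, qseq in queries.items():
        scored = []
        for tid, tseq in targets.items():
            s = float(aligner.score(qseq, tseq))
            if s >= params.score_threshold:
                scored.append((-s, tid))
        scored.sort()
        candidates = [(tid, -neg) for neg, tid in scored[: params.top_k]]
        kept = retain_candidates(
            [s for _, s in candidates], params.drop_cutoff, params.drop_from
        )
        out[qid] = {
            "candidates": candidates,
            "retained": [candidates[i][0] for i in kept],
        }
    return out


def retain_candidates(
    scores: Sequence[float], drop_cutoff: float = 10.0, drop_from: str = "previous"
) -> List[int]:
    """Indices of retained candidates under the score-drop rule.

    Retains index 0, then each next index while the drop from the reference
    score (previous retained, or the top score) is strictly below
    ``drop_cutoff``.
    """
    if not scores:
        return []
    kept = [0]
    ref = scores[0]
    for i in range(1, len(scores)):
        if ref - scores[i] < drop_cutoff:
            kept.append(i)
            if drop_from == "previous":
                ref = scores[i]
        else:
            break
    return kept


# ---------------------------------------------------------------------------
# syntenic assignment


@dataclass(frozen=True)
class SyntenyAssignment:
    gene_id: str
    assigned_to: str  # "member_a", "member_b" or "undetermined"
    support_a: int
    support_b: int


def _flanking(
    gene_id: str, order: Mapping[str, List[str]], index: Mapping[str, Tuple[str, int]], window: int
) -> List[str]:
    scaffold, pos = index[gene_id]
    genes = order[scaffold]
    lo = max(pos - window, 0)
    return [g for g in genes[lo : pos + window + 1] if g != gene_id]


def gene_order(models: Iterable[GeneModel]):
    """Per-scaffold left-to-right gene id lists plus a gene -> (scaffold, rank) index."""
    by_scaffold: Dict[str, List[GeneModel]] = {}
    for m in models:
        by_scaffold.setdefault(m.scaffold, []).append(m)
    order = {
        sc: [m.gene_id for m in sorted(ms, key=lambda m: (m.start, m.gene_id))]
        for sc, ms in by_scaffold.items()
    }
    index = {g: (sc, i) for sc, genes in order.items() for i, g in enumerate(genes)}
    return order, index


def assign_synteny(
    gene_id: str,
    pair: OhnologPair,
    gene_annotation: Iterable[GeneModel],
    focal_annotation: Iterable[GeneModel],
    orthogroups: Mapping[str, str],
    window: int = 8,
    min_support: int = 2,
) -> SyntenyAssignment:
    """Assign a post-WGH gene to one pair member's lineage by shared flanking context.

    Counts how many of the up-to-16 genes flanking ``gene_id`` share an
    orthogroup with the flanking genes of each pair member in the focal
    species; the gene is assigned to the side with strictly greater support
    of at least ``min_support``, otherwise left undetermined.  Windows are
    truncated at scaffold edges.
    """
    g_order, g_index = gene_order(gene_annotation)
    f_order, f_index = gene_order(focal_annotation)
    if gene_id not in g_index:
        raise KeyError(f"gene {gene_id} not in its annotation")
    flank = _flanking(gene_id, g_order, g_index, window)
    flank_groups = {orthogroups[g] for g in flank if g in orthogroups}
    support = {}
    for side, member in (("member_a", pair.member_a), ("member_b", pair.member_b)):
        if member not in f_index:
            raise KeyError(f"pair member {member} not in focal annotation")
        mflank = _flanking(member, f_order, f_index, window)
        mgroups = {orthogroups[g] for g in mflank if g in orthogroups}
        support[side] = len(flank_groups & mgroups)
    sa, sb = support["member_a"], support["member_b"]
    if sa > sb and sa >= min_support:
        assigned = "member_a"
    elif sb > sa and sb >= min_support:
        assigned = "member_b"
    else:
        assigned = "undetermined"
    return SyntenyAssignment(gene_id, assigned, sa, sb)


# ---------------------------------------------------------------------------
# promoter-subset filters


def filter_promoter_subset(
    de_pairs: Sequence,
    stre_counts: Mapping[str, float],
    nonwgh_species: Sequence[str],
    max_duplicated_species: int = 8,
) -> Tuple[list, pd.DataFrame]:
    """Apply the three promoter-analysis filters to classified DE pairs.

    ``de_pairs`` are records with ``pair`` (an :class:`OhnologPair`) and
    ``high_member`` attributes.  A pair is removed when (1) the high-LFC
    member's promoter has zero STREs, (2) more than ``max_duplicated_species``
    non-WGH species carry duplicate orthologs, or (3) it has no non-WGH
    ortholog at all.  Pairs whose high member lacks a promoter scan are
    excluded and counted separately.  The predicates are independent, so any
    application order yields the same retained set; the report lists every
    filter each removed pair failed.
    """
    retained = []
    rows = []
    for rec in de_pairs:
        pair: OhnologPair = rec.pair
        failed = []
        if rec.high_member not in stre_counts:
            rows.append({"pillar_id": pair.pillar_id, "removed_by": "missing_promoter"})
            continue
        if stre_counts[rec.high_member] == 0:
            failed.append("no_stre_in_high_member")
        n_dup = sum(
            1 for sp in nonwgh_species if len(pair.orthologs.get(sp, ())) > 1
        )
        if n_dup > max_duplicated_species:
            failed.append("duplicated_in_many_species")
        n_orth = sum(len(pair.orthologs.get(sp, ())) for sp in nonwgh_species)
        if n_orth == 0:
            failed.append("no_nonwgh_ortholog")
        if failed:
            rows.append({"pillar_id": pair.pillar_id, "removed_by": ";".join(failed)})
        else:
            retained.append(rec)
            rows.append({"pillar_id": pair.pillar_id, "removed_by": ""})
    report = pd.DataFrame(rows, columns=["pillar_id", "removed_by"])
    return retained, report
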