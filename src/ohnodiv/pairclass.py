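"""Differential-expression categories and ohnolog-pair classification.

Genes are binned by log2 fold change (LFC) at a 1% false-discovery-rate
significance gate: strongly repressed (LFC < -2), weakly repressed
(-2 <= LFC < -1), weakly activated (1 < LFC <= 2), strongly activated
(LFC > 2), and no change (everything else, including any non-significant
gene).  Each ohnolog pair is sorted into a low- and a high-LFC member; when
exactly one member passes the FDR gate, the non-significant member's LFC is
treated as 0 for sorting (so a significant activated gene is always the
high member and a significant repressed gene the low member).

``DE_PKA`` is the set of pairs whose high member is strongly activated
while the low member is repressed or unchanged.  ``DE_Stress`` is the
cross-species analogue on the LFC_est statistic with thresholds
high > 1.5, low < 0.9 and difference > 0.9.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .orthology import OhnologPair


class DECategory(str, enum.Enum):
    STRONGLY_REPRESSED = "strongly_repressed"
    WEAKLY_REPRESSED = "weakly_repressed"
    NO_CHANGE = "no_change"
    WEAKLY_ACTIVATED = "weakly_activated"
    STRONGLY_ACTIVATED = "strongly_activated"


REPRESSED_OR_UNCHANGED = {
    DECategory.NO_CHANGE,
    DECategory.WEAKLY_REPRESSED,
    DECategory.STRONGLY_REPRESSED,
}


@dataclass(frozen=True)
class Thresholds:
    strong_lfc: float = 2.0
    weak_lfc: float = 1.0
    fdr: float = 0.01
    stress_activated_min: float = 1.5
    stress_low_max: float = 0.9
    stress_min_diff: float = 0.9
    species_activated_lfc: float = 2.5

    def __post_init__(self):
        if not (self.strong_lfc > self.weak_lfc > 0):
            raise ValueError("need strong_lfc > weak_lfc > 0")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")


DEFAULT_THRESHOLDS = Thresholds()


def _significant(padj: Optional[float], fdr: float) -> bool:
    # a missing adjusted p (e.g. removed by independent filtering) is
    # conservatively non-significant
    return padj is not None and not (isinstance(padj, float) and math.isnan(padj)) and padj <= fdr


def classify_gene(
    lfc: float, padj: Optional[float], th: Thresholds = DEFAULT_THRESHOLDS
) -> DECategory:
    """Assign one gene's DE category from its LFC and adjusted p-value.

    Boundary conventions follow the printed intervals literally: LFC exactly
    at ``strong_lfc`` with significance is *weakly* activated, LFC exactly at
    ``weak_lfc`` is no change.
    """
    if lfc is None or (isinstance(lfc, float) and math.isnan(lfc)):
        raise ValueError("missing LFC")
    if _significant(padj, th.fdr):
        if lfc > th.strong_lfc:
            return DECategory.STRONGLY_ACTIVATED
        if th.weak_lfc < lfc <= th.strong_lfc:
            return DECategory.WEAKLY_ACTIVATED
        if lfc < -th.strong_lfc:
            return DECategory.STRONGLY_REPRESSED
        if -th.strong_lfc <= lfc < -th.weak_lfc:
            return DECategory.WEAKLY_REPRESSED
    return DECategory.NO_CHANGE


def sort_pair(
    pair: OhnologPair,
    lfc_a: float,
    padj_a: Optional[float],
    lfc_b: float,
    padj_b: Optional[float],
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> Tuple[str, str, str]:
    """Order a pair into (low, high) members.

    With exactly one FDR-significant member, the other member's LFC is
    replaced by 0 for sorting; otherwise raw LFCs decide.  Exact ties are
    broken lexicographically by gene id, so the result is independent of the
    (member_a, member_b) input order.  The returned basis is ``raw_lfc``,
    ``zero_replacement`` (override applied, same order as raw LFC), or
    ``fdr_override`` (override reversed the raw order).
    """
    sig_a, sig_b = _significant(padj_a, th.fdr), _significant(padj_b, th.fdr)
    key_a, key_b = lfc_a, lfc_b
    basis = "raw_lfc"
    if sig_a != sig_b:
        if sig_a:
            key_b = 0.0
        else:
            key_a = 0.0
        raw = _order(pair.member_a, lfc_a, pair.member_b, lfc_b)
        eff = _order(pair.member_a, key_a, pair.member_b, key_b)
        basis = "zero_replacement" if raw == eff else "fdr_override"
        return (*eff, basis)
    return (*_order(pair.member_a, key_a, pair.member_b, key_b), basis)


def _order(id_a: str, key_a: float, id_b: str, key_b: float) -> Tuple[str, str]:
    if (key_a, id_a) <= (key_b, id_b):
        return id_a, id_b
    return id_b, id_a


@dataclass(frozen=True)
class PairClassification:
    pair: OhnologPair
    low_member: str
    high_member: str
    low_category: DECategory
    high_category: DECategory
    sort_basis: str
    in_de_pka: bool = False
    in_de_stress: bool = False


def classify_pairs(
    pairs: Sequence[OhnologPair],
    expression: pd.DataFrame,
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> List[PairClassification]:
    """Classify and sort every pair whose two members have expression data.

    ``expression`` is indexed by gene id with columns ``lfc`` and ``padj``.
    Pairs with a member absent from the table are skipped.
    """
    out = []
    for pair in pairs:
        if pair.member_a not in expression.index or pair.member_b not in expression.index:
            continue
        ra, rb = expression.loc[pair.member_a], expression.loc[pair.member_b]
        low, high, basis = sort_pair(pair, ra["lfc"], ra["padj"], rb["lfc"], rb["padj"], th)
        cats = {
            pair.member_a: classify_gene(ra["lfc"], ra["padj"], th),
            pair.member_b: classify_gene(rb["lfc"], rb["padj"], th),
        }
        out.append(
            PairClassification(pair, low, high, cats[low], cats[high], basis)
        )
    return out


def define_de_pka(classified: Sequence[PairClassification]) -> List[PairClassification]:
    """Pairs whose high member is strongly activated and low member is not activated.

    Returns new records with ``in_de_pka`` set.
    """
    out = []
    for rec in classified:
        flag = (
            rec.high_category is DECategory.STRONGLY_ACTIVATED
            and rec.low_category in REPRESSED_OR_UNCHANGED
        )
        out.append(replace(rec, in_de_pka=flag))
    return out


def de_stress_membership(
    low_est: float, high_est: float, th: Thresholds = DEFAULT_THRESHOLDS
) -> bool:
    return (
        high_est > th.stress_activated_min
        and low_est < th.stress_low_max
        and (high_est - low_est) > th.stress_min_diff
    )


def define_de_stress(
    pairs: Sequence[OhnologPair],
    lfc_est: Mapping[str, float],
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> Tuple[List[OhnologPair], dict]:
    """Select pairs differentially expressed under PKA-like stress.

    Members are ordered by LFC_est; the pair is selected when the higher
    member exceeds ``stress_activated_min``, the lower member is below
    ``stress_low_max`` and their difference exceeds ``stress_min_diff``.
    Pairs with a missing member value are excluded and counted.
    """
    selected = []
    n_missing = 0
    for pair in pairs:
        ea = lfc_est.get(pair.member_a)
        eb = lfc_est.get(pair.member_b)
        if ea is None or eb is None or np.isnan(ea) or np.isnan(eb):
            n_missing += 1
            continue
        low, high = sorted([ea, eb])
        if de_stress_membership(low, high, th):
            selected.append(pair)
    return selected, {"n_missing_member": n_missing, "n_selected": len(selected)}


def cutoff_overlap_curve(
    pairs: Sequence[OhnologPair],
    lfc_est: Mapping[str, float],
    reference_pillars: Iterable[str],
    low_max_grid: Sequence[float],
    activated_min_grid: Sequence[float],
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """|DE_Stress| and its overlap with a reference pair set over a cutoff grid.

    Used to choose the low-member cutoff: with the activated threshold fixed,
    the selected set grows monotonically as ``low_max`` is relaxed and the
    overlap with the reference plateaus once ``low_max`` clears the noise
    ceiling of true low members.
    """
    ref = set(reference_pillars)
    rows = []
    for amin in activated_min_grid:
        for lmax in low_max_grid:
            t = replace(th, stress_activated_min=amin, stress_low_max=lmax)
            sel, _ = define_de_stress(pairs, lfc_est, t)
            pillars = {p.pillar_id for p in sel}
            rows.append(
                {
                    "activated_min": amin,
                    "low_max": lmax,
                    "n_de_stress": len(pillars),
                    "n_overlap": len(pillars & ref),
                }
            )
    return pd.DataFrame(rows)


def classification_table(classified: Sequence[PairClassification]) -> pd.DataFrame:
    rows = [
        {
            "pillar_id": rec.pair.pillar_id,
            "low_member": rec.low_member,
            "high_member": rec.high_member,
            "low_category": rec.low_category.value,
            "high_category": rec.high_category.value,
            "sort_basis": rec.sort_basis,
            "in_de_pka": rec.in_de_pka,
            "in_de_stress": rec.in_de_stress,
        }
        for rec in classified
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pillar_id",
            "low_member",
            "high_member",
            "low_category",
            "high_category",
            "sort_basis",
            "in_de_pka",
            "in_de_stress",
        ],
    )


def category_counts(classified: Sequence[PairClassification]) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for rec in classified:
        key = f"{rec.low_category.value}|{rec.high_category.value}"
        counts[key] = counts.get(key, 0) + 1
    return counts
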