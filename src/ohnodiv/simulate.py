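"""Seeded synthetic study generator.

Emulates the input universe of a post-whole-genome-hybridization (WGH)
ohnolog study: genomes with annotated genes and planted promoter motifs,
a pillar orthology table, PKA-inhibition expression tables, cross-species
stress LFC matrices, microarray replicate matrices, and a GO map — plus
truth labels sufficient to score every downstream stage.

Study structure
---------------
``n_pillars`` ancestral loci pass through the WGH.  The focal post-WGH
species retains both copies (an ohnolog pair) for a fixed fraction of
pillars and one copy (the ancestrally surviving lineage, shared across all
post-WGH species) otherwise.  Non-WGH species carry one ortholog per pillar
(occasionally missing or duplicated).  A fixed fraction of retained pairs
is planted as differentially expressed (DE) under PKA inhibition: the high
member has low basal expression and a large positive LFC, the low member
moderate expression and LFC near 0.  Each DE pair carries a mechanism
label: ``post_wgh_gain`` (promoter STREs appear only in the focal high
member) or ``pre_wgh_gain`` (the ZT-branch orthologs are STRE-rich, the
high member descends from the ZT parent = subgenome A).

Promoter sequences use yeast-like base composition (A/T 0.31, C/G 0.19),
giving ~0.28 chance CCCCT occurrences per 700-bp promoter; planted rates
on top of that are calibrated so background promoters average ~0.63 STREs
(~45% with at least one) and induced promoters ~1.35 (~75%).

All generators are deterministic functions of :class:`SimConfig`; the same
config yields byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel, Promoter, extract_promoters
from .expression import StressMatrix
from .motifs import reverse_complement
from .orthology import OhnologPair, Singleton

BASES = np.array(list("ACGT"))
STRE_SEQ = "CCCCT"

# fixed child-stream ids so each generator draws independent, reproducible
# randomness from the one user seed
_STREAM_PLAN = 0
_STREAM_GENOME = 1
_STREAM_EXPRESSION = 2
_STREAM_GO = 3
_STREAM_REPLICATES = 4
_STREAM_STRESS = 5


@dataclass(frozen=True)
class SimConfig:
    """Study-generator configuration; defaults are the reference conditions."""

    seed: int = 0
    # species composition: post-WGH first, then KLE-branch, ZT-branch, outgroups
    n_species: int = 2
    n_postwgh_species: int = 1
    n_outgroups: int = 0
    zt_fraction: float = 0.5
    # pillar structure
    n_pillars: int = 200
    frac_retained_pairs: float = 0.25
    frac_de_pairs: float = 0.25
    frac_pre_wgh_gain: float = 0.5
    frac_ortholog_missing: float = 0.1
    frac_nonwgh_duplicated: float = 0.03
    # genome layout
    n_scaffolds: int = 2
    scaffold_length: int = 300_000
    gene_length: int = 500
    intergenic_mean: float = 300.0
    intergenic_min: int = 210
    promoter_length: int = 700
    base_composition: Tuple[float, float, float, float] = (0.31, 0.19, 0.19, 0.31)
    # promoter motif planting
    plant_motifs: bool = True
    promoter_stre_rate_background: float = 0.35
    promoter_stre_rate_induced: float = 1.1
    force_induced_stre: bool = False
    nonwgh_rate_base: float = 0.8
    nonwgh_rate_sigma: float = 1.0
    stre_rate_zt_gain: float = 4.0
    stre_depletion_pre_gain: float = 0.05
    # expression effects
    basal_rlog_means: Tuple[float, float, float] = (4.4, 6.4, 6.4)  # high, low, background
    rlog_sd: float = 0.5
    lfc_effect_high: float = 5.0
    lfc_noise_sd: float = 0.3
    lfc_null_sd: float = 0.3
    frac_esr: float = 0.15
    esr_effect_sd: float = 2.5
    # stress compendium
    n_stress_conditions: int = 12
    n_pka_like: int = 5
    n_decoy: int = 2
    stress_correlation: float = 0.8
    stress_correlation_secondary: float = 0.7
    decoy_correlation: float = 0.5
    frac_stress_missing: float = 0.05
    # microarrays
    n_replicates: int = 3
    frac_duplicate_probes: float = 0.05
    # GO map
    n_go_terms: int = 20
    go_background_rate: float = 0.1
    go_enriched_rate: float = 0.8

    def __post_init__(self):
        for name in (
            "frac_retained_pairs",
            "frac_de_pairs",
            "frac_pre_wgh_gain",
            "frac_ortholog_missing",
            "frac_nonwgh_duplicated",
            "frac_esr",
            "go_background_rate",
            "go_enriched_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_species", "n_pillars", "n_scaffolds", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_postwgh_species < 1 or self.n_postwgh_species > self.n_species:
            raise ValueError("need 1 <= n_postwgh_species <= n_species")
        if self.n_pka_like + self.n_decoy > self.n_stress_conditions:
            raise ValueError("PKA-like + decoy conditions exceed n_stress_conditions")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


class ScaffoldSizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# study plan


@dataclass
class StudyPlan:
    config: SimConfig
    species: List[str]
    roles: Dict[str, str]
    focal: str
    retained: np.ndarray
    de: np.ndarray
    mechanism: np.ndarray
    high_copy: np.ndarray
    ancestral_copy: np.ndarray
    esr: np.ndarray
    esr_effect: np.ndarray
    present: Dict[str, np.ndarray]
    duplicated: Dict[str, np.ndarray]
    rate_mult: Dict[str, float]
    stre_offsets: Dict[str, List[int]] = field(default_factory=dict)

    def genes_of(self, species: str) -> List[Tuple[int, str, str]]:
        """(pillar, copy tag, gene id) for every gene of a species, pillar order."""
        out = []
        if self.roles[species] == "post":
            for i in range(len(self.retained)):
                if self.retained[i]:
                    for tag in ("a", "b"):
                        out.append((i, tag, gene_id(species, i, tag)))
                else:
                    tag = self.ancestral_copy[i]
                    out.append((i, tag, gene_id(species, i, tag)))
        else:
            for i in range(len(self.retained)):
                if self.present[species][i]:
                    out.append((i, "", gene_id(species, i, "")))
                    if self.duplicated[species][i]:
                        out.append((i, "", gene_id(species, i, "", dup=True)))
        return out

    def is_induced(self, species: str, pillar: int, gid: str) -> bool:
        """Planted high-LFC member (or its same-lineage post-WGH ortholog)?"""
        if self.roles[species] != "post" or not self.de[pillar]:
            return False
        return gid == gene_id(species, pillar, self.high_copy[pillar])


def gene_id(species: str, pillar: int, tag: str, dup: bool = False) -> str:
    suffix = f"_{tag}" if tag else ""
    if dup:
        suffix += "_d2"
    return f"{species}_g{pillar:05d}{suffix}"


def species_names(config: SimConfig) -> Tuple[List[str], Dict[str, str]]:
    names, roles = [], {}
    n_post = config.n_postwgh_species
    n_out = config.n_outgroups
    n_nonwgh = config.n_species - n_post - n_out
    if n_nonwgh < 0:
        raise ValueError("species composition exceeds n_species")
    n_zt = int(round(config.zt_fraction * n_nonwgh))
    n_kle = n_nonwgh - n_zt
    for i in range(n_post):
        names.append(f"post{i}")
        roles[names[-1]] = "post"
    for i in range(n_kle):
        names.append(f"kle{i}")
        roles[names[-1]] = "kle"
    for i in range(n_zt):
        names.append(f"zt{i}")
        roles[names[-1]] = "zt"
    for i in range(n_out):
        names.append(f"out{i}")
        roles[names[-1]] = "out"
    return names, roles


def plan_study(config: SimConfig) -> StudyPlan:
    """Deterministically decide the latent structure of the study."""
    rng = config.rng(_STREAM_PLAN)
    species, roles = species_names(config)
    n = config.n_pillars
    retained = np.zeros(n, dtype=bool)
    n_ret = int(round(config.frac_retained_pairs * n))
    retained[rng.permutation(n)[:n_ret]] = True
    de = np.zeros(n, dtype=bool)
    ret_idx = np.flatnonzero(retained)
    n_de = int(round(config.frac_de_pairs * n_ret))
    de[rng.permutation(ret_idx)[:n_de]] = True
    mechanism = np.array([""] * n, dtype=object)
    de_idx = np.flatnonzero(de)
    n_pre = int(round(config.frac_pre_wgh_gain * len(de_idx)))
    pre = rng.permutation(de_idx)[:n_pre]
    mechanism[de_idx] = "post_wgh_gain"
    mechanism[pre] = "pre_wgh_gain"
    high_copy = np.array([""] * n, dtype=object)
    # pre-WGH gains ride the ZT-derived subgenome (copy a); post-WGH gains
    # strike either copy
    for i in de_idx:
        high_copy[i] = "a" if mechanism[i] == "pre_wgh_gain" else rng.choice(["a", "b"])
    ancestral_copy = rng.choice(["a", "b"], size=n)
    esr = np.zeros(n, dtype=bool)
    candidates = np.flatnonzero(~de)
    n_esr = int(round(config.frac_esr * n))
    esr[rng.permutation(candidates)[:n_esr]] = True
    esr_effect = np.where(esr, rng.normal(0.0, config.esr_effect_sd, size=n), 0.0)
    present, duplicated, rate_mult = {}, {}, {}
    for sp in species:
        if roles[sp] == "post":
            present[sp] = np.ones(n, dtype=bool)
            duplicated[sp] = np.zeros(n, dtype=bool)
            rate_mult[sp] = 1.0
        else:
            present[sp] = rng.random(n) >= config.frac_ortholog_missing
            duplicated[sp] = present[sp] & (rng.random(n) < config.frac_nonwgh_duplicated)
            rate_mult[sp] = float(np.exp(rng.normal(0.0, config.nonwgh_rate_sigma)))
    return StudyPlan(
        config=config,
        species=species,
        roles=roles,
        focal=species[0],
        retained=retained,
        de=de,
        mechanism=mechanism,
        high_copy=high_copy,
        ancestral_copy=ancestral_copy,
        esr=esr,
        esr_effect=esr_effect,
        present=present,
        duplicated=duplicated,
        rate_mult=rate_mult,
    )


# ---------------------------------------------------------------------------
# genomes


def _stre_rate(plan: StudyPlan, species: str, pillar: int, gid: str) -> float:
    """Expected planted STREs in this gene's promoter."""
    cfg = plan.config
    role = plan.roles[species]
    if role == "post":
        if plan.is_induced(species, pillar, gid) and cfg.promoter_stre_rate_induced > 0:
            return cfg.promoter_stre_rate_induced
        return cfg.promoter_stre_rate_background
    base = cfg.nonwgh_rate_base * plan.rate_mult[species]
    if plan.de[pillar] and plan.mechanism[pillar] == "pre_wgh_gain":
        if role == "zt":
            return cfg.stre_rate_zt_gain
        return cfg.stre_depletion_pre_gain * base
    return base


def generate_genome(
    config: SimConfig, plan: Optional[StudyPlan] = None
) -> Dict[str, Tuple[List[GeneModel], Dict[str, str]]]:
    """Per-species gene annotation and scaffold sequences.

    Post-WGH species carry two homeologous scaffold sets (subgenomes A and
    B); gene order within a subgenome follows pillar order, so synteny is
    conserved across species.  Promoter motifs are planted at
    non-overlapping genomic slots so no planted occurrence destroys another.
    """
    plan = plan or plan_study(config)
    out: Dict[str, Tuple[List[GeneModel], Dict[str, str]]] = {}
    for sp_index, sp in enumerate(plan.species):
        rng = np.random.default_rng([config.seed, _STREAM_GENOME, sp_index])
        genes = plan.genes_of(sp)
        if plan.roles[sp] == "post":
            groups = {
                "A": [(p, t, g) for p, t, g in genes if t == "a"],
                "B": [(p, t, g) for p, t, g in genes if t == "b"],
            }
        else:
            groups = {"": genes}
        models: List[GeneModel] = []
        sequences: Dict[str, str] = {}
        for sub, sub_genes in groups.items():
            per_scaffold = int(np.ceil(len(sub_genes) / config.n_scaffolds))
            for sc_i in range(config.n_scaffolds):
                chunk = sub_genes[sc_i * per_scaffold : (sc_i + 1) * per_scaffold]
                scaffold = f"{sp}_sc{sub}{sc_i}"
                seq = rng.choice(BASES, size=config.scaffold_length, p=config.base_composition)
                cursor = config.promoter_length + int(rng.integers(0, 50))
                claimed: List[Tuple[int, int]] = []
                for pillar, tag, gid in chunk:
                    start = cursor
                    end = start + config.gene_length
                    if end + config.promoter_length > config.scaffold_length:
                        raise ScaffoldSizeError(
                            f"scaffold {scaffold} too short: need more than "
                            f"{end + config.promoter_length} bp, have {config.scaffold_length}"
                        )
                    strand = "+" if rng.random() < 0.5 else "-"
                    models.append(GeneModel(gid, scaffold, start, end, strand))
                    if config.plant_motifs:
                        _plant_stres(
                            seq, claimed, rng, plan, sp, pillar, gid, start, end, strand
                        )
                    gap = config.intergenic_min + int(
                        rng.exponential(config.intergenic_mean)
                    )
                    cursor = end + gap
                sequences[scaffold] = seq.astype("S1").tobytes().decode("ascii")
        out[sp] = (models, sequences)
    return out


def _plant_stres(
    seq: np.ndarray,
    claimed: List[Tuple[int, int]],
    rng: np.random.Generator,
    plan: StudyPlan,
    species: str,
    pillar: int,
    gid: str,
    start: int,
    end: int,
    strand: str,
) -> List[int]:
    cfg = plan.config
    rate = _stre_rate(plan, species, pillar, gid)
    count = int(rng.poisson(rate))
    if (
        cfg.force_induced_stre
        and plan.is_induced(species, pillar, gid)
        and count == 0
    ):
        count = 1
    k = len(STRE_SEQ)
    planted = []
    for _ in range(count):
        for _try in range(50):
            offset = int(rng.integers(0, cfg.promoter_length - k + 1))
            if strand == "+":
                pos = start - cfg.promoter_length + offset
                motif = STRE_SEQ
            else:
                pos = end + cfg.promoter_length - offset - k
                motif = reverse_complement(STRE_SEQ)
            if pos < 0 or pos + k > len(seq):
                continue
            if any(pos < hi and lo < pos + k for lo, hi in claimed):
                continue
            seq[pos : pos + k] = list(motif)
            claimed.append((pos, pos + k))
            planted.append(offset)
            break
    planted.sort()
    plan.stre_offsets[gid] = planted
    return planted


# ---------------------------------------------------------------------------
# orthology


def generate_orthology(
    config: SimConfig,
    genomes: Optional[Mapping[str, Tuple[List[GeneModel], Dict[str, str]]]] = None,
    plan: Optional[StudyPlan] = None,
) -> Tuple[List[OhnologPair], List[Singleton]]:
    """Pillar table: ohnolog pairs (focal retained) plus singleton rows.

    Every generated gene id appears in exactly one pillar; non-WGH slots
    carry duplicate ids when the plan duplicated the ortholog.
    """
    plan = plan or plan_study(config)
    nonfocal = [sp for sp in plan.species if sp != plan.focal]
    pairs: List[OhnologPair] = []
    singles: List[Singleton] = []
    for i in range(config.n_pillars):
        pid = f"P{i:05d}"
        orthologs = {}
        for sp in nonfocal:
            if plan.roles[sp] == "post":
                ids = [gene_id(sp, i, t) for t in (("a", "b") if plan.retained[i] else (plan.ancestral_copy[i],))]
            elif plan.present[sp][i]:
                ids = [gene_id(sp, i, "")]
                if plan.duplicated[sp][i]:
                    ids.append(gene_id(sp, i, "", dup=True))
            else:
                ids = []
            if ids:
                orthologs[sp] = tuple(ids)
        if plan.retained[i]:
            pairs.append(
                OhnologPair(pid, gene_id(plan.focal, i, "a"), gene_id(plan.focal, i, "b"), orthologs)
            )
        else:
            singles.append(
                Singleton(pid, gene_id(plan.focal, i, plan.ancestral_copy[i]), orthologs)
            )
    return pairs, singles


def orthogroup_map(plan: StudyPlan) -> Dict[str, str]:
    """gene id -> pillar id for every gene of every species."""
    out = {}
    for sp in plan.species:
        for pillar, _tag, gid in plan.genes_of(sp):
            out[gid] = f"P{pillar:05d}"
    return out


# ---------------------------------------------------------------------------
# expression


@dataclass
class SimExpression:
    focal_table: pd.DataFrame
    pka_vectors: Dict[str, pd.Series]
    stress: Dict[str, StressMatrix]
    pka_like_conditions: List[str]
    decoy_conditions: List[str]


def _latent_pka_vector(
    plan: StudyPlan, species: str, rng: np.random.Generator
) -> pd.Series:
    """True PKA-inhibition LFC response of one species' genes."""
    cfg = plan.config
    genes = plan.genes_of(species)
    values, index = [], []
    for pillar, tag, gid in genes:
        v = plan.esr_effect[pillar] + rng.normal(0.0, cfg.lfc_null_sd)
        if plan.roles[species] == "post" and plan.is_induced(species, pillar, gid):
            v = rng.normal(cfg.lfc_effect_high, cfg.lfc_noise_sd)
        index.append(gid)
        values.append(v)
    return pd.Series(values, index=index, dtype=float)


def generate_expression(
    config: SimConfig, plan: Optional[StudyPlan] = None
) -> SimExpression:
    """PKA-inhibition expression tables plus the stress compendium.

    The focal table has per-gene LFC, BH-adjusted p-value and regularized-log
    expression (control and treated).  Planted DE-pair high members draw LFC
    around ``lfc_effect_high`` with tiny adjusted p and low basal expression;
    their low partners and all non-WGH orthologs are unresponsive.  A shared
    environmental-stress-response (ESR) component gives the cross-species
    correlation structure.  Each species' stress matrix contains
    ``n_pka_like`` conditions correlated with that species' latent PKA
    response at the configured level, ``n_decoy`` weakly correlated
    conditions, and pure-noise conditions.
    """
    plan = plan or plan_study(config)
    cfg = config
    rng = config.rng(_STREAM_EXPRESSION)
    pka_vectors = {sp: _latent_pka_vector(plan, sp, rng) for sp in plan.species}
    focal = plan.focal
    lfc = pka_vectors[focal]
    rows = []
    means = dict(zip(("high", "low", "background"), cfg.basal_rlog_means))
    for pillar, tag, gid in plan.genes_of(focal):
        is_high = plan.is_induced(focal, pillar, gid)
        is_low = plan.de[pillar] and not is_high
        v = lfc[gid]
        if is_high:
            padj = 10.0 ** -rng.uniform(4.0, 10.0)
            rlog0 = rng.normal(means["high"], cfg.rlog_sd)
        else:
            # significance follows the true planted effect, not the noisy
            # draw: genes with a real shared-stress effect are significant,
            # pure-null genes get a uniform adjusted p
            if abs(plan.esr_effect[pillar]) > 1.0:
                padj = 10.0 ** -rng.uniform(2.0, 8.0)
            else:
                padj = rng.uniform(0.0, 1.0)
            rlog0 = rng.normal(means["low"] if is_low else means["background"], cfg.rlog_sd)
        rows.append(
            {
                "gene_id": gid,
                "lfc": v,
                "padj": padj,
                "rlog_control": rlog0,
                "rlog_treated": rlog0 + v,
            }
        )
    focal_table = pd.DataFrame(rows).set_index("gene_id")

    srng = config.rng(_STREAM_STRESS)
    cond_names = [f"cond{j:02d}" for j in range(cfg.n_stress_conditions)]
    pka_like = cond_names[: cfg.n_pka_like]
    decoys = cond_names[cfg.n_pka_like : cfg.n_pka_like + cfg.n_decoy]
    stress: Dict[str, StressMatrix] = {}
    for sp_i, sp in enumerate(plan.species):
        v = pka_vectors[sp].to_numpy()
        z = (v - v.mean()) / v.std()
        n_genes = len(v)
        cols = {}
        r_pka = cfg.stress_correlation if sp == focal else cfg.stress_correlation_secondary
        for j, cond in enumerate(cond_names):
            if cond in pka_like:
                r = r_pka
            elif cond in decoys:
                r = cfg.decoy_correlation
            else:
                r = 0.0
            noise = srng.normal(0.0, 1.0, n_genes)
            x = r * z + np.sqrt(max(1.0 - r * r, 0.0)) * noise
            if cfg.frac_stress_missing > 0:
                mask = srng.random(n_genes) < cfg.frac_stress_missing
                x = np.where(mask, np.nan, x)
            cols[cond] = x
        df = pd.DataFrame(cols, index=pka_vectors[sp].index)
        stress[sp] = StressMatrix(df, species=sp, normalized=False)
    return SimExpression(focal_table, pka_vectors, stress, pka_like, decoys)


def generate_replicates(
    config: SimConfig, plan: Optional[StudyPlan] = None
) -> Dict[str, pd.DataFrame]:
    """Raw-intensity microarray replicate matrices (with duplicate probes).

    Per species: one column per replicate on a linear intensity scale, with
    replicate-specific location/scale distortions (what quantile
    normalization undoes) and a fraction of genes spotted twice.
    """
    plan = plan or plan_study(config)
    cfg = config
    out = {}
    for sp_i, sp in enumerate(plan.species):
        rng = np.random.default_rng([cfg.seed, _STREAM_REPLICATES, sp_i])
        genes = [gid for _p, _t, gid in plan.genes_of(sp)]
        truth = rng.normal(8.0, 1.5, len(genes))
        names = list(genes)
        values = list(truth)
        n_dup = int(round(cfg.frac_duplicate_probes * len(genes)))
        for idx in rng.permutation(len(genes))[:n_dup]:
            names.append(genes[idx])
            values.append(truth[idx] + rng.normal(0.0, 0.2))
        values = np.asarray(values)
        cols = {}
        for r in range(cfg.n_replicates):
            shift = rng.normal(0.0, 0.5)
            scale = np.exp(rng.normal(0.0, 0.1))
            cols[f"rep{r}"] = 2.0 ** (scale * (values + rng.normal(0, 0.4, len(values))) + shift)
        out[sp] = pd.DataFrame(cols, index=pd.Index(names, name="gene_id"))
    return out


# ---------------------------------------------------------------------------
# GO map


def generate_go(
    config: SimConfig, plan: Optional[StudyPlan] = None
) -> Tuple[Dict[str, set], str]:
    """Focal-species GO map with one planted enriched term.

    Term ``T00`` is assigned to planted DE-pair members at
    ``go_enriched_rate`` and to everything at ``go_background_rate``; other
    terms are background-rate everywhere.  Returns (map, enriched term id).
    """
    plan = plan or plan_study(config)
    cfg = config
    rng = config.rng(_STREAM_GO)
    terms = [f"T{t:02d}" for t in range(cfg.n_go_terms)]
    enriched = terms[0] if terms else ""
    go: Dict[str, set] = {}
    for pillar, tag, gid in plan.genes_of(plan.focal):
        assigned = set()
        for t in terms:
            rate = cfg.go_background_rate
            if t == enriched and plan.de[pillar]:
                rate = cfg.go_enriched_rate
            if rng.random() < rate:
                assigned.add(t)
        go[gid] = assigned
    return go, enriched


# ---------------------------------------------------------------------------
# bundle + on-disk study


@dataclass
class SimStudy:
    config: SimConfig
    plan: StudyPlan
    genomes: Dict[str, Tuple[List[GeneModel], Dict[str, str]]]
    pairs: List[OhnologPair]
    singletons: List[Singleton]
    expression: SimExpression
    replicates: Dict[str, pd.DataFrame]
    go_map: Dict[str, set]
    enriched_term: str

    def promoters(self, species: str) -> Dict[str, Promoter]:
        models, seqs = self.genomes[species]
        return extract_promoters(models, seqs, self.config.promoter_length)

    def truth(self) -> dict:
        plan = self.plan
        n = self.config.n_pillars
        pillars = []
        for i in range(n):
            pillars.append(
                {
                    "pillar_id": f"P{i:05d}",
                    "retained": bool(plan.retained[i]),
                    "de": bool(plan.de[i]),
                    "mechanism": plan.mechanism[i],
                    "high_member": (
                        gene_id(plan.focal, i, plan.high_copy[i]) if plan.de[i] else ""
                    ),
                    "esr_effect": float(plan.esr_effect[i]),
                }
            )
        return {
            "seed": self.config.seed,
            "species": plan.species,
            "roles": plan.roles,
            "focal": plan.focal,
            "pillars": pillars,
            "pka_like_conditions": self.expression.pka_like_conditions,
            "decoy_conditions": self.expression.decoy_conditions,
            "enriched_term": self.enriched_term,
            "rate_mult": plan.rate_mult,
            "planted_stre_offsets": plan.stre_offsets,
        }


def simulate_study(config: SimConfig, with_genomes: bool = True) -> SimStudy:
    """Run every generator off one plan and bundle the results."""
    plan = plan_study(config)
    genomes = generate_genome(config, plan) if with_genomes else {}
    pairs, singles = generate_orthology(config, plan=plan)
    expression = generate_expression(config, plan)
    replicates = generate_replicates(config, plan)
    go_map, enriched = generate_go(config, plan)
    return SimStudy(
        config, plan, genomes, pairs, singles, expression, replicates, go_map, enriched
    )


def write_study(study: SimStudy, outdir) -> Dict[str, str]:
    """Write all study artifacts as plain-text files; returns path map."""
    from .annotation import write_annotation, write_fasta
    from .enrichment import write_go_map
    from .expression import write_matrix
    from .orthology import write_pillars

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}
    for sp, (models, seqs) in study.genomes.items():
        gff = outdir / f"{sp}.gff3"
        fasta = outdir / f"{sp}.fa"
        write_annotation(models, gff)
        write_fasta(seqs, fasta)
        paths[f"gff:{sp}"] = str(gff)
        paths[f"fasta:{sp}"] = str(fasta)
    pillars = outdir / "pillars.tsv"
    write_pillars(study.pairs, study.singletons, study.plan.species, study.plan.focal, pillars)
    paths["pillars"] = str(pillars)
    expr = outdir / "expression_focal.tsv"
    write_matrix(study.expression.focal_table, expr)
    paths["expression"] = str(expr)
    for sp, sm in study.expression.stress.items():
        p = outdir / f"stress_{sp}.tsv"
        write_matrix(sm.data, p)
        paths[f"stress:{sp}"] = str(p)
    for sp, reps in study.replicates.items():
        p = outdir / f"replicates_{sp}.tsv"
        write_matrix(reps, p)
        paths[f"replicates:{sp}"] = str(p)
    go = outdir / "go_map.tsv"
    write_go_map(study.go_map, go)
    paths["go"] = str(go)
    truth = outdir / "truth.json"
    with open(truth, "w") as fh:
        json.dump(study.truth(), fh, indent=1, sort_keys=True)
    paths["truth"] = str(truth)
    return paths
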