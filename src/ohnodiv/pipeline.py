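"""End-to-end orchestration of the ohnolog-divergence analysis.

Stages run in dependency order from a single seeded configuration:

1. ``simulate``   - write the synthetic study inputs (or load user inputs)
2. ``promoters``  - extract 700-bp promoters per species
3. ``scan``       - STRE/TATA motif tables per species
4. ``classify``   - DE categories, pair sorting, DE_PKA
5. ``stress``     - normalization, PKA-like condition selection, LFC_est,
                    DE_Stress and the cutoff-overlap curve
6. ``filter``     - the three promoter-subset filters
7. ``cluster``    - STRE-profile UPGMA + inconsistency flat clusters,
                    GO-indicator Ward clusters
8. ``enrich``     - GO, ohnolog and per-species STRE enrichment

Artifacts are plain TSV/JSON; a manifest records the config hash, seed and
per-stage row counts, and identical configurations yield byte-identical
artifact trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import write_promoters
from .cluster import (
    build_stre_profiles,
    correlation_distance_matrix,
    inconsistency_flat_clusters,
    linkage_table,
    to_newick,
    upgma,
    ward_go_clusters,
)
from .enrichment import (
    go_enrichment,
    ohnolog_enrichment,
    stre_enrichment_by_species,
)
from .expression import (
    collapse_duplicates,
    compute_lfc_est,
    quantile_normalize,
    select_pka_like,
    z_normalize_species,
)
from .motifs import DEFAULT_PATTERNS, build_motif_table, counts_for, read_patterns
from .pairclass import (
    Thresholds,
    category_counts,
    classification_table,
    classify_pairs,
    cutoff_overlap_curve,
    define_de_pka,
    define_de_stress,
)
from .orthology import filter_promoter_subset
from .simulate import SimConfig, simulate_study, write_study

log = logging.getLogger("ohnodiv")


@dataclass
class RunConfig:
    """Everything one full run needs; serializable to/from YAML."""

    outdir: str
    seed: int = 0
    sim: Dict = field(default_factory=dict)
    thresholds: Dict = field(default_factory=dict)
    both_strands: bool = False
    pattern_file: Optional[str] = None
    cluster_t: float = 1.1
    low_max_grid: Sequence[float] = (0.3, 0.6, 0.9, 1.2, 1.5, 1e9)
    activated_min_grid: Sequence[float] = (1.5,)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def thresholds_obj(self) -> Thresholds:
        return Thresholds(**self.thresholds)

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # analysis identity, not artifact location
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> Dict[str, object]:
    """Execute every stage; returns in-memory results keyed by stage."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds_obj()
    counts: Dict[str, int] = {}
    results: Dict[str, object] = {}

    def stage(name):
        log.info("stage %s", name)

    # 1. simulate ----------------------------------------------------------
    stage("simulate")
    study = simulate_study(config.sim_config())
    write_study(study, out / "inputs")
    plan = study.plan
    counts["pillars"] = config.sim_config().n_pillars
    counts["pairs"] = len(study.pairs)
    results["study"] = study

    # 2-3. promoters + motif scan -----------------------------------------
    stage("promoters/scan")
    patterns = (
        read_patterns(config.pattern_file) if config.pattern_file else DEFAULT_PATTERNS
    )
    motif_tables = {}
    stre_counts = {}
    for sp in plan.species:
        promoters = study.promoters(sp)
        write_promoters(promoters, out / f"promoters_{sp}.fa")
        table = build_motif_table(
            {g: p.sequence for g, p in promoters.items()},
            patterns,
            both_strands=config.both_strands,
        )
        table.to_csv(out / f"motifs_{sp}.tsv", sep="\t", index=False)
        motif_tables[sp] = table
        stre_counts[sp] = counts_for(table, "STRE").to_dict()
    counts["promoters_focal"] = len(stre_counts[plan.focal])
    results["motif_tables"] = motif_tables
    results["stre_counts"] = stre_counts

    # 4. classification ----------------------------------------------------
    stage("classify")
    classified = classify_pairs(study.pairs, study.expression.focal_table, th)
    classified = define_de_pka(classified)
    de_pka = [rec for rec in classified if rec.in_de_pka]
    classification_table(classified).to_csv(out / "pair_classification.tsv", sep="\t", index=False)
    with open(out / "category_counts.json", "w") as fh:
        json.dump(category_counts(classified), fh, indent=1, sort_keys=True)
    counts["pairs_classified"] = len(classified)
    counts["de_pka"] = len(de_pka)
    results["classified"] = classified
    results["de_pka"] = de_pka

    # 5. stress ------------------------------------------------------------
    stage("stress")
    # microarray replicates: quantile normalize, then median-collapse
    # duplicate probes to one row per gene
    for sp, reps in study.replicates.items():
        collapsed = collapse_duplicates(quantile_normalize(reps))
        collapsed.to_csv(out / f"replicates_collapsed_{sp}.tsv", sep="\t",
                         float_format="%.6g")
    counts["replicate_rows_collapsed"] = sum(
        len(collapse_duplicates(r)) for r in study.replicates.values()
    )
    normalized = {sp: z_normalize_species(sm) for sp, sm in study.expression.stress.items()}
    reference_species = [plan.focal] + [
        sp for sp in plan.species if plan.roles[sp] != "post"
    ][:1]
    pka_vectors = {sp: study.expression.pka_vectors[sp] for sp in reference_species}
    selected, corr_report = select_pka_like(normalized, pka_vectors)
    corr_report.to_csv(out / "condition_selection.tsv", sep="\t", index=False)
    results["pka_like_selected"] = selected
    counts["pka_like_conditions"] = len(selected)
    lfc_est = (
        compute_lfc_est(normalized[plan.focal], selected)["lfc_est"]
        if selected
        else pd.Series(dtype=float)
    )
    lfc_est.to_frame().to_csv(out / "lfc_est_focal.tsv", sep="\t")
    de_stress, stress_stats = define_de_stress(study.pairs, lfc_est.to_dict(), th)
    overlap = cutoff_overlap_curve(
        study.pairs,
        lfc_est.to_dict(),
        {rec.pair.pillar_id for rec in de_pka},
        config.low_max_grid,
        config.activated_min_grid,
        th,
    )
    overlap.to_csv(out / "cutoff_overlap.tsv", sep="\t", index=False)
    counts["de_stress"] = len(de_stress)
    results["de_stress"] = de_stress
    results["lfc_est"] = lfc_est

    # 6. promoter-subset filters ------------------------------------------
    stage("filter")
    nonwgh = [sp for sp in plan.species if plan.roles[sp] != "post"]
    retained, filter_report = filter_promoter_subset(
        de_pka, stre_counts[plan.focal], nonwgh
    )
    filter_report.to_csv(out / "promoter_subset_filters.tsv", sep="\t", index=False)
    counts["promoter_subset"] = len(retained)
    results["promoter_subset"] = retained

    # 7. clustering --------------------------------------------------------
    stage("cluster")
    profile_species = nonwgh  # non-WGH + outgroups enter the profiles
    results["cluster"] = None
    if len(retained) >= 2 and profile_species:
        profiles = build_stre_profiles(
            [rec.pair for rec in retained], stre_counts, profile_species
        )
        profiles.to_csv(out / "stre_profiles.tsv", sep="\t")
        if len(profiles) >= 2:
            D = correlation_distance_matrix(profiles)
            Z = upgma(D)
            labels = inconsistency_flat_clusters(Z, t=config.cluster_t)
            linkage_table(Z).to_csv(out / "stre_linkage.tsv", sep="\t", index=False)
            pd.DataFrame(
                {"pillar_id": profiles.index, "cluster": labels}
            ).to_csv(out / "stre_clusters.tsv", sep="\t", index=False)
            (out / "stre_dendrogram.nwk").write_text(
                to_newick(Z, list(profiles.index)) + "\n"
            )
            counts["stre_profile_rows"] = len(profiles)
            results["cluster"] = {"profiles": profiles, "Z": Z, "labels": labels}
    go_terms = sorted({t for ts in study.go_map.values() for t in ts})
    if de_pka and go_terms:
        Zg, glabels, vectors = ward_go_clusters(
            [rec.pair for rec in de_pka], study.go_map, go_terms
        )
        pd.DataFrame(
            {"pillar_id": vectors.index, "cluster": glabels}
        ).to_csv(out / "go_ward_clusters.tsv", sep="\t", index=False)

    # 8. enrichment --------------------------------------------------------
    stage("enrich")
    background = set(study.expression.focal_table.index)
    high_set = {rec.high_member for rec in de_pka}
    low_set = {rec.low_member for rec in de_pka}
    enr_high = go_enrichment(high_set, background, study.go_map) if high_set else pd.DataFrame()
    if len(enr_high):
        enr_high.to_csv(out / "go_enrichment_de_pka_high.tsv", sep="\t", index=False)
    enr_low = go_enrichment(low_set, background, study.go_map) if low_set else pd.DataFrame()
    if len(enr_low):
        enr_low.to_csv(out / "go_enrichment_de_pka_low.tsv", sep="\t", index=False)
    ohnolog_genes = {g for p in study.pairs for g in (p.member_a, p.member_b)}
    activated = {
        g
        for g in background
        if study.expression.focal_table.loc[g, "lfc"] > th.strong_lfc
        and study.expression.focal_table.loc[g, "padj"] <= th.fdr
    }
    p_ohno, tab = (
        ohnolog_enrichment(activated, background, ohnolog_genes)
        if activated
        else (float("nan"), None)
    )
    stre_enr = stre_enrichment_by_species(
        stre_counts,
        {sp: normalized[sp].data for sp in plan.species},
        lfc_min=th.species_activated_lfc,
    )
    stre_enr.to_csv(out / "stre_enrichment_by_species.tsv", sep="\t", index=False)
    results["ohnolog_enrichment_p"] = p_ohno
    results["stre_enrichment"] = stre_enr
    results["go_enrichment_high"] = enr_high

    # manifest -------------------------------------------------------------
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stage_counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
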