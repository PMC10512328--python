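"""Pillar parsing, alignment name-mapping, synteny and promoter filters."""

import random

import numpy as np
import pytest

from ohnodiv.annotation import GeneModel
from ohnodiv.orthology import (
    NameMapParams,
    OhnologPair,
    PillarFormatError,
    Singleton,
    align_score,
    assign_synteny,
    filter_promoter_subset,
    load_pillars,
    map_gene_names,
    retain_candidates,
    write_pillars,
)
from ohnodiv.simulate import gene_id, orthogroup_map, plan_study
from oracles import gotoh_score


class TestPillars:
    def test_round_trip_from_generator(self, tmp_path, study):
        path = tmp_path / "pillars.tsv"
        write_pillars(study.pairs, study.singletons, study.plan.species, "post0", path)
        pairs, singles = load_pillars(path, "post0")
        assert len(pairs) == len(study.pairs)
        assert len(singles) == len(study.singletons)
        by_id = {p.pillar_id: p for p in pairs}
        for orig in study.pairs:
            got = by_id[orig.pillar_id]
            assert {got.member_a, got.member_b} == {orig.member_a, orig.member_b}
            assert dict(got.orthologs) == dict(orig.orthologs)

    def test_two_focal_entries_make_a_pair(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("pillar_id\tS_1\tS_2\tK\nP1\tA1\tA2\tK1\nP2\tA3\t\tK2\n")
        pairs, singles = load_pillars(path, "S")
        assert pairs == [OhnologPair("P1", "A1", "A2", {"K": ("K1",)})]
        assert singles == [Singleton("P2", "A3", {"K": ("K2",)})]

    def test_more_than_two_focal_entries_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("pillar_id\tS_1\tS_2\tK\nP9\tA1,A2\tA3\tK1\n")
        with pytest.raises(PillarFormatError, match="P9"):
            load_pillars(path, "S")

    def test_every_gene_in_exactly_one_pillar(self, study):
        seen = []
        for p in study.pairs:
            seen += [p.member_a, p.member_b]
            for ids in p.orthologs.values():
                seen += list(ids)
        for s in study.singletons:
            seen.append(s.gene_id)
            for ids in s.orthologs.values():
                seen += list(ids)
        assert len(seen) == len(set(seen))
        annotated = {
            m.gene_id for sp in study.genomes for m in study.genomes[sp][0]
        }
        assert set(seen) == annotated

    def test_identical_members_rejected(self):
        with pytest.raises(ValueError):
            OhnologPair("P0", "A", "A")


class TestAlignScore:
    def test_identity(self):
        assert align_score("ACDEFGHIKL", "ACDEFGHIKL") == 10.0

    def test_single_gap(self):
        assert align_score("ACD", "AD") == 1.5

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_score("", "ACD")

    def test_symmetry_random_pairs(self):
        rng = random.Random(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(100):
            s1 = "".join(rng.choice(aa) for _ in range(rng.randint(1, 30)))
            s2 = "".join(rng.choice(aa) for _ in range(rng.randint(1, 30)))
            assert align_score(s1, s2) == align_score(s2, s1)

    def test_matches_quadratic_dp_oracle(self):
        rng = random.Random(4)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(150):
            s1 = "".join(rng.choice(aa) for _ in range(rng.randint(1, 50)))
            s2 = "".join(rng.choice(aa) for _ in range(rng.randint(1, 50)))
            assert align_score(s1, s2) == pytest.approx(gotoh_score(s1, s2), abs=1e-9)


class TestRetention:
    def test_small_drops_retained_until_big_drop(self):
        # drops of 5 then 15: keep the first two
        assert retain_candidates([150, 145, 130]) == [0, 1]

    def test_single_candidate(self):
        assert retain_candidates([150]) == [0]

    def test_empty(self):
        assert retain_candidates([]) == []

    def test_drop_from_top_variant(self):
        # consecutive: 150->145->141 drops 5,4 -> all kept;
        # from top: 150-141 = 9 < 10 -> also kept; 150->139 (drop 11) cut
        assert retain_candidates([150, 145, 141], drop_from="previous") == [0, 1, 2]
        assert retain_candidates([150, 145, 139], drop_from="top") == [0, 1]
        assert retain_candidates([150, 145, 139], drop_from="previous") == [0, 1, 2]

    def test_map_gene_names_threshold_and_prefix(self):
        queries = {"q1": "MKVLAAGGHHII"}
        targets = {
            "t_exact": "MKVLAAGGHHII",
            "t_close": "MKVLAAGGHHIV",
            "t_far": "WWWWCCCC",
        }
        params = NameMapParams(score_threshold=5.0)
        res = map_gene_names(queries, targets, params)
        cand_ids = [t for t, _ in res["q1"]["candidates"]]
        assert cand_ids[0] == "t_exact"
        assert "t_far" not in cand_ids
        # retained list is a prefix of the candidate list
        assert res["q1"]["retained"] == cand_ids[: len(res["q1"]["retained"])]

    def test_below_threshold_maps_to_empty(self):
        res = map_gene_names({"q": "MKV"}, {"t": "WWW"}, NameMapParams(score_threshold=120.0))
        assert res["q"]["candidates"] == [] and res["q"]["retained"] == []


@pytest.fixture(scope="module")
def two_postwgh():
    from ohnodiv.simulate import SimConfig, simulate_study

    cfg = SimConfig(
        seed=23,
        n_species=3,
        n_postwgh_species=2,
        n_pillars=100,
        frac_retained_pairs=0.4,
        scaffold_length=120_000,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="module")
def big_two_postwgh():
    # large enough that random 16-gene flanks rarely share 2+ orthogroups
    from ohnodiv.simulate import SimConfig, simulate_study

    cfg = SimConfig(
        seed=29,
        n_species=2,
        n_postwgh_species=2,
        n_pillars=1000,
        frac_retained_pairs=0.4,
        n_scaffolds=2,
        scaffold_length=800_000,
        plant_motifs=False,
    )
    return simulate_study(cfg)


class TestSynteny:

    def test_conserved_order_assigns_true_lineage(self, two_postwgh):
        study = two_postwgh
        plan = study.plan
        groups = orthogroup_map(plan)
        focal_models = study.genomes["post0"][0]
        other_models = study.genomes["post1"][0]
        pairs = {p.pillar_id: p for p in study.pairs}
        n_checked = n_correct = 0
        for i in np.flatnonzero(plan.retained)[:30]:
            pair = pairs[f"P{i:05d}"]
            for tag, side in (("a", "member_a"), ("b", "member_b")):
                gid = gene_id("post1", int(i), tag)
                res = assign_synteny(gid, pair, other_models, focal_models, groups)
                n_checked += 1
                n_correct += res.assigned_to == side
        assert n_checked == 60
        assert n_correct == n_checked

    def test_shuffled_order_mostly_undetermined(self, big_two_postwgh):
        study = big_two_postwgh
        plan = study.plan
        groups = orthogroup_map(plan)
        focal_models = study.genomes["post0"][0]
        models = study.genomes["post1"][0]
        rng = np.random.RandomState(0)
        # permute which gene sits at which locus, destroying synteny
        ids = [m.gene_id for m in models]
        perm = rng.permutation(len(ids))
        shuffled = [
            GeneModel(ids[perm[k]], m.scaffold, m.start, m.end, m.strand)
            for k, m in enumerate(models)
        ]
        pairs = {p.pillar_id: p for p in study.pairs}
        results = []
        for i in np.flatnonzero(plan.retained)[:25]:
            pair = pairs[f"P{i:05d}"]
            res = assign_synteny(gene_id("post1", int(i), "a"), pair, shuffled, focal_models, groups)
            results.append(res.assigned_to)
        undet = results.count("undetermined")
        assert undet / len(results) >= 0.9

    def test_tie_support_is_undetermined(self):
        # two identical single-gene contexts -> tied support 0/0
        focal = [
            GeneModel("fa", "s1", 0, 10, "+"),
            GeneModel("fb", "s2", 0, 10, "+"),
        ]
        other = [GeneModel("x", "s3", 0, 10, "+")]
        pair = OhnologPair("P0", "fa", "fb")
        res = assign_synteny("x", pair, other, focal, {})
        assert res.assigned_to == "undetermined"


class _Rec:
    def __init__(self, pair, high):
        self.pair = pair
        self.high_member = high


class TestPromoterSubsetFilters:
    def make(self, pid, high_count, dup_species=0, n_orth=3):
        orthologs = {}
        for i in range(max(n_orth, dup_species)):
            ids = ("x%d" % i, "y%d" % i) if i < dup_species else ("x%d" % i,)
            orthologs[f"sp{i}"] = ids
        pair = OhnologPair(pid, f"{pid}_a", f"{pid}_b", orthologs)
        return _Rec(pair, f"{pid}_a"), {f"{pid}_a": high_count}

    def test_zero_stre_high_member_removed(self):
        rec, counts = self.make("P1", 0)
        kept, report = filter_promoter_subset([rec], counts, [f"sp{i}" for i in range(9)])
        assert kept == []
        assert "no_stre_in_high_member" in report["removed_by"].iloc[0]

    def test_duplicated_in_more_than_eight_species_removed(self):
        rec, counts = self.make("P2", 2, dup_species=9, n_orth=9)
        kept, report = filter_promoter_subset([rec], counts, [f"sp{i}" for i in range(9)])
        assert kept == []
        assert "duplicated_in_many_species" in report["removed_by"].iloc[0]

    def test_duplicated_in_exactly_eight_species_kept(self):
        rec, counts = self.make("P3", 2, dup_species=8, n_orth=8)
        kept, _ = filter_promoter_subset([rec], counts, [f"sp{i}" for i in range(8)])
        assert len(kept) == 1

    def test_no_nonwgh_ortholog_removed(self):
        rec, counts = self.make("P4", 2, n_orth=0)
        kept, report = filter_promoter_subset([rec], counts, ["spA"])
        assert kept == []
        assert "no_nonwgh_ortholog" in report["removed_by"].iloc[0]

    def test_missing_promoter_counted_separately(self):
        rec, _ = self.make("P5", 1)
        kept, report = filter_promoter_subset([rec], {}, ["sp0"])
        assert kept == []
        assert report["removed_by"].iloc[0] == "missing_promoter"

    def test_retained_equals_brute_force_predicates(self, multispecies_study):
        study = multispecies_study
        plan = study.plan
        nonwgh = [sp for sp in plan.species if plan.roles[sp] != "post"]
        from ohnodiv.motifs import STRE, scan

        counts = {}
        for g, p in study.promoters("post0").items():
            counts[g] = len(scan(p.sequence, STRE))
        recs = []
        for i in np.flatnonzero(plan.de):
            pid = f"P{i:05d}"
            pair = next(p for p in study.pairs if p.pillar_id == pid)
            recs.append(_Rec(pair, gene_id("post0", int(i), plan.high_copy[i])))
        kept, _ = filter_promoter_subset(recs, counts, nonwgh)
        expected = {
            r.pair.pillar_id
            for r in recs
            if counts[r.high_member] > 0
            and sum(1 for sp in nonwgh if len(r.pair.orthologs.get(sp, ())) > 1) <= 8
            and sum(len(r.pair.orthologs.get(sp, ())) for sp in nonwgh) > 0
        }
        assert {r.pair.pillar_id for r in kept} == expected

    def test_filters_order_independent(self):
        # single pass applies all predicates at once; verify report lists all
        rec, counts = self.make("P6", 0, dup_species=9, n_orth=9)
        kept, report = filter_promoter_subset([rec], counts, [f"sp{i}" for i in range(9)])
        assert kept == []
        assert set(report["removed_by"].iloc[0].split(";")) == {
            "no_stre_in_high_member",
            "duplicated_in_many_species",
        }
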