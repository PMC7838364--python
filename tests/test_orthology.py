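"""Reciprocal best hits (with double-argmax oracle) and orthogroup
components."""

import numpy as np
import pandas as pd
import pytest

from oilseednet.orthology import (build_orthogroups, map_gene_sets,
                                  reciprocal_best_hits)
from oilseednet.simulate import (PlantedModule, SimConfig, simulate_expression,
                                 simulate_similarity_table)


def hit_table(rows):
    """rows: (query, subject, qsp, ssp, score[, identity])"""
    recs = []
    for row in rows:
        q, s, qsp, ssp, score = row[:5]
        ident = row[5] if len(row) > 5 else 0.9
        recs.append((q, s, qsp, ssp, float(score), ident, 0.9))
    return pd.DataFrame(recs, columns=["query", "subject", "query_species",
                                       "subject_species", "score",
                                       "identity", "coverage"])


def rbh_oracle(scores_ab: np.ndarray) -> set[tuple[int, int]]:
    """Brute-force double-argmax RBH on a symmetric-score matrix: pair (i,j)
    iff j is the unique argmax of row i and i the unique argmax of column
    j."""
    pairs = set()
    n_a, n_b = scores_ab.shape
    for i in range(n_a):
        row = scores_ab[i]
        j = int(row.argmax())
        if (row == row[j]).sum() > 1:
            continue
        col = scores_ab[:, j]
        if (col == col.max()).sum() > 1:
            continue
        if int(col.argmax()) == i:
            pairs.add((i, j))
    return pairs


class TestReciprocalBestHits:
    def test_mutual_best_hit_pairs(self):
        hits = hit_table([("A1", "B1", "a", "b", 50),
                          ("B1", "A1", "b", "a", 50)])
        assert reciprocal_best_hits(hits, "a", "b") == {("A1", "B1")}

    def test_tied_best_hit_disqualifies(self):
        hits = hit_table([("A1", "B1", "a", "b", 50, 0.9),
                          ("A1", "B2", "a", "b", 50, 0.9),
                          ("B1", "A1", "b", "a", 50),
                          ("B2", "A1", "b", "a", 40)])
        assert reciprocal_best_hits(hits, "a", "b") == set()

    def test_identity_breaks_score_tie(self):
        hits = hit_table([("A1", "B1", "a", "b", 50, 0.95),
                          ("A1", "B2", "a", "b", 50, 0.80),
                          ("B1", "A1", "b", "a", 50)])
        assert reciprocal_best_hits(hits, "a", "b") == {("A1", "B1")}

    def test_empty_table(self):
        assert reciprocal_best_hits(hit_table([]), "a", "b") == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(3, 21, size=2)
        scores = rng.integers(10, 200, size=(n_a, n_b)).astype(float)
        rows = []
        for i in range(n_a):
            for j in range(n_b):
                rows.append((f"A{i}", f"B{j}", "a", "b", scores[i, j], 0.9))
                rows.append((f"B{j}", f"A{i}", "b", "a", scores[i, j], 0.9))
        hits = hit_table(rows)
        got = reciprocal_best_hits(hits, "a", "b")
        expected = {(f"A{i}", f"B{j}") for i, j in rbh_oracle(scores)}
        assert got == expected
        # symmetry in species order
        flipped = {(a, b) for b, a in reciprocal_best_hits(hits, "b", "a")}
        assert flipped == got
        assert len(got) <= min(n_a, n_b)


class TestBuildOrthogroups:
    def test_two_disjoint_cliques(self):
        hits = hit_table([("A1", "B1", "a", "b", 100),
                          ("B1", "A1", "b", "a", 100),
                          ("A2", "B2", "a", "b", 90),
                          ("B2", "A2", "b", "a", 90)])
        groups = build_orthogroups(hits, ["a", "b"], score_floor=0.5)
        assert sorted(map(sorted, groups)) == [["A1", "B1"], ["A2", "B2"]]

    def test_paralog_pair_forms_three_gene_group(self):
        hits = hit_table([("A1", "B1", "a", "b", 100),
                          ("A1b", "B1", "a", "b", 95),
                          ("B1", "A1", "b", "a", 100)])
        groups = build_orthogroups(hits, ["a", "b"], score_floor=0.5)
        assert sorted(map(sorted, groups)) == [["A1", "A1b", "B1"]]

    def test_floor_above_all_scores_gives_singletons(self):
        hits = hit_table([("A1", "B1", "a", "b", 100),
                          ("B1", "A1", "b", "a", 100)])
        groups = build_orthogroups(hits, ["a", "b"], score_floor=2.0)
        assert sorted(map(sorted, groups)) == [["A1"], ["B1"]]

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError, match="score_floor"):
            build_orthogroups(hit_table([]), ["a", "b"], score_floor=-0.1)

    def test_output_partitions_all_table_genes(self):
        _, truth = simulate_expression(SimConfig(
            n_species=3, n_background_genes=40,
            planted_modules=(PlantedModule(10, "bell", 0.8),),
            de_genes=(), seed=2))
        hits = simulate_similarity_table(truth, decoy_rate=0.3, seed=4)
        groups = build_orthogroups(hits, truth.species)
        covered = sorted(g for grp in groups for g in grp)
        assert covered == sorted(set(hits["query"]) | set(hits["subject"]))
        assert len(covered) == len(set(covered))   # disjoint cover


class TestMapGeneSets:
    def species_of(self, genes):
        return {g: g.split("_")[0] for g in genes}

    def test_fully_covered_group_is_shared(self):
        groups = [frozenset({"a_1", "b_1", "c_1"})]
        sets = {"a": {"a_1"}, "b": {"b_1"}, "c": {"c_1"}}
        shared, flags = map_gene_sets(groups, sets,
                                      self.species_of(["a_1", "b_1", "c_1"]))
        assert len(shared) == 1 and all(flags.values())

    def test_two_of_three_species_not_shared(self):
        groups = [frozenset({"a_1", "b_1", "c_1"})]
        sets = {"a": {"a_1"}, "b": {"b_1"}, "c": {"c_9"}}
        species_of = self.species_of(["a_1", "b_1", "c_1", "c_9"])
        shared, flags = map_gene_sets(groups, sets, species_of)
        assert shared == [] and not flags["a_1"]

    def test_planted_shared_groups_recovered_exactly(self):
        rng = np.random.default_rng(0)
        groups, sets = [], {"a": set(), "b": set(), "c": set()}
        species_of = {}
        for i in range(30):
            members = {f"a_{i}", f"b_{i}", f"c_{i}"}
            groups.append(frozenset(members))
            for g in members:
                species_of[g] = g.split("_")[0]
            if i < 10:                       # planted shared groups
                for sp in sets:
                    sets[sp].add(f"{sp}_{i}")
            else:                            # decoys: only one species' set
                sets["a"].add(f"a_{i}")
        shared, _ = map_gene_sets(groups, sets, species_of)
        assert len(shared) == 10

    def test_species_missing_from_groups_rejected(self):
        groups = [frozenset({"a_1", "b_1"})]
        sets = {"a": {"a_1"}, "z": {"z_1"}}
        with pytest.raises(ValueError, match="absent"):
            map_gene_sets(groups, sets, self.species_of(["a_1", "b_1"]))
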