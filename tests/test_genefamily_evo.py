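"""Orthology, pseudogene discovery, phyletic patterns, Sankoff parsimony."""

import numpy as np
import pandas as pd
import pytest

from crossimmune.io import tree_from_string
from crossimmune.genefamily_evo import (
    augment_orthogroups,
    benchmark_false_positives,
    brute_force_parsimony,
    compile_phyletic_pattern,
    detect_putative_pseudogenes,
    merge_family_hits,
    reciprocal_best_hits,
    sankoff_ancestral,
)
from crossimmune.synthetic_data import simulate_homology_tables


def _hit(q, s, pident, evalue, bitscore=100.0):
    return {
        "qseqid": q, "sseqid": s, "pident": pident, "length": 100,
        "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": 100,
        "sstart": 1, "send": 100, "evalue": evalue, "bitscore": bitscore,
    }


class TestReciprocalBestHits:
    def test_noiseless_tables_recover_planted_orthologs_exactly(self):
        ab, ba, _, _, truth = simulate_homology_tables(
            {"KLRA": 5, "MHC-I": 4}, identity_noise=0.0, seed=1
        )
        pairs = reciprocal_best_hits(ab, ba)
        assert dict(zip(pairs.gene_a, pairs.gene_b)) == truth.ortholog_map

    def test_identity_exactly_eighty_excluded(self):
        ab = pd.DataFrame([_hit("a.t1", "b.t1", 80.0, 1e-40)])
        ba = pd.DataFrame([_hit("b.t1", "a.t1", 80.0, 1e-40)])
        assert len(reciprocal_best_hits(ab, ba)) == 0
        ab.loc[0, "pident"] = 80.01
        ba.loc[0, "pident"] = 80.01
        assert len(reciprocal_best_hits(ab, ba)) == 1

    def test_symmetric_in_table_order(self):
        ab, ba, _, _, _ = simulate_homology_tables(
            {"KLRA": 4, "KLRB": 3}, identity_noise=1.0, seed=2
        )
        fwd = reciprocal_best_hits(ab, ba)
        rev = reciprocal_best_hits(ba, ab)
        fwd_pairs = {frozenset(p) for p in zip(fwd.gene_a, fwd.gene_b)}
        rev_pairs = {frozenset(p) for p in zip(rev.gene_a, rev.gene_b)}
        assert fwd_pairs == rev_pairs

    def test_empty_tables_give_empty_result(self):
        empty = pd.DataFrame([_hit("a.t1", "b.t1", 90, 1e-5)]).iloc[:0]
        assert len(reciprocal_best_hits(empty, empty)) == 0


class TestAugmentOrthogroups:
    ORTHOGROUPS = pd.DataFrame(
        {"gene_id": ["klra_1", "klra_2", "mhc_1"],
         "family": ["KLRA", "KLRA", "MHC-I"]}
    )

    def test_strong_hit_joins_family(self):
        hits = pd.DataFrame([_hit("ps1.t1", "klra_1.t1", 92.0, 1e-20)])
        out = augment_orthogroups(self.ORTHOGROUPS, hits)
        assert out.set_index("gene_id").loc["ps1", "family"] == "KLRA"

    def test_weak_identity_stays_unassigned(self):
        hits = pd.DataFrame([_hit("ps1.t1", "klra_1.t1", 75.0, 1e-20)])
        out = augment_orthogroups(self.ORTHOGROUPS, hits)
        assert "ps1" not in set(out.gene_id)

    def test_two_family_conflict_resolved_by_evalue_and_tie_flagged(self):
        hits = pd.DataFrame(
            [
                _hit("ps1.t1", "klra_1.t1", 90.0, 1e-30),
                _hit("ps1.t1", "mhc_1.t1", 90.0, 1e-10),
                _hit("ps2.t1", "klra_1.t1", 88.0, 1e-10),
                _hit("ps2.t1", "mhc_1.t1", 88.0, 1e-10),
            ]
        )
        out = augment_orthogroups(self.ORTHOGROUPS, hits).set_index("gene_id")
        assert out.loc["ps1", "family"] == "KLRA"
        assert not out.loc["ps1", "ambiguous"]
        assert out.loc["ps2", "ambiguous"]


class TestPutativePseudogenes:
    def _genomic(self, rows):
        return pd.DataFrame(
            rows,
            columns=["qseqid", "family", "scaffold", "start", "end", "pident",
                     "domain_evalue", "domain_pident"],
        )

    def _annotations(self):
        return pd.DataFrame(
            {
                "species": ["nmr"], "gene_id": ["klra_1"], "symbol": ["Klra1"],
                "family": ["KLRA"], "biotype": ["protein_coding"],
                "scaffold": ["scafA"], "start": [10_000], "end": [12_000],
            }
        )

    def test_intergenic_decayed_locus_emitted(self):
        hits = self._genomic(
            [("q.t1", "KLRA", "scafA", 50_000, 50_900, 55.0, 1e-5, 70.0)]
        )
        out = detect_putative_pseudogenes(hits, self._annotations())
        assert len(out) == 1
        assert out.iloc[0].biotype == "putative_pseudogene"

    def test_hit_overlapping_annotated_gene_never_emitted(self):
        hits = self._genomic(
            [("q.t1", "KLRA", "scafA", 11_500, 12_400, 55.0, 1e-5, 70.0)]
        )
        assert len(detect_putative_pseudogenes(hits, self._annotations())) == 0

    def test_domain_confirmation_thresholds_enforced(self):
        rows = [
            ("q.t1", "KLRA", "scafA", 50_000, 50_900, 55.0, 0.1, 70.0),   # e too high
            ("q.t1", "KLRA", "scafA", 60_000, 60_900, 55.0, 1e-5, 60.0),  # id too low
            ("q.t1", "KLRA", "scafA", 70_000, 70_900, 39.0, 1e-5, 70.0),  # id < 40
        ]
        assert len(detect_putative_pseudogenes(self._genomic(rows),
                                               self._annotations())) == 0

    def test_off_locus_scaffold_excluded(self):
        hits = self._genomic(
            [("q.t1", "KLRA", "other_scaf", 50_000, 50_900, 55.0, 1e-5, 70.0)]
        )
        assert len(detect_putative_pseudogenes(hits, self._annotations())) == 0

    def test_excluded_families_never_emit(self):
        ann = self._annotations().assign(family="KIR")
        hits = self._genomic(
            [("q.t1", "KIR", "scafA", 50_000, 50_900, 55.0, 1e-5, 70.0)]
        )
        assert len(detect_putative_pseudogenes(hits, ann)) == 0

    def test_overlapping_same_family_hits_merge_to_interval_union(self):
        rows = [
            ("q1.t1", "KLRA", "scafA", 100, 400, 55.0, 1e-5, 70.0),
            ("q2.t1", "KLRA", "scafA", 300, 600, 50.0, 1e-7, 65.0),
        ]
        merged = merge_family_hits(self._genomic(rows))
        assert len(merged) == 1
        assert (merged.iloc[0].start, merged.iloc[0].end) == (100, 600)
        assert merged.iloc[0].domain_evalue == 1e-7
        assert merged.iloc[0].domain_pident == 70.0

    def test_merging_is_idempotent(self):
        rows = [
            ("q1.t1", "KLRA", "scafA", 100, 400, 55.0, 1e-5, 70.0),
            ("q2.t1", "KLRA", "scafA", 300, 600, 50.0, 1e-7, 65.0),
            ("q3.t1", "MHC-I", "scafB", 100, 200, 45.0, 1e-3, 75.0),
        ]
        once = merge_family_hits(self._genomic(rows))
        twice = merge_family_hits(once.drop(columns="n_queries").assign(qseqid="m"))
        pd.testing.assert_frame_equal(
            once[["family", "scaffold", "start", "end"]],
            twice[["family", "scaffold", "start", "end"]],
        )

    def test_missing_coordinates_rejected(self):
        hits = self._genomic(
            [("q.t1", "KLRA", "scafA", np.nan, 50_900, 55.0, 1e-5, 70.0)]
        )
        with pytest.raises(ValueError):
            detect_putative_pseudogenes(hits, self._annotations())


class TestFalsePositiveBenchmark:
    def test_all_own_family_hits_give_zero(self):
        _, _, gh, ann, _ = simulate_homology_tables(
            {"KLRA": 8, "KLRB": 6}, cross_family_hit_fraction=0.0, seed=3
        )
        out = benchmark_false_positives(gh, ann)
        covered = out[out.n_covering_hits > 0]
        assert (covered.fp_fraction == 0).all()

    def test_planted_confusion_fraction_recovered(self):
        _, _, gh, ann, truth = simulate_homology_tables(
            {"KLRA": 40, "KLRB": 40}, cross_family_hit_fraction=0.25, seed=4
        )
        out = benchmark_false_positives(gh, ann)
        out = out[out.search_species == "nmr"]
        measured = out.n_false_positive.sum() / out.n_covering_hits.sum()
        assert measured == pytest.approx(truth.confusion_fraction, abs=0.02)

    def test_families_at_threshold_flagged(self):
        _, _, gh, ann, _ = simulate_homology_tables(
            {"KLRA": 30, "KLRB": 30}, cross_family_hit_fraction=0.4, seed=5
        )
        out = benchmark_false_positives(gh, ann)
        assert out[(out.search_species == "nmr") & (out.fp_fraction >= 0.05)].flagged.all()


class TestPhyleticPattern:
    def _annotations(self):
        rows = []
        for i in range(3):
            rows.append(dict(species="mouse", gene_id=f"m{i}", symbol=None,
                             family="KLRA", biotype="protein_coding",
                             scaffold="s", start=i, end=i + 1))
        rows.append(dict(species="mouse", gene_id="mps", symbol=None,
                         family="KLRA", biotype="annotated_pseudogene",
                         scaffold="s", start=9, end=10))
        rows.append(dict(species="mouse", gene_id="psi0", symbol=None,
                         family="KLRA", biotype="putative_pseudogene",
                         scaffold="s", start=20, end=21))
        rows.append(dict(species="mouse", gene_id="kir_psi", symbol=None,
                         family="KIR", biotype="putative_pseudogene",
                         scaffold="s", start=30, end=31))
        return pd.DataFrame(rows)

    def test_counts_split_by_biotype_and_totals_conserved(self):
        pat = compile_phyletic_pattern(
            self._annotations(), ["mouse", "nmr"], ["KLRA", "KIR"]
        )
        row = pat.set_index(["species", "family"]).loc[("mouse", "KLRA")]
        assert (row.P, row.Psi, row.psi) == (3, 1, 1)
        assert (pat.total == pat.P + pat.Psi + pat.psi).all()

    def test_putative_counts_zeroed_for_excluded_families(self):
        pat = compile_phyletic_pattern(
            self._annotations(), ["mouse"], ["KIR"]
        ).iloc[0]
        assert pat.psi == 0

    def test_missing_species_gets_explicit_zeros(self):
        pat = compile_phyletic_pattern(self._annotations(), ["nmr"], ["KLRA"]).iloc[0]
        assert (pat.P, pat.Psi, pat.psi, pat.total) == (0, 0, 0, 0)


def _random_tree_and_counts(rng, max_tips=6, max_count=4):
    n_tips = int(rng.integers(3, max_tips + 1))
    labels = [f"t{i}" for i in range(n_tips)]
    # random topology by sequential joining
    nodes = [f"{l}:1" for l in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        merged = f"({nodes[i]},{nodes[j]}):1"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    counts = {l: int(rng.integers(0, max_count + 1)) for l in labels}
    return tree_from_string(newick), counts


class TestSankoff:
    def test_constant_tips_reconstruct_certainly(self):
        tree = tree_from_string("((A,B),(C,D));")
        res = sankoff_ancestral(tree, {t: 2 for t in "ABCD"})
        assert res.min_cost == 0
        for node, state in res.map_state.items():
            assert state == 2
            assert res.node_probabilities(node)[2] == 1.0

    def test_balanced_split_has_cooptimal_root_range(self):
        # tips (0,0,3,3): any root state 0..3 achieves the minimal cost 3
        tree = tree_from_string("((A,B),(C,D));")
        res = sankoff_ancestral(tree, {"A": 0, "B": 0, "C": 3, "D": 3})
        assert res.min_cost == 3
        root = tree.seed_node.label
        opt = res.states[(res.states.node == root) & res.states.optimal]
        assert set(opt.state) == {0, 1, 2, 3}
        np.testing.assert_allclose(opt.probability, 0.25)

    def test_probabilities_sum_to_one_per_node(self):
        tree = tree_from_string("((A,B),((C,D),E));")
        res = sankoff_ancestral(tree, {"A": 1, "B": 4, "C": 0, "D": 2, "E": 3})
        sums = res.states.groupby("node").probability.sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_missing_leaf_count_rejected(self):
        tree = tree_from_string("(A,B);")
        with pytest.raises(ValueError):
            sankoff_ancestral(tree, {"A": 1})

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            tree, counts = _random_tree_and_counts(rng)
            res = sankoff_ancestral(tree, counts)
            tree2 = tree_from_string(tree.as_string(schema="newick"))
            bf_cost, bf_assignments = brute_force_parsimony(tree2, counts)
            assert res.min_cost == bf_cost
            # per-node co-optimal state sets agree with enumerated optima
            for node in res.map_state:
                dp_opt = set(
                    res.states[(res.states.node == node) & res.states.optimal].state
                )
                bf_opt = {a[node] for a in bf_assignments if node in a}
                if bf_opt:
                    assert dp_opt == bf_opt

    def test_cost_invariant_to_rerooting(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            tree, counts = _random_tree_and_counts(rng)
            cost1 = sankoff_ancestral(tree, counts).min_cost
            tree.reroot_at_midpoint()
            cost2 = sankoff_ancestral(tree, counts).min_cost
            assert cost1 == cost2


class TestBruteForce:
    def test_single_edge_path_metric(self):
        tree = tree_from_string("(A,B);")
        cost, _ = brute_force_parsimony(tree, {"A": 3, "B": 1})
        assert cost == 2

    def test_constant_tips_cost_zero(self):
        tree = tree_from_string("((A,B),C);")
        cost, _ = brute_force_parsimony(tree, {"A": 1, "B": 1, "C": 1})
        assert cost == 0

    def test_size_guard(self):
        tree = tree_from_string("(A,B);")
        with pytest.raises(ValueError):
            brute_force_parsimony(tree, {"A": 9, "B": 0})
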