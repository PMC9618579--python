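"""DEG selection, set-algebra, enrichment-score and overlap-statistic tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from fibrophase import (
    Signature,
    multi_level_compare,
    overlap_analysis,
    preranked_es,
    screen_signatures,
    select_degs,
)
from fibrophase.overlap import EX_VIVO_RULE, parse_condition_label, parse_signature_name


def brute_force_es(ranked_genes, scores, members, weight):
    """Independent running-sum enumeration (plain Python loop)."""
    idx = np.argsort(-np.asarray(scores), kind="stable")
    genes = [ranked_genes[i] for i in idx]
    scores = [scores[i] for i in idx]
    nh = sum(g in members for g in genes)
    n = len(genes)
    nr = sum(abs(s) ** weight for g, s in zip(genes, scores) if g in members)
    run, best = 0.0, 0.0
    for g, s in zip(genes, scores):
        if g in members:
            run += (abs(s) ** weight / nr) if nr > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


def toy_table(fdrs, pvals=None, logfcs=None):
    n = len(fdrs)
    return pd.DataFrame(
        {
            "gene": [f"G{i}" for i in range(n)],
            "logFC": logfcs if logfcs is not None else [0.0] * n,
            "pvalue": pvals if pvals is not None else [0.5] * n,
            "fdr": list(fdrs),
        }
    )


class TestSelectDegs:
    def test_all_insignificant_gives_empty_set(self):
        assert select_degs(toy_table([1.0] * 4)) == set()

    def test_empty_table_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert select_degs(toy_table([])) == set()

    def test_fdr_boundary_is_inclusive(self):
        table = toy_table([0.01, 0.04, 0.05, 0.06, 0.5])
        assert select_degs(table, {"fdr": 0.05}) == {"G0", "G1", "G2"}

    def test_ex_vivo_rule_combines_thresholds(self):
        table = toy_table(
            fdrs=[0.5] * 4,
            pvals=[0.005, 0.005, 0.02, 0.005],
            logfcs=[1.5, 0.5, 2.0, -1.0],
        )
        # needs |logFC| >= 1 AND p <= 0.01 (both boundaries inclusive)
        assert select_degs(table, EX_VIVO_RULE) == {"G0", "G3"}

    def test_matches_per_row_brute_force(self, rng):
        n = 200
        table = toy_table(
            fdrs=rng.uniform(0, 1, n),
            pvals=rng.uniform(0, 1, n),
            logfcs=rng.normal(0, 2, n),
        )
        rule = {"fdr": 0.2, "p": 0.3, "abs_logfc": 1.0}
        got = select_degs(table, rule)
        expect = {
            row.gene
            for row in table.itertuples()
            if row.fdr <= 0.2 and row.pvalue <= 0.3 and abs(row.logFC) >= 1.0
        }
        assert got == expect

    def test_rejects_unknown_rule_key(self):
        with pytest.raises(ValueError):
            select_degs(toy_table([0.1]), {"lfc": 1})


class TestConditionParsing:
    def test_label_round_trip(self):
        fac = parse_condition_label("MI/CC/24H")
        assert fac == {
            "cell_type": "M", "stimulus": "I", "culture": "CC", "time": "24", "oxygen": "H",
        }

    def test_signature_name_parsing(self):
        parts = parse_signature_name("MIvsM0_CC/24H")
        assert parts["first"] == "MI" and parts["second"] == "M0"
        assert parts["context"] == ["CC", "24H"]

    def test_malformed_label_rejected(self):
        with pytest.raises(ValueError):
            parse_condition_label("whatever")


class TestMultiLevelCompare:
    SETS = {
        "MI/CC/24H": {"a", "b", "c"},
        "MI/CC/24N": {"b", "c", "d"},
        "MI/SC/24H": {"a", "e"},
        "MI/SC/24N": {"e"},
    }

    def test_level_one_is_passthrough(self):
        assert multi_level_compare(self.SETS, level=1, axis="oxygen") == self.SETS

    def test_identical_pairs_have_empty_differences(self):
        sets = {"MI/CC/24H": {"x", "y"}, "MI/CC/24N": {"x", "y"}}
        out = multi_level_compare(sets, level=2, axis="oxygen", mode="difference")
        assert all(v == set() for v in out.values())

    def test_disjoint_pairs_have_empty_intersection(self):
        sets = {"MI/CC/24H": {"x"}, "MI/CC/24N": {"y"}}
        out = multi_level_compare(sets, level=2, axis="oxygen", mode="intersection")
        assert all(v == set() for v in out.values())

    def test_venn_mode_matches_hand_enumeration(self):
        out = multi_level_compare(self.SETS, level=2, axis="oxygen")
        # oxygen codes sort H < N, so the H arm is listed first
        assert out["MI/CC/24H|MI/CC/24N:MI/CC/24H_only"] == {"a"}
        assert out["MI/CC/24H|MI/CC/24N:shared"] == {"b", "c"}
        assert out["MI/CC/24H|MI/CC/24N:MI/CC/24N_only"] == {"d"}
        assert out["MI/SC/24H|MI/SC/24N:MI/SC/24H_only"] == {"a"}
        assert out["MI/SC/24H|MI/SC/24N:shared"] == {"e"}

    def test_unpairable_conditions_raise(self):
        with pytest.raises(ValueError):
            multi_level_compare({"MI/CC/24H": {"a"}}, level=2, axis="oxygen")


class TestPrerankedEs:
    def test_top_loaded_set_matches_brute_force(self):
        genes = [f"G{i}" for i in range(10)]
        scores = list(np.linspace(3, -3, 10))
        members = {"G0", "G1", "G2"}
        es, _ = preranked_es(list(zip(genes, scores)), members, weight=1.0, n_perm=50, seed=0)
        assert es == pytest.approx(brute_force_es(genes, scores, members, 1.0))
        assert es > 0

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 15))
            genes = [f"G{i}" for i in range(n)]
            scores = rng.normal(size=n).tolist()
            k = int(rng.integers(1, n - 1))
            members = set(rng.choice(genes, size=k, replace=False))
            for w in (0.0, 1.0):
                es, _ = preranked_es(
                    list(zip(genes, scores)), members, weight=w, n_perm=10, seed=1
                )
                assert es == pytest.approx(brute_force_es(genes, scores, members, w))

    def test_permutation_p_matches_exhaustive_enumeration(self):
        genes = [f"G{i}" for i in range(6)]
        scores = [2.2, 1.4, 0.8, -0.3, -1.1, -2.0]
        members = {"G0", "G2"}
        ranked = list(zip(genes, scores))
        es_mc, p_mc = preranked_es(ranked, members, n_perm=1000, seed=5)
        es_ex, p_ex = preranked_es(ranked, members, exhaustive=True)
        assert es_mc == es_ex
        se = np.sqrt(p_ex * (1 - p_ex) / 1000)
        assert abs(p_mc - p_ex) <= 3 * se + 1.0 / 1001

    def test_full_universe_set_is_degenerate(self):
        ranked = [("A", 1.0), ("B", 0.5)]
        with pytest.raises(ValueError):
            preranked_es(ranked, {"A", "B"})

    def test_no_overlap_is_an_error(self):
        with pytest.raises(ValueError):
            preranked_es([("A", 1.0), ("B", 0.5)], {"Z"})

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_unweighted_es_flips_sign_under_list_reversal(self, seed):
        r = np.random.default_rng(seed)
        n = 12
        genes = [f"G{i}" for i in range(n)]
        scores = np.sort(r.normal(size=n))[::-1]
        scores += np.linspace(0, 1e-6, n)[::-1]  # break ties
        k = int(r.integers(1, n - 1))
        members = set(r.choice(genes, size=k, replace=False))
        # skip instances where the running sum hits its extremal magnitude
        # with both signs: the signed ES is then a tie-break, not a negation
        inc = np.where([g in members for g in genes], 1.0 / k, -1.0 / (n - k))
        run = np.cumsum(inc)
        assume(np.sum(np.abs(np.abs(run) - np.abs(run).max()) < 1e-12) == 1)
        es_fwd, _ = preranked_es(list(zip(genes, scores)), members, weight=0.0, n_perm=10, seed=0)
        es_rev, _ = preranked_es(
            list(zip(genes, -scores)), members, weight=0.0, n_perm=10, seed=0
        )
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)


def make_sigs(defs):
    return [
        Signature(name=n, genes=frozenset(g), discriminating_variable=v)
        for n, g, v in defs
    ]


class TestOverlapAnalysis:
    def test_disjoint_signatures_explain_nothing(self):
        sigs = make_sigs([("s1", {"x", "y"}, "inflammation")])
        res = overlap_analysis({"a", "b"}, sigs)
        assert res.explained_fraction == 0.0 and res.unexplained_fraction == 1.0

    def test_superset_signature_explains_everything_univocally(self):
        ev = {"a", "b", "c"}
        sigs = make_sigs([("s1", {"a", "b", "c", "z"}, "hypoxia")])
        res = overlap_analysis(ev, sigs)
        assert res.explained_fraction == 1.0
        assert res.univocal_fraction_by_variable["hypoxia"] == 1.0
        assert res.per_signature_unique_fraction["s1"] == 1.0

    def test_hand_worked_three_signature_instance(self):
        ev = set("abcdefgh")  # |E| = 8
        sigs = make_sigs(
            [
                ("s1", {"a", "b", "c"}, "inflammation"),
                ("s2", {"c", "d"}, "IL4"),
                ("s3", {"x", "y"}, "hypoxia"),
            ]
        )
        res = overlap_analysis(ev, sigs)
        assert res.explained_fraction == pytest.approx(4 / 8)
        assert res.univocal_fraction_by_variable["inflammation"] == pytest.approx(2 / 8)
        assert res.univocal_fraction_by_variable["IL4"] == pytest.approx(1 / 8)
        assert res.shared_matrix.loc["s1", "s2"] == pytest.approx(1 / 8)  # gene c
        assert res.shared_matrix.loc["s1", "s1"] == pytest.approx(3 / 8)

    def test_fractions_match_brute_force_membership_scan(self, rng):
        universe = [f"G{i}" for i in range(60)]
        ev = set(rng.choice(universe, 25, replace=False))
        sigs = make_sigs(
            [
                (f"s{k}", set(rng.choice(universe, 15, replace=False)), "inflammation")
                for k in range(4)
            ]
        )
        res = overlap_analysis(ev, sigs)
        explained = sum(any(g in s.genes for s in sigs) for g in ev) / len(ev)
        assert res.explained_fraction == pytest.approx(explained, abs=1e-15)
        for a in sigs:
            for b in sigs:
                brute = sum(g in a.genes and g in b.genes for g in ev) / len(ev)
                assert res.shared_matrix.loc[a.name, b.name] == pytest.approx(brute, abs=1e-15)

    def test_partition_identity_and_matrix_dominance(self, rng):
        universe = [f"G{i}" for i in range(80)]
        ev = set(rng.choice(universe, 30, replace=False))
        sigs = make_sigs(
            [(f"s{k}", set(rng.choice(universe, 20, replace=False)), "hypoxia") for k in range(3)]
        )
        res = overlap_analysis(ev, sigs)
        assert res.explained_fraction + res.unexplained_fraction == pytest.approx(1.0, abs=1e-12)
        multi = res.explained_fraction - res.univocal_total
        assert multi >= -1e-12
        m = res.shared_matrix.to_numpy()
        assert (np.diag(m)[:, None] >= m - 1e-15).all()

    def test_pathway_contributions(self):
        ev = {"a", "b", "c", "d"}
        sigs = make_sigs([("s1", {"a", "b"}, "inflammation"), ("s2", {"c"}, "IL4")])
        res = overlap_analysis(ev, sigs, pathways={"P1": {"a", "c", "q"}, "P2": {"z"}})
        assert res.pathway_contribution.loc["P1", "s1"] == pytest.approx(0.5)
        assert res.pathway_contribution.loc["P1", "s2"] == pytest.approx(0.5)
        assert res.pathway_contribution.loc["P2"].eq(0).all()

    def test_duplicate_names_rejected(self):
        sigs = make_sigs([("s", {"a"}, "IL4"), ("s", {"b"}, "IL4")])
        with pytest.raises(ValueError):
            overlap_analysis({"a"}, sigs)


class TestScreenSignatures:
    def test_empty_signature_list(self):
        ranked = pd.DataFrame({"gene": ["A", "B"], "logFC": [1.0, -1.0]})
        assert screen_signatures(ranked, []) == []

    def test_zero_overlap_dropped_regardless_of_scores(self):
        ranked = pd.DataFrame({"gene": list("ABCD"), "logFC": [3.0, 2.0, -2.0, -3.0]})
        sig = Signature(name="s", genes=frozenset({"Z"}))
        assert screen_signatures(ranked, [sig], exvivo={"A", "B"}) == []

    def test_tightening_threshold_never_grows_retention(self, rng):
        from fibrophase import plant_ranked_instance

        ranked, planted = plant_ranked_instance(60, 8, effect=2.5, seed=9)
        null = set(rng.choice([g for g in ranked["gene"] if g not in planted], 8, replace=False))
        sigs = [
            Signature(name="planted", genes=frozenset(planted)),
            Signature(name="null", genes=frozenset(null)),
        ]
        loose = {s.name for s in screen_signatures(ranked, sigs, p_threshold=0.5, n_perm=200)}
        tight = {s.name for s in screen_signatures(ranked, sigs, p_threshold=0.01, n_perm=200)}
        assert tight <= loose
        assert "planted" in tight
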