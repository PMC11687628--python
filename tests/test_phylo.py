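import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivephy.exceptions import (
    MissingBranchLengthError,
    NewickParseError,
    PolytomyError,
    ValidationError,
)
from drivephy.phylo import (
    check_ultrametric,
    independent_contrasts,
    paint_regimes,
    parse_newick,
)
from drivephy.phylo import regime_changes

from conftest import random_painting, random_tree
from oracles import fitch_min_changes, gls_brownian_rate, gls_root_estimate


class TestParse:
    def test_three_tip_depths(self, three_tip):
        assert three_tip.n_tips == 3
        d = three_tip.depths()
        assert all(d[i] == 2 for i in three_tip.tip_ids)
        ok, dev = check_ultrametric(three_tip)
        assert ok and dev == 0

    def test_single_tip(self):
        t = parse_newick("(A:1);")
        assert t.n_tips == 1
        assert sum(1 for n in range(t.n_nodes) if len(t.children[n]) == 2) == 0

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1):1,C:2")

    def test_missing_branch_length_names_node(self):
        with pytest.raises(MissingBranchLengthError, match="B"):
            parse_newick("((A:1,B):1,C:2);")

    def test_polytomy_flagged_not_rejected(self):
        t = parse_newick("(A:1,B:1,C:1);")
        assert t.has_polytomies()

    def test_regime_comments_preserved(self):
        t = parse_newick("((A[&regime=asymmetric]:1,B[&regime=symmetric]:1):1,C[&regime=symmetric]:2);")
        from drivephy.phylo import regime_from_comments

        assert regime_from_comments(t) == {
            "A": "asymmetric",
            "B": "symmetric",
            "C": "symmetric",
        }

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_preserves_distances(self, seed):
        t = random_tree(50, seed)
        t2 = parse_newick(t.to_newick())
        order = np.argsort(t.tip_labels)
        order2 = np.argsort(t2.tip_labels)
        d1 = t.patristic_distances()[np.ix_(order, order)]
        d2 = t2.patristic_distances()[np.ix_(order2, order2)]
        assert sorted(t.tip_labels) == sorted(t2.tip_labels)
        assert np.max(np.abs(d1 - d2)) < 1e-9


class TestPrune:
    def test_prune_preserves_depths(self, three_tip):
        p = three_tip.prune_to_taxa({"A", "C"})
        assert sorted(p.tip_labels) == ["A", "C"]
        d = p.depths(include_root_edge=True)
        assert {p.labels[i]: d[i] for i in p.tip_ids} == {"A": 2.0, "C": 2.0}

    def test_prune_to_all_is_identity(self, three_tip):
        p = three_tip.prune_to_taxa(set(three_tip.tip_labels))
        i1 = np.argsort(three_tip.tip_labels)
        i2 = np.argsort(p.tip_labels)
        assert np.allclose(
            p.patristic_distances()[np.ix_(i2, i2)],
            three_tip.patristic_distances()[np.ix_(i1, i1)],
        )

    def test_unknown_label_lists_missing(self, three_tip):
        with pytest.raises(ValidationError, match="X"):
            three_tip.prune_to_taxa({"A", "X"})

    @pytest.mark.parametrize("seed", [3, 4])
    def test_prune_preserves_patristic_distances(self, seed):
        t = random_tree(20, seed)
        keep = sorted(t.tip_labels)[:5]
        p = t.prune_to_taxa(keep)
        full = t.patristic_distances()
        idx = [t.tip_labels.index(l) for l in keep]
        sub = full[np.ix_(idx, idx)]
        pidx = [p.tip_labels.index(l) for l in keep]
        got = p.patristic_distances()[np.ix_(pidx, pidx)]
        assert np.max(np.abs(got - sub)) < 1e-9


class TestUltrametric:
    def test_unequal_depths_fail(self):
        t = parse_newick("((A:1,B:2):1,C:2);")
        ok, dev = check_ultrametric(t, rel_tol=1e-6)
        assert not ok and dev > 0.3

    @pytest.mark.parametrize("seed", range(5))
    def test_yule_trees_ultrametric(self, seed):
        ok, dev = check_ultrametric(random_tree(20, seed), rel_tol=1e-9)
        assert ok, dev


class TestPainting:
    def test_hand_example(self, three_tip):
        rm = paint_regimes(
            three_tip, {"A": "asym", "B": "asym", "C": "sym"}, "sym"
        )
        lab = {three_tip.labels.get(n): n for n in three_tip.tip_ids}
        internal = next(
            n for n in range(three_tip.n_nodes)
            if n != three_tip.root and not three_tip.is_tip(n)
        )
        assert rm.branch_regime[lab["A"]] == "asym"
        assert rm.branch_regime[lab["B"]] == "asym"
        assert rm.branch_regime[internal] == "asym"
        assert rm.branch_regime[lab["C"]] == "sym"
        assert rm.root_regime == "sym"

    def test_uniform_tips(self, three_tip):
        rm = paint_regimes(three_tip, {t: "x" for t in "ABC"}, "x")
        assert set(rm.branch_regime.values()) == {"x"}

    def test_unassigned_tip_raises(self, three_tip):
        with pytest.raises(ValidationError, match="C"):
            paint_regimes(three_tip, {"A": "x", "B": "x"}, "x")

    def test_caterpillar_alternating_matches_bruteforce(self):
        nwk = "(((((((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5):1,G:6):1,H:7):1,I:8):1,J:9);"
        t = parse_newick(nwk)
        tips = {l: ("a" if i % 2 == 0 else "b") for i, l in enumerate(t.tip_labels)}
        rm = paint_regimes(t, tips, "a", alphabet=("a", "b"))
        assert regime_changes(t, rm) == fitch_min_changes(t, tips, ("a", "b"))

    @pytest.mark.parametrize("seed", range(6))
    def test_random_paintings_minimal(self, seed):
        t = random_tree(8, seed + 50)
        tips = random_painting(t, seed, alphabet=("a", "b"))
        rm = paint_regimes(t, tips, "a", alphabet=("a", "b"))
        assert regime_changes(t, rm) == fitch_min_changes(t, tips, ("a", "b"))


class TestContrasts:
    def test_two_tip_formula(self):
        t = parse_newick("(A:1,B:1);")
        cs = independent_contrasts(t, {"A": 3.0, "B": 1.0})
        assert len(cs) == 1
        assert cs.contrasts[0] == pytest.approx(2 / np.sqrt(2), abs=1e-5)

    def test_three_tip_hand_recursion(self, three_tip):
        cs = independent_contrasts(three_tip, {"A": 2.0, "B": 0.0, "C": 4.0})
        assert sorted(np.round(cs.contrasts, 5)) == [-1.60357, 1.41421]
        assert cs.variances.tolist() == [2.0, 3.5]
        assert cs.node_estimates[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_count_and_sign_invariance(self, seed):
        t = random_tree(12, seed + 10)
        rng = np.random.default_rng(seed)
        vals = dict(zip(t.tip_labels, rng.normal(size=12)))
        cs = independent_contrasts(t, vals)
        assert len(cs) == t.n_tips - 1
        # reordering children flips contrast signs only
        t2 = parse_newick(t.to_newick())
        cs2 = independent_contrasts(t2, vals)
        assert np.allclose(np.sort(np.abs(cs.contrasts)), np.sort(np.abs(cs2.contrasts)))

    @pytest.mark.parametrize("seed", range(6))
    def test_mean_squared_contrast_is_reml_rate(self, seed):
        t = random_tree(7, seed + 30)
        rng = np.random.default_rng(seed)
        vals = dict(zip(t.tip_labels, rng.normal(size=7)))
        cs = independent_contrasts(t, vals)
        reml = gls_brownian_rate(t, vals)
        assert np.mean(cs.contrasts**2) == pytest.approx(reml, abs=1e-8)
        assert cs.root_estimate == pytest.approx(gls_root_estimate(t, vals), abs=1e-8)

    def test_polytomy_raises_then_resolvable(self):
        t = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(PolytomyError):
            independent_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})
        r = t.resolve_polytomies()
        assert not r.has_polytomies()
        cs = independent_contrasts(r, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert len(cs) == 2

    def test_zero_branch_length_raises(self):
        t = parse_newick("((A:0,B:1):1,C:2);")
        with pytest.raises(ValidationError):
            independent_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_contrasts_affine_equivariance(self, seed):
        t = random_tree(6, 123)
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=6)
        base = independent_contrasts(t, dict(zip(t.tip_labels, vals))).contrasts
        scaled = independent_contrasts(
            t, dict(zip(t.tip_labels, 2.5 * vals + 7.0))
        ).contrasts
        assert np.allclose(scaled, 2.5 * base)
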