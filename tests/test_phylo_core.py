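"""Tree reading, pruning, covariance, rescaling and contrasts."""

from itertools import combinations

import numpy as np
import pytest

import mastphylo as mp
from mastphylo.errors import InvalidInputError, TreeError
from mastphylo.phylo_core import (canonical_label, covariance_from_tree,
                                  independent_contrasts, lambda_rescale,
                                  parse_newick, prune_to)


def test_read_newick_examples(tmp_path, tree3):
    assert tree3.n_tips == 3 and tree3.height == pytest.approx(2.0)
    p = tmp_path / "t.nwk"
    p.write_text("(A:1,B:1);\n")
    assert mp.read_newick(p).n_tips == 2
    with pytest.raises(TreeError):
        parse_newick("((A:1,B:1;")                      # malformed
    with pytest.raises(TreeError, match="duplicate"):
        parse_newick("((A:1,A:1):1,C:2);")
    with pytest.raises(TreeError, match="missing branch lengths"):
        parse_newick("((A:1,B):1,C:2);")


def test_canonical_labels():
    assert canonical_label(" Quercus_robur  ") == "Quercus robur"
    t = parse_newick("((Quercus_robur:1,B:1):1,C:2);")
    assert "Quercus robur" in t.tip_labels


def test_prune_preserves_path_lengths(tree3):
    res = prune_to(tree3, ["A", "C"])
    assert res.tree.tip_labels == ("A", "C")
    assert res.tree.tip_depths() == pytest.approx([2.0, 2.0])  # A-C path = 4
    # identity prune
    assert prune_to(tree3, ["A", "B", "C"]).tree.n_tips == 3
    with pytest.raises(InvalidInputError):
        prune_to(tree3, ["A"])
    with pytest.raises(InvalidInputError, match="not in tree"):
        prune_to(tree3, ["A", "Z"])
    rep = prune_to(tree3, ["A", "B", "Z"], on_missing="report")
    assert rep.missing == ("Z",) and rep.tree.n_tips == 2


def test_covariance_examples(tree3):
    C = covariance_from_tree(tree3, normalize=False)
    assert C.labels == ("A", "B", "C")
    np.testing.assert_allclose(C.matrix, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])
    star = parse_newick("(A:1,B:1,C:1);")
    np.testing.assert_allclose(covariance_from_tree(star, normalize=False).matrix,
                               np.eye(3))
    Cn = covariance_from_tree(tree3, normalize=True)
    np.testing.assert_allclose(np.diag(Cn.matrix), 1.0)


@pytest.mark.parametrize("lam, expected", [
    (1.0, [[2, 1], [1, 2]]),
    (0.0, [[2, 0], [0, 2]]),
    (0.5, [[2, 0.5], [0.5, 2]]),
])
def test_lambda_rescale(lam, expected):
    C = mp.PhyloCovariance(np.array([[2.0, 1.0], [1.0, 2.0]]), ("A", "B"))
    np.testing.assert_allclose(lambda_rescale(C, lam).matrix, expected)
    with pytest.raises(InvalidInputError):
        lambda_rescale(C, 1.5)


def test_restrict_matches_prune_covariance():
    """Covariance of a pruned tree == restriction of the full covariance,
    exhaustively over all tip subsets of size 2-5 of an 8-tip Yule tree."""
    tree = mp.simulate_tree(8, seed=4)
    C = covariance_from_tree(tree, normalize=False)
    for size in (2, 3, 4, 5):
        for subset in combinations(tree.tip_labels, size):
            sub = prune_to(tree, subset).tree
            Csub = covariance_from_tree(sub, normalize=False)
            Cres = C.restrict(Csub.labels)
            np.testing.assert_allclose(Csub.matrix, Cres.matrix, atol=1e-10)


def test_covariance_psd_on_random_trees():
    for seed in range(100):
        tree = mp.simulate_tree(12, seed=seed)
        C = covariance_from_tree(tree).matrix
        assert np.linalg.eigvalsh(C).min() >= -1e-10 * np.trace(C)


def test_contrasts_examples(balanced4):
    # identical values -> all contrasts zero
    cs = independent_contrasts(balanced4, {"A": 2, "B": 2, "C": 2, "D": 2})
    np.testing.assert_allclose(cs.contrasts, 0.0)
    assert cs.n == 3
    # two-tip hand formula
    two = parse_newick("(A:1,B:4);")
    cs2 = independent_contrasts(two, {"A": 3, "B": 0})
    assert cs2.contrasts == pytest.approx([3 / np.sqrt(5)])
    with pytest.raises(InvalidInputError, match="missing"):
        independent_contrasts(two, {"A": 3})


def test_contrasts_star_tree_cross_products_match_centered_values(rng):
    """On a star tree the contrasts are an orthogonal rotation of the
    centred data: cross products of contrasts equal centred cross products."""
    n = 12
    labels = [f"t{i}" for i in range(n)]
    star = parse_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    cx = independent_contrasts(star, dict(zip(labels, x))).contrasts
    cy = independent_contrasts(star, dict(zip(labels, y))).contrasts
    assert cx @ cy == pytest.approx((x - x.mean()) @ (y - y.mean()), abs=1e-10)
    assert cx @ cx == pytest.approx(((x - x.mean()) ** 2).sum(), abs=1e-10)


def test_polytomy_resolution_is_deterministic():
    t = parse_newick("(A:1,B:1,C:1,D:1);")
    assert t.has_polytomies
    r1 = t.resolve_polytomies(seed=3)
    r2 = t.resolve_polytomies(seed=3)
    assert r1.write_newick() == r2.write_newick()
    assert not r1.has_polytomies
    assert r1.height == pytest.approx(t.height)
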