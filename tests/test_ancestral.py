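"""Mk-model likelihood, rate estimation, marginal reconstruction."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

import mitocompare as mc
from mitocompare.ancestral import label_nodes
from mitocompare.synthetic import random_tree


def _enumerate_likelihood(tree, states, k, rate, alphabet):
    """Independent oracle: sum over all internal-node state assignments."""
    idx = {a: i for i, a in enumerate(alphabet)}
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    total = 0.0
    marg = {id(nd): np.zeros(k) for nd in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip([id(n) for n in internals], assign))
        p = 1.0 / k
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            ps = amap[id(nd.parent_node)]
            if nd.is_leaf():
                s = states.get(nd.taxon.label)
                if s is None:
                    continue  # missing leaf: sums over all its states = 1
                cs = idx[s]
            else:
                cs = amap[id(nd)]
            p *= mc.transition_matrix(k, rate, nd.edge.length or 0.0)[ps, cs]
        total += p
        for nd in internals:
            marg[id(nd)][amap[id(nd)]] += p
    return total, {key: v / total for key, v in marg.items()}


TREES = [
    "((A:0.1,B:0.2):0.3,(C:0.1,D:0.4):0.2):0.0;",
    "(((A:0.05,B:0.1):0.2,C:0.3):0.1,(D:0.2,E:0.1,F:0.3):0.25):0.0;",  # multifurcation
    "((A:0.5,B:0.5):0.5,C:1.0):0.0;",
]
STATE_SETS = [
    {"A": "X", "B": "X", "C": "Y", "D": "X", "E": "Y", "F": "Z"},
    {"A": "X", "B": "Y", "C": "Y", "D": "Z", "E": "W", "F": "X"},
    {"A": "X", "B": None, "C": "Y", "D": "Y", "E": "X", "F": None},  # missing leaves
]


@pytest.mark.parametrize("nwk", TREES)
@pytest.mark.parametrize("raw", STATE_SETS)
@pytest.mark.parametrize("rate", [0.05, 0.7, 3.0])
def test_pruning_equals_enumeration(nwk, raw, rate):
    """Pruning log-likelihood and marginals equal brute-force enumeration on
    trees of <= 6 leaves to 1e-10."""
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    states = {t: s for t, s in raw.items() if t in leaves}
    alphabet = tuple(sorted({s for s in states.values() if s})) or ("X", "Y")
    if len(alphabet) < 2:
        alphabet = ("X", "Y")
    model = mc.MkModel(nwk, states, alphabet=alphabet)
    k = len(alphabet)
    total, marg = _enumerate_likelihood(tree, states, k, rate, alphabet)
    assert model.loglike(rate) == pytest.approx(math.log(total), abs=1e-10)
    got = model._marginals(rate)
    labels = label_nodes(tree)
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        expected = marg[id(nd)]
        row = got.loc[labels[id(nd)]].to_numpy()
        assert np.abs(row - expected).max() < 1e-10


def test_single_branch_closed_form():
    """k=2, one branch of length t: P(stay) = 1/2 + 1/2 e^(-2 r t)."""
    for rate, t in [(0.3, 1.0), (1.5, 0.2)]:
        P = mc.transition_matrix(2, rate, t)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-2 * rate * t))
        assert np.allclose(P.sum(axis=1), 1.0)


def test_low_rate_limit_two_identical_leaves():
    """As rate -> 0, two leaves in the same state give loglik -> log(1/k)."""
    model = mc.MkModel("(A:1.0,B:1.0):0.0;", {"A": "X", "B": "X"},
                       alphabet=("X", "Y", "Z"))
    assert model.loglike(1e-9) == pytest.approx(math.log(1 / 3), abs=1e-6)


def test_marginals_sum_to_one_and_star_tree_limit():
    nwk = "(A:0.1,B:0.1,C:0.1,D:0.1):0.0;"
    model = mc.MkModel(nwk, {t: "A" for t in "ABCD"}, alphabet=("A", "B"))
    m = model._marginals(1e-6)
    assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)
    assert m.loc[model.root_label, "A"] > 0.999999


def test_label_permutation_equivariance():
    """Permuting state letters permutes the outputs identically: same fitted
    log-likelihood, and marginals (at a fixed rate) permuted column-for-column."""
    nwk = TREES[0]
    states = {"A": "X", "B": "Y", "C": "X", "D": "Z"}
    swap = {"X": "Z", "Y": "Y", "Z": "X"}
    swapped = {t: swap[s] for t, s in states.items()}
    fit1 = mc.MkModel(nwk, states, alphabet=("X", "Y", "Z")).fit()
    fit2 = mc.MkModel(nwk, swapped, alphabet=("X", "Y", "Z")).fit()
    assert fit1.llf == pytest.approx(fit2.llf, abs=1e-9)
    m1 = mc.marginal_ancestral(nwk, states, 0.7, alphabet=("X", "Y", "Z"))
    m2 = mc.marginal_ancestral(nwk, swapped, 0.7, alphabet=("X", "Y", "Z"))
    m1p = m1.rename(columns=swap)[list(m2.columns)]
    pd.testing.assert_frame_equal(
        m1p.sort_index(), m2.sort_index(), atol=1e-12, rtol=0
    )


def test_invariant_character_is_boundary_flagged():
    rate, flags = mc.estimate_rate("(A:1,B:1):0;", {"A": "X", "B": "X"},
                                   alphabet=("X", "Y"))
    assert any("lower bound" in f for f in flags)


def test_fitted_rate_beats_random_rates():
    """Optimizer sanity: the returned rate's likelihood is >= that of 100
    random rates in the search interval."""
    tree = random_tree(40, seed=5)
    states, _ = mc.simulate_characters(tree, k=3, rate=0.8, seed=5)
    model = mc.MkModel(tree, states, alphabet=("A", "B", "C"))
    res = model.fit()
    rng = np.random.default_rng(0)
    rates = np.exp(rng.uniform(math.log(1e-6), math.log(1e3), size=100))
    assert res.llf >= max(model.loglike(r) for r in rates) - 1e-9


def test_rate_recovery_within_factor_two():
    """Data simulated at a known rate on 64-leaf trees recovers the rate
    within a factor of 2 in >= 90% of 50 seeded replicates."""
    ok = 0
    for rep in range(50):
        tree = random_tree(64, seed=1000 + rep)
        states, _ = mc.simulate_characters(tree, k=4, rate=1.0, seed=rep)
        rate, _ = mc.estimate_rate(tree, states, alphabet=("A", "B", "C", "D"))
        ok += 0.5 <= rate <= 2.0
    assert ok >= 45


def test_count_transitions_examples():
    # uniform states: zero events
    nwk = "((A:1,B:1):1,(C:1,D:1):1):0;"
    res = mc.MkModel(nwk, {t: "X" for t in "ABCD"}, alphabet=("X", "Y")).fit()
    assert res.count_transitions() == {}
    # one derived clade: a single event on its stem branch
    res = mc.MkModel(nwk, {"A": "Y", "B": "Y", "C": "X", "D": "X"},
                     alphabet=("X", "Y")).fit()
    trans = res.count_transitions()
    assert sum(trans.values()) == 1
    # two independently derived clades on a larger tree: two events
    nwk2 = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1):0;"
    states = {"A": "Y", "B": "Y", "E": "Y", "F": "Y",
              "C": "X", "D": "X", "G": "X", "H": "X"}
    res = mc.MkModel(nwk2, states, alphabet=("X", "Y")).fit()
    trans = res.count_transitions()
    assert trans.get(("X", "Y")) == 2


def test_dominant_state_reconstructed_as_root():
    """A rare derived state confined to one clade leaves the dominant state
    at the root."""
    tree = random_tree(30, seed=3)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    # pick one small clade and mark it derived
    internal = [nd for nd in tree.preorder_node_iter()
                if not nd.is_leaf() and 2 <= len(nd.leaf_nodes()) <= 5]
    derived = {lf.taxon.label for lf in internal[-1].leaf_nodes()}
    states = {t: ("B" if t in derived else "A") for t in leaves}
    res = mc.MkModel(tree, states, alphabet=("A", "B")).fit()
    assert res.map_states()[res.model.root_label] == "A"
    assert res.occurrence.loc[res.model.root_label, "A"] > 50.0


def test_negative_branch_and_bad_rate_errors():
    with pytest.raises(mc.MitoError, match="negative branch"):
        mc.MkModel("(A:1,B:-0.5):0;", {"A": "X", "B": "Y"})
    model = mc.MkModel("(A:1,B:1):0;", {"A": "X", "B": "Y"})
    with pytest.raises(mc.MitoError, match="rate"):
        model.loglike(0.0)


def test_summary_and_tsv_roundtrip():
    res = mc.MkModel(TREES[0], {"A": "X", "B": "X", "C": "Y", "D": "X"}).fit()
    text = res.summary()
    assert "rate (ML)" in text and "root occurrences" in text
    tsv = res.to_tsv()
    assert tsv.splitlines()[0].startswith("node\tmap_state")
    nwk = res.annotated_newick()
    assert "state" in nwk


def test_mcmc_occurrences_close_to_ml():
    states = {"A": "X", "B": "X", "C": "Y", "D": "X"}
    ml = mc.MkModel(TREES[0], states).fit()
    bb = mc.MkModel(TREES[0], states).fit(method="mcmc", mcmc_samples=400,
                                          mcmc_burn=100, seed=11)
    root = ml.model.root_label
    assert abs(ml.marginals.loc[root].max() - bb.marginals.loc[root].max()) < 0.2
    assert np.allclose(bb.marginals.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def test_simulate_rate_zero_propagates_root_state():
    tree = random_tree(20, seed=1)
    matrix, log = mc.simulate_characters(tree, k=6, rate=0.0, seed=1)
    assert len(set(matrix.states.values())) == 1
    assert set(log.node_states.values()) == set(matrix.states.values())


def test_branch_transition_frequency_matches_closed_form():
    """Monte-Carlo stay frequency over 10,000 single-branch simulations is
    within 2% of 1/k + (1-1/k) e^(-k r t/(k-1))."""
    k, rate, t = 4, 0.9, 0.7
    nwk = f"(A:{t},B:0.0):0.0;"
    stays = 0
    n = 10000
    rng_seeds = range(n)
    stay_truth = 1 / k + (1 - 1 / k) * math.exp(-k * rate * t / (k - 1))
    for seed in rng_seeds:
        matrix, log = mc.simulate_characters(nwk, k=k, rate=rate, seed=seed)
        stays += matrix.states["A"] == log.node_states["N0"]
    assert stays / n == pytest.approx(stay_truth, abs=0.02)


def test_root_states_near_uniform_across_seeds():
    """Chi-square goodness of fit at alpha = 0.01 for the uniform root prior
    over the 6 letters A-F."""
    from scipy.stats import chisquare

    counts = {c: 0 for c in "ABCDEF"}
    nwk = "(A:0.1,B:0.1):0.0;"
    n = 1200
    for seed in range(n):
        _, log = mc.simulate_characters(nwk, k=6, rate=0.5, seed=seed)
        counts[log.node_states["N0"]] += 1
    stat, p = chisquare(list(counts.values()))
    assert p > 0.01
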