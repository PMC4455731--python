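"""Markov model fitting and stochastic character mapping."""
import itertools

import numpy as np
import pytest
import scipy.linalg

from morphorate.simmap import (CharacterHistory, DiscreteCharacter, QMatrix,
                               fit_q, pruning_loglik, sample_histories,
                               sample_history, summarize_maps,
                               transition_probability,
                               history_to_simmap_newick)
from morphorate.synthetic_data import simulate_character, simulate_tree
from morphorate.trees import PhyloTree


def _char(tree, states):
    return DiscreteCharacter.from_dict(
        dict(zip(tree.tip_labels, states)))


# --------------------------------------------------------------------- #
# transition probabilities
# --------------------------------------------------------------------- #

def test_transition_probability_zero_time_is_identity():
    Q = QMatrix.binary(0.4, 0.9)
    np.testing.assert_allclose(transition_probability(Q, 0.0), np.eye(2),
                               atol=1e-14)


@pytest.mark.parametrize("q,t", [(0.3, 0.5), (2.0, 1.7)])
def test_equal_rates_closed_form(q, t):
    Q = QMatrix.binary(q, q)
    P = transition_probability(Q, t)
    stay = (1 + np.exp(-2 * q * t)) / 2
    np.testing.assert_allclose(P, [[stay, 1 - stay], [1 - stay, stay]],
                               atol=1e-12)


def test_long_time_limit_is_stationary():
    Q = QMatrix.binary(0.7, 0.3)
    P = transition_probability(Q, 200.0)
    pi = Q.stationary()
    np.testing.assert_allclose(P, np.tile(pi, (2, 1)), atol=1e-10)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


# --------------------------------------------------------------------- #
# pruning likelihood
# --------------------------------------------------------------------- #

def _enumeration_loglik(tree, char, Q, prior):
    """Brute-force sum over all internal-node state assignments."""
    k = Q.k
    tips = char.state_indices(tree.tip_labels)
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    P = {i: scipy.linalg.expm(Q.rates * tree.blen[i])
         for i in range(tree.n_nodes)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        states = dict(zip(internal, assign))
        for tip, s in enumerate(tips):
            states[tip] = s
        lik = prior[states[tree.root]]
        for i in range(tree.n_nodes):
            if tree.parent[i] >= 0:
                lik *= P[i][states[tree.parent[i]], states[i]]
        total += lik
    return np.log(total)


def test_single_cherry_flat_prior():
    # two tips on zero branches: likelihood is the prior mass on the joint
    t = PhyloTree.from_newick("(A:0,B:0);")
    char = _char(t, ["0", "1"])
    Q = QMatrix.binary(0.5, 0.5)
    # states disagree on zero-length branches -> impossible
    assert pruning_loglik(t, char, Q) == -np.inf
    char2 = DiscreteCharacter.from_dict({"A": "0", "B": "0"},
                                        states=("0", "1"))
    assert pruning_loglik(t, char2, Q) == pytest.approx(np.log(0.5))


def test_pruning_matches_enumeration_on_four_tips(rng):
    t = PhyloTree.from_newick("((A:0.3,B:0.9):0.4,(C:1.1,D:0.2):0.6);")
    for _ in range(5):
        Q = QMatrix.binary(*rng.uniform(0.1, 3.0, 2))
        states = rng.choice(["0", "1"], size=4)
        if len(set(states)) < 2:
            states[0] = "0"; states[1] = "1"
        char = DiscreteCharacter.from_dict(
            dict(zip(t.tip_labels, states)), states=("0", "1"))
        got = pruning_loglik(t, char, Q, root_prior="flat")
        want = _enumeration_loglik(t, char, Q, np.array([0.5, 0.5]))
        assert got == pytest.approx(want, abs=1e-10)


def test_pruning_invariant_to_tip_relabeling():
    t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = PhyloTree.from_newick("((C:1,D:1):1,(A:1,B:1):1);")
    Q = QMatrix.binary(0.4, 0.8)
    char = DiscreteCharacter.from_dict(
        {"A": "0", "B": "1", "C": "0", "D": "1"}, states=("0", "1"))
    assert pruning_loglik(t1, char, Q) == \
        pytest.approx(pruning_loglik(t2, char, Q), abs=1e-12)


# --------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------- #

def test_ard_has_two_free_rates_and_dominates_er(rng):
    t = simulate_tree(40, rng=rng)
    char, _ = simulate_character(t, QMatrix.binary(0.8, 0.8), rng=rng,
                                 min_minority=5)
    ard = fit_q(t, char, model="ARD")
    er = fit_q(t, char, model="ER")
    q = ard.Q.rates
    assert q[0, 1] >= 0 and q[1, 0] >= 0      # two independent parameters
    assert er.Q.rates[0, 1] == pytest.approx(er.Q.rates[1, 0])
    assert er.loglik <= ard.loglik + 1e-6
    assert ard.converged


def test_fit_recovers_generating_rates():
    """ML is consistent: median fitted rates over replicates of 200-tip
    trees stay within a factor of 1.5 of the generating rates (individual
    binary-Mk fits are far noisier; see the phytools equivalence test)."""
    true = QMatrix.binary(1.2, 0.7)
    q01s, q10s = [], []
    for seed in range(50):
        r = np.random.default_rng(1000 + seed)
        t = simulate_tree(200, rng=r)
        char, _ = simulate_character(t, true, rng=r, min_minority=10,
                                     max_attempts=200)
        fit = fit_q(t, char, model="ARD")
        q01s.append(fit.Q.rates[0, 1])
        q10s.append(fit.Q.rates[1, 0])
    assert 1.2 / 1.5 <= np.median(q01s) <= 1.2 * 1.5
    assert 0.7 / 1.5 <= np.median(q10s) <= 0.7 * 1.5


def test_fit_matches_phytools_reference(tmp_path):
    """The fitted ARD Q and log-likelihood coincide with phytools::fitMk
    (flat root prior) on the same data."""
    import shutil, subprocess
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the reference fit")
    r = np.random.default_rng(77)
    t = simulate_tree(60, rng=r)
    char, _ = simulate_character(t, QMatrix.binary(0.9, 0.6), rng=r,
                                 min_minority=8, max_attempts=500)
    fit = fit_q(t, char, model="ARD")
    from morphorate.trees import write_newick
    write_newick(t, str(tmp_path / "t.nwk"))
    states = ";".join(f"{lab}={char.data[lab]}" for lab in t.tip_labels)
    script = tmp_path / "fit.R"
    script.write_text(
        'suppressMessages(library(phytools))\n'
        f'tr <- read.tree("{tmp_path / "t.nwk"}")\n'
        f'kv <- strsplit(strsplit("{states}", ";")[[1]], "=")\n'
        'x <- setNames(sapply(kv, `[`, 2), sapply(kv, `[`, 1))\n'
        'fit <- fitMk(tr, x, model="ARD", pi="equal")\n'
        'cat(fit$rates[2], fit$rates[1], fit$logLik, "\\n")\n')
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True)
    q01_r, q10_r, ll_r = map(float, out.stdout.split()[-3:])
    assert fit.Q.rates[0, 1] == pytest.approx(q01_r, rel=1e-3)
    assert fit.Q.rates[1, 0] == pytest.approx(q10_r, rel=1e-3)
    assert fit.loglik == pytest.approx(ll_r, abs=1e-3)


def test_constant_character_not_identifiable(rng):
    t = simulate_tree(10, rng=rng)
    char = DiscreteCharacter.from_dict(
        {lab: "0" for lab in t.tip_labels}, states=("0", "1"))
    with pytest.raises(ValueError, match="constant"):
        fit_q(t, char)


# --------------------------------------------------------------------- #
# stochastic maps
# --------------------------------------------------------------------- #

def test_histories_end_in_observed_tip_states(rng):
    t = simulate_tree(15, rng=rng)
    Q = QMatrix.binary(0.6, 0.9)
    char, _ = simulate_character(t, Q, rng=rng, min_minority=3)
    tips = char.state_indices(t.tip_labels)
    for seed in range(5):
        h = sample_history(t, char, Q, rng=seed)
        np.testing.assert_array_equal(h.node_states[: t.n_tips], tips)
        for i in range(t.n_nodes):
            assert h.segments[i][-1][0] == h.node_states[i]


def test_history_durations_conserve_branch_lengths(rng):
    t = simulate_tree(12, rng=rng)
    Q = QMatrix.binary(1.5, 1.5)
    char, _ = simulate_character(t, Q, rng=rng, min_minority=2)
    h = sample_history(t, char, Q, rng=0)
    for i in range(t.n_nodes):
        total = sum(d for _, d in h.segments[i])
        assert total == pytest.approx(t.blen[i], abs=1e-9)
        states = [s for s, _ in h.segments[i]]
        assert all(a != b for a, b in zip(states, states[1:]))
        if t.parent[i] >= 0:     # branch starts in the parent's state
            assert h.segments[i][0][0] == h.node_states[t.parent[i]]


def test_histories_deterministic_given_seed(rng):
    t = simulate_tree(10, rng=rng)
    Q = QMatrix.binary(0.7, 0.4)
    char, _ = simulate_character(t, Q, rng=rng, min_minority=2)
    h1 = sample_histories(t, char, Q, n=5, rng=123)
    h2 = sample_histories(t, char, Q, n=5, rng=123)
    for a, b in zip(h1, h2):
        np.testing.assert_array_equal(a.node_states, b.node_states)
        assert a.segments == b.segments


def test_near_zero_rates_give_zero_transitions(rng):
    t = simulate_tree(8, rng=rng)
    char = DiscreteCharacter.from_dict(
        {lab: "0" for lab in t.tip_labels}, states=("0", "1"))
    Q = QMatrix.binary(1e-9, 1e-9)
    h = sample_history(t, char, Q, rng=1)
    assert h.n_transitions == 0


def test_node_marginals_match_exact_posterior(rng):
    """Sampled node-state frequencies reproduce the enumerated conditional
    posterior on a 3-tip tree within Monte-Carlo error."""
    t = PhyloTree.from_newick("((A:0.6,B:0.4):0.5,C:1.1);")
    Q = QMatrix.binary(0.9, 0.5)
    char = DiscreteCharacter.from_dict({"A": "0", "B": "1", "C": "1"},
                                       states=("0", "1"))
    # exact joint posterior over (root, inner) states by enumeration
    P = {i: scipy.linalg.expm(Q.rates * t.blen[i]) for i in range(t.n_nodes)}
    tips = char.state_indices(t.tip_labels)
    inner = [i for i in range(t.n_nodes)
             if t.children[i] and i != t.root]
    assert len(inner) == 1
    inner = inner[0]
    post = np.zeros((2, 2))
    for rs in (0, 1):
        for ns in (0, 1):
            states = {t.root: rs, inner: ns}
            for tip, s in enumerate(tips):
                states[tip] = s
            lik = 0.5
            for i in range(t.n_nodes):
                if t.parent[i] >= 0:
                    lik *= P[i][states[t.parent[i]], states[i]]
            post[rs, ns] = lik
    post /= post.sum()
    n = 10_000
    hists = sample_histories(t, char, Q, n=n, rng=77)
    freq = np.zeros((2, 2))
    for h in hists:
        freq[h.node_states[t.root], h.node_states[inner]] += 1
    freq /= n
    for rs in (0, 1):
        for ns in (0, 1):
            se = np.sqrt(max(post[rs, ns] * (1 - post[rs, ns]), 1e-12) / n)
            assert abs(freq[rs, ns] - post[rs, ns]) <= 3 * se + 1e-3


def test_branch_path_transition_rate_matches_rejection_oracle(rng):
    """Mean transition count on a single endpoint-conditioned branch agrees
    with brute-force forward simulation filtered on the endpoint."""
    Q = QMatrix.binary(1.2, 0.8)
    t_len, a, b = 0.9, 0, 0
    tree = PhyloTree.from_newick(f"(A:{t_len},B:0.1);")
    # rejection oracle by dense forward simulation
    reps, counts = 30_000, []
    for _ in range(reps):
        s, tt, k = a, 0.0, 0
        while True:
            wait = rng.exponential(1 / -Q.rates[s, s])
            if tt + wait > t_len:
                break
            tt += wait
            s = 1 - s
            k += 1
        if s == b:
            counts.append(k)
    oracle = np.mean(counts)
    # uniformization sampler on the same branch
    from morphorate.simmap import _sample_path
    Pt = transition_probability(Q, t_len)
    ks = []
    for _ in range(20_000):
        segs = _sample_path(Q.rates, a, b, t_len, rng, Pt[a, b])
        ks.append(len(segs) - 1)
    got = np.mean(ks)
    se = np.std(ks) / np.sqrt(len(ks)) + np.std(counts) / np.sqrt(len(counts))
    assert abs(got - oracle) <= 4 * se + 0.01


# --------------------------------------------------------------------- #
# summaries and export
# --------------------------------------------------------------------- #

def test_summary_counts_and_occupancy(rng):
    t = simulate_tree(10, rng=rng)
    Q = QMatrix.binary(0.8, 0.8)
    char, _ = simulate_character(t, Q, rng=rng, min_minority=2)
    hists = sample_histories(t, char, Q, n=50, rng=5)
    ms = summarize_maps(hists)
    assert ms.n_maps == 50
    assert sum(ms.total_counts.values()) == 50
    assert sum(ms.state_time_proportion.values()) == pytest.approx(1.0)
    assert ms.modal_total >= 1          # both states observed at the tips


def test_summary_of_transition_free_history():
    t = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
    h = CharacterHistory(
        node_states=np.zeros(t.n_nodes, dtype=int),
        segments=[[(0, float(t.blen[i]))] for i in range(t.n_nodes)],
        states=("0", "1"))
    ms = summarize_maps([h])
    assert ms.modal_total == 0 and ms.mean_total == 0.0
    assert all(v["mean"] == 0 for v in ms.per_type.values())


def test_simmap_newick_export_contains_segments(rng):
    t = simulate_tree(6, rng=rng)
    Q = QMatrix.binary(0.9, 0.9)
    char, _ = simulate_character(t, Q, rng=rng, min_minority=1)
    h = sample_history(t, char, Q, rng=2)
    s = history_to_simmap_newick(t, h)
    assert s.endswith(";") and "{" in s
    for lab in t.tip_labels:
        assert lab in s
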