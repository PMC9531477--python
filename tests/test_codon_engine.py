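import itertools

import numpy as np
import pytest
from scipy.linalg import expm as scipy_expm

from selscan.codon import (
    CODONS,
    AlignmentError,
    CodonAlignment,
    CodonLikelihood,
    CodonModelParams,
    build_rate_matrix,
    expected_rate,
    filter_alignment,
    fit_branch_model,
    lrt,
)
from selscan.codon.code import CODON_INDEX, NONSYNONYMOUS, SINGLE_NT
from selscan.simulate import (
    OneRatioRegime,
    SimulationConfig,
    TwoRatioRegime,
    simulate_codon_alignment,
)
from selscan.tree import parse_newick


def random_pi(rng):
    pi = rng.dirichlet(np.ones(61))
    return pi / pi.sum()


class TestRateMatrix:
    def test_purifying_limit_zeroes_nonsynonymous_rates(self):
        rng = np.random.default_rng(0)
        q = build_rate_matrix(2.0, random_pi(rng), 0.0)
        assert np.all(q[NONSYNONYMOUS] == 0.0)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        q = build_rate_matrix(3.0, random_pi(rng), 0.7)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_neutral_uniform_stationary_distribution(self):
        pi = np.full(61, 1 / 61)
        q = build_rate_matrix(1.0, pi, 1.0)
        assert np.abs(pi @ q).max() < 1e-14
        assert np.allclose(q, q.T)  # uniform pi makes GY94 symmetric

    @pytest.mark.parametrize("seed", range(5))
    def test_detailed_balance_and_stationarity(self, seed):
        rng = np.random.default_rng(seed)
        pi = random_pi(rng)
        kappa = rng.uniform(0.5, 5)
        omega = rng.uniform(0.01, 3)
        q = build_rate_matrix(kappa, pi, omega)
        flux = pi[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-12
        assert np.abs(pi @ q).max() < 1e-10

    def test_scaling_gives_unit_expected_rate(self):
        rng = np.random.default_rng(2)
        pi = random_pi(rng)
        rate = expected_rate(2.0, pi, 0.4)
        q = build_rate_matrix(2.0, pi, 0.4, scale=rate)
        assert -np.dot(pi, np.diag(q)) == pytest.approx(1.0)


class TestFilterAlignment:
    def _aln(self, n_codons, taxa=("a", "b")):
        seq = "".join(itertools.islice(itertools.cycle(["ATG", "AAA", "CCC"]), n_codons))
        return CodonAlignment(list(taxa), [seq] * len(taxa))

    def test_short_alignment_rejected(self):
        with pytest.raises(AlignmentError, match="99"):
            filter_alignment(self._aln(32))  # 96 nt

    def test_boundary_length_accepted(self):
        assert filter_alignment(self._aln(33)).length == 99

    def test_all_gap_column_removed(self):
        aln = CodonAlignment(
            ["a", "b"],
            ["ATG" + "---" + "AAA" * 32, "ATG" + "---" + "AAA" * 32],
        )
        out = filter_alignment(aln)
        assert out.length == aln.length - 3

    def test_stop_codon_rejected_with_position(self):
        aln = CodonAlignment(["a", "b"], ["ATGTAAAAA" * 11, "ATGAAAAAA" * 11])
        with pytest.raises(AlignmentError, match="position 4"):
            filter_alignment(aln)


def brute_force_loglik(tree, aln, pi, kappa, scale, omega_bg, omega_fg=None):
    """Exhaustive enumeration over internal-node states; scipy expm."""
    if omega_fg is None:
        omega_fg = omega_bg
    rate = expected_rate(kappa, pi, omega_bg)
    mats = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        om = omega_fg if node.foreground else omega_bg
        q = build_rate_matrix(kappa, pi, om, scale=rate)
        mats[node.index] = scipy_expm(q * node.length * scale)
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    mat = aln.codon_matrix()
    row = {t: i for i, t in enumerate(aln.taxa)}
    total = 0.0
    for s in range(aln.n_codons):
        site_l = 0.0
        for assignment in itertools.product(range(61), repeat=len(internal)):
            states = {n.index: a for n, a in zip(internal, assignment)}
            for leaf in leaves:
                states[leaf.index] = mat[row[leaf.name], s]
            prob = pi[states[tree.root]]
            for node in nodes:
                if node.parent is None:
                    continue
                prob *= mats[node.index][states[node.parent], states[node.index]]
            site_l += prob
        total += np.log(site_l)
    return total


class TestLikelihoodOracle:
    def test_single_leaf_is_log_pi(self):
        tree = parse_newick("A;")
        aln = CodonAlignment(["A"], ["ATG"])
        rng = np.random.default_rng(3)
        pi = random_pi(rng)
        engine = CodonLikelihood(tree, aln, pi=pi)
        assert engine.loglik_branch(2.0, 1.0, 0.5) == pytest.approx(
            np.log(pi[CODON_INDEX["ATG"]])
        )

    def test_zero_branch_lengths_identical_sequences(self):
        tree = parse_newick("(A:0,B:0,C:0);")
        aln = CodonAlignment(["A", "B", "C"], ["ATGAAA"] * 3)
        rng = np.random.default_rng(4)
        pi = random_pi(rng)
        engine = CodonLikelihood(tree, aln, pi=pi)
        expected = sum(np.log(pi[CODON_INDEX[c]]) for c in ("ATG", "AAA"))
        assert engine.loglik_branch(2.0, 1.0, 0.5) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_pruning_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = parse_newick("((A:0.3,B:0.15):0.2,C:0.4);")
        if seed % 2:
            tree.set_foreground(["A"])
        n_sites = int(rng.integers(1, 6))
        seqs = [
            "".join(CODONS[i] for i in rng.integers(0, 61, size=n_sites))
            for _ in range(3)
        ]
        aln = CodonAlignment(["A", "B", "C"], seqs)
        pi = random_pi(rng)
        kappa = rng.uniform(0.5, 4)
        omega_bg = rng.uniform(0.05, 2)
        omega_fg = rng.uniform(0.05, 3)
        scale = rng.uniform(0.5, 2)
        engine = CodonLikelihood(tree, aln, pi=pi)
        fast = engine.loglik_branch(kappa, scale, omega_bg, omega_fg)
        slow = brute_force_loglik(tree, aln, pi, kappa, scale, omega_bg, omega_fg)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_missing_taxon_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        aln = CodonAlignment(["A"], ["ATG"])
        with pytest.raises(ValueError, match="missing"):
            CodonLikelihood(tree, aln)

    def test_gap_codons_are_missing_data(self):
        tree = parse_newick("(A:0.2,B:0.2);")
        pi = np.full(61, 1 / 61)
        full = CodonAlignment(["A", "B"], ["ATG", "AAA"])
        gapped = CodonAlignment(["A", "B"], ["ATG---", "AAA---"])
        e1 = CodonLikelihood(tree, full, pi=pi)
        e2 = CodonLikelihood(tree, gapped, pi=pi)
        # the all-gap column contributes log(1) = 0
        assert e1.loglik_branch(2.0, 1.0, 0.5) == pytest.approx(
            e2.loglik_branch(2.0, 1.0, 0.5)
        )


class TestBranchFits:
    def test_one_ratio_recovery(self, heron_tree):
        aln, _ = simulate_codon_alignment(
            SimulationConfig(heron_tree, 500, OneRatioRegime(0.2), seed=11)
        )
        fit = fit_branch_model(heron_tree, aln, two_ratio=False, n_restarts=2, seed=0)
        assert fit.params.omega_by_class["background"] == pytest.approx(0.2, abs=0.1)

    def test_two_ratio_recovery_detects_positive_foreground(self, heron_tree):
        aln, _ = simulate_codon_alignment(
            SimulationConfig(heron_tree, 500, TwoRatioRegime(0.2, 1.5), seed=12)
        )
        null = fit_branch_model(heron_tree, aln, two_ratio=False, n_restarts=1, seed=0)
        alt = fit_branch_model(heron_tree, aln, two_ratio=True, n_restarts=1,
                               seed=0, init=null.params)
        assert alt.params.omega_by_class["foreground"] > 1.0
        assert alt.lnL >= null.lnL - 1e-6

    def test_two_ratio_requires_foreground(self, fixture_tree):
        aln, _ = simulate_codon_alignment(
            SimulationConfig(parse_newick("(A:0.1,B:0.1);"), 40,
                             OneRatioRegime(0.5), seed=13)
        )
        with pytest.raises(ValueError, match="foreground"):
            fit_branch_model(parse_newick("(A:0.1,B:0.1);"), aln, two_ratio=True)


class TestLRT:
    def _fit(self, lnl, n_free):
        params = CodonModelParams(
            kappa=2.0, codon_frequencies=np.full(61, 1 / 61),
            omega_by_class={"background": 0.5},
        )
        from selscan.codon import FitResult

        return FitResult(lnl, params, n_free, True, 1)

    def test_identical_fits_give_p_one(self):
        res = lrt(self._fit(-100.0, 3), self._fit(-100.0, 4), 1)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_chi2_quantile(self):
        res = lrt(self._fit(-100.0, 3), self._fit(-100.0 + 3.841 / 2, 4), 1)
        assert res.p == pytest.approx(0.05, abs=1e-3)

    def test_zero_statistic_df2(self):
        assert lrt(self._fit(-5.0, 3), self._fit(-5.0, 5), 2).p == 1.0

    def test_alt_below_null_is_an_error(self):
        with pytest.raises(ValueError, match="optimizer"):
            lrt(self._fit(-100.0, 3), self._fit(-100.1, 4), 1)

    def test_boundary_mixture_halves_p(self):
        from scipy.stats import chi2

        res = lrt(self._fit(-100.0, 7), self._fit(-98.0, 8), "mixture01")
        assert res.p == pytest.approx(0.5 * chi2.sf(4.0, 1))
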