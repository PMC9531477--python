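"""GY94-style codon substitution model and pruning likelihood.

The instantaneous rate of change between codons differing at exactly one
nucleotide is pi_j * kappa^[transition] * omega^[nonsynonymous]; all
multi-nucleotide exchanges are instantaneous-rate zero.  The chain is
reversible with stationary distribution pi, so transition probabilities
are computed through a symmetric eigendecomposition.  Rate matrices are
scaled so branch lengths are expected substitutions per codon under the
background omega class.

Likelihoods are computed by Felsenstein pruning over unique site
patterns, with per-site rescaling against underflow.  Gap codons are
missing data (partial likelihood one).  For mixture models the per-site
likelihood is the weight-average of the per-class site likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..tree import PhyloTree
from .code import (
    N_CODONS,
    NONSYNONYMOUS,
    SINGLE_NT,
    TRANSITION,
    codon_indices,
    f3x4_frequencies,
)

__all__ = [
    "CodonAlignment",
    "MixtureParams",
    "CodonModelParams",
    "AlignmentError",
    "filter_alignment",
    "build_rate_matrix",
    "expected_rate",
    "CodonLikelihood",
    "log_likelihood",
]


class AlignmentError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """A gap-aware in-frame codon alignment."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa/sequence count mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError("sequences have unequal lengths")
        if self.length % 3:
            raise AlignmentError("alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon_matrix(self) -> np.ndarray:
        """(n_taxa, n_codons) state indices; -1 for gap/ambiguous codons.
        Raises on stop codons."""
        rows = []
        for taxon, seq in zip(self.taxa, self.sequences):
            try:
                rows.append(codon_indices(seq))
            except ValueError as exc:
                raise AlignmentError(f"{taxon}: {exc}") from None
        return np.vstack(rows)


def filter_alignment(alignment: CodonAlignment, min_len: int = 99) -> CodonAlignment:
    """Apply the short-alignment filter and drop all-gap codon columns.

    Alignments shorter than *min_len* nucleotides (after removing columns
    that are gaps in every taxon) are rejected, as are alignments
    containing stop codons.
    """
    mat = alignment.codon_matrix()  # validates stops
    keep = ~np.all(mat == -1, axis=0)
    new_seqs = [
        "".join(seq[3 * k : 3 * k + 3] for k in range(alignment.n_codons) if keep[k])
        for seq in alignment.sequences
    ]
    out = CodonAlignment(list(alignment.taxa), new_seqs)
    if out.length < min_len:
        raise AlignmentError(
            f"alignment of {out.length} nt is shorter than the {min_len} nt minimum"
        )
    return out


@dataclass
class MixtureParams:
    """Three-class omega mixture: omega1 <= omega2 <= 1 <= omega3."""

    omegas: tuple[float, float, float]
    weights: tuple[float, float, float]
    foreground_omega3: float | None = None  # episodic test: separate fg class 3

    def __post_init__(self):
        w1, w2, w3 = self.omegas
        if not (w1 <= w2 <= 1.0 <= w3):
            raise ValueError(f"mixture ordering violated: {self.omegas}")
        if abs(sum(self.weights) - 1.0) > 1e-8 or min(self.weights) < 0:
            raise ValueError("mixture weights must lie on the simplex")
        if self.foreground_omega3 is not None and self.foreground_omega3 < 1.0:
            raise ValueError("foreground omega3 must be >= 1")


@dataclass
class CodonModelParams:
    kappa: float
    codon_frequencies: np.ndarray
    omega_by_class: Mapping[str, float] | None = None  # {"background","foreground"}
    mixture: MixtureParams | None = None
    k: float | None = None  # selection-intensity exponent (foreground = bg^k)
    branch_scale: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        pi = np.asarray(self.codon_frequencies, dtype=float)
        if pi.shape != (N_CODONS,) or abs(pi.sum() - 1.0) > 1e-6 or pi.min() < 0:
            raise ValueError("codon frequencies must be a 61-simplex vector")
        self.codon_frequencies = pi / pi.sum()
        if self.k is not None and self.k < 0:
            raise ValueError("k must be non-negative")


def build_rate_matrix(
    kappa: float, pi: np.ndarray, omega: float, scale: float | None = None
) -> np.ndarray:
    """61x61 GY94 generator; rows sum to zero.

    If *scale* is given the matrix is divided by it; pass
    ``expected_rate`` of the background class so branch lengths read as
    expected substitutions per codon at the background omega.
    """
    factor = np.where(SINGLE_NT, np.where(TRANSITION, kappa, 1.0), 0.0)
    factor = factor * np.where(NONSYNONYMOUS, omega, 1.0)
    q = factor * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale is not None:
        q = q / scale
    return q


def expected_rate(kappa: float, pi: np.ndarray, omega: float) -> float:
    """Expected substitutions per codon per unit time for an unscaled matrix."""
    q = build_rate_matrix(kappa, pi, omega)
    return float(-np.dot(pi, np.diag(q)))


class _Spectral:
    """Eigendecomposition of a reversible generator for fast expm."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        b = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        w, u = np.linalg.eigh((b + b.T) / 2.0)
        # generator eigenvalues are non-positive; clip roundoff positives so
        # exp(w t) cannot overflow for extreme omega values
        self.w = np.minimum(w, 0.0)
        self.left = u / sqrt_pi[:, None]  # D^-1 U
        self.right = u.T * sqrt_pi[None, :]  # U^T D

    def expm(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(p, 0.0, None, out=p)
        return p


class CodonLikelihood:
    """Pruning-algorithm likelihood evaluator bound to (tree, alignment).

    Branch omega classes are looked up per node: foreground-flagged
    branches use the "foreground" omega, all others "background".
    """

    def __init__(self, tree: PhyloTree, alignment: CodonAlignment,
                 pi: np.ndarray | None = None):
        leaf_names = set(tree.leaf_names())
        missing = leaf_names - set(alignment.taxa)
        if missing:
            raise ValueError(f"taxa missing from alignment: {sorted(missing)}")
        self.tree = tree
        self.alignment = alignment
        self.pi = f3x4_frequencies(alignment.sequences) if pi is None else np.asarray(pi)

        mat = alignment.codon_matrix()
        taxon_row = {t: i for i, t in enumerate(alignment.taxa)}
        order = [taxon_row[n.name] for n in tree.postorder() if n.is_leaf]
        mat = mat[order]
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_leaves, n_patterns)
        self.pattern_counts = counts.astype(float)
        self.pattern_inverse = inverse
        self.postorder = list(tree.postorder())
        self._leaf_rank = {}
        r = 0
        for node in self.postorder:
            if node.is_leaf:
                self._leaf_rank[node.index] = r
                r += 1
        # leaf partials are 0/1 indicators; build once
        npat = patterns.shape[1]
        self._leaf_partials = {}
        for node in self.postorder:
            if not node.is_leaf:
                continue
            states = patterns[self._leaf_rank[node.index]]
            part = np.zeros((N_CODONS, npat))
            obs = states >= 0
            part[states[obs], np.nonzero(obs)[0]] = 1.0
            part[:, ~obs] = 1.0
            self._leaf_partials[node.index] = part

    # -- core ------------------------------------------------------------
    def _pattern_loglik(self, kappa: float, scale: float,
                        omega_bg: float, omega_fg: float,
                        rate: float | None = None,
                        cache: dict | None = None) -> np.ndarray:
        """Per-pattern log-likelihood for one background/foreground omega pair.

        *rate* fixes the time-scale normalization (shared across mixture
        components); when omitted it is the expected rate at omega_bg.
        *cache* memoizes spectral decompositions by omega within one
        likelihood evaluation.
        """
        pi = self.pi
        if rate is None:
            rate = expected_rate(kappa, pi, omega_bg)
        if cache is None:
            cache = {}

        def spec_for(omega: float) -> _Spectral:
            if cache is not None and omega in cache:
                return cache[omega]
            s = _Spectral(build_rate_matrix(kappa, pi, omega, scale=rate), pi)
            if cache is not None:
                cache[omega] = s
            return s

        spectral = {"background": spec_for(omega_bg),
                    "foreground": spec_for(omega_fg)}

        npat = self.patterns.shape[1]
        log_scale = np.zeros(npat)
        partial = {}
        for node in self.postorder:
            if node.is_leaf:
                partial[node.index] = self._leaf_partials[node.index]
                continue
            acc = np.ones((N_CODONS, npat))
            for child_idx in node.children:
                child = self.tree.nodes[child_idx]
                spec = spectral["foreground" if child.foreground else "background"]
                p = spec.expm(child.length * scale)
                acc *= p @ partial[child_idx]
                del partial[child_idx]
            m = acc.max(axis=0)
            m[m == 0.0] = 1.0
            acc /= m
            log_scale += np.log(m)
            partial[node.index] = acc
        root = partial[self.tree.nodes[self.tree.root].index]
        site_l = pi @ root
        return np.log(np.maximum(site_l, 1e-300)) + log_scale

    def loglik_branch(self, kappa: float, scale: float,
                      omega_bg: float, omega_fg: float | None = None) -> float:
        if omega_fg is None:
            omega_fg = omega_bg
        ll = self._pattern_loglik(kappa, scale, omega_bg, omega_fg)
        return float(ll @ self.pattern_counts)

    def loglik_mixture(
        self,
        kappa: float,
        scale: float,
        components: Sequence[tuple[float, float, float]],
    ) -> float:
        """components: (weight, omega_background, omega_foreground) triples.

        All components share one time scale: the weight-averaged expected
        substitution rate over the background classes (the expected rate
        is linear in omega, so this equals the rate at the mean omega).
        """
        rate = sum(w * expected_rate(kappa, self.pi, wb) for w, wb, _ in components)
        cache: dict = {}
        per_class = np.array(
            [self._pattern_loglik(kappa, scale, wb, wf, rate=rate, cache=cache)
             for _, wb, wf in components]
        )
        logw = np.log(np.array([max(c[0], 1e-300) for c in components]))
        stacked = per_class + logw[:, None]
        m = stacked.max(axis=0)
        site_ll = m + np.log(np.exp(stacked - m).sum(axis=0))
        return float(site_ll @ self.pattern_counts)

    def site_log_likelihoods(self, kappa, scale, omega_bg, omega_fg=None) -> np.ndarray:
        """Per-codon-column log-likelihoods (expanded from patterns)."""
        if omega_fg is None:
            omega_fg = omega_bg
        ll = self._pattern_loglik(kappa, scale, omega_bg, omega_fg)
        return ll[self.pattern_inverse]


def _mixture_components(params: CodonModelParams) -> list[tuple[float, float, float]]:
    mix = params.mixture
    if params.k is not None:
        # selection-intensity model: same class on both partitions,
        # foreground omega raised to the power k
        return [
            (mix.weights[c], mix.omegas[c], float(np.power(mix.omegas[c], params.k)))
            for c in range(3)
        ]
    if mix.foreground_omega3 is not None:
        # episodic model: classes drawn independently per partition
        fg = (mix.omegas[0], mix.omegas[1], mix.foreground_omega3)
        return [
            (mix.weights[i] * mix.weights[j], mix.omegas[i], fg[j])
            for i in range(3)
            for j in range(3)
        ]
    return [(mix.weights[c], mix.omegas[c], mix.omegas[c]) for c in range(3)]


def log_likelihood(tree: PhyloTree, alignment: CodonAlignment,
                   params: CodonModelParams) -> float:
    """Log-likelihood of an alignment under a codon model on a tree."""
    engine = CodonLikelihood(tree, alignment, pi=params.codon_frequencies)
    if params.mixture is not None:
        return engine.loglik_mixture(
            params.kappa, params.branch_scale, _mixture_components(params)
        )
    omega_map = params.omega_by_class or {"background": 1.0}
    bg = omega_map.get("background", 1.0)
    fg = omega_map.get("foreground", bg)
    return engine.loglik_branch(params.kappa, params.branch_scale, bg, fg)
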