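"""SLAC-style counting test for site-level selection.

Ancestral codon states are reconstructed by marginal posterior (MAP) at
each internal node under a fitted model; synonymous and nonsynonymous
changes are then counted per codon column along every branch, averaging
over equally weighted minimal mutational pathways when parent and child
differ at more than one nucleotide.  Expected proportions come from
Nei–Gojobori synonymous/nonsynonymous site counts of the codons observed
at the site, and a two-sided binomial test per site compares the
observed nonsynonymous fraction against that expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from ..tree import PhyloTree
from .code import (
    AMINO_ACIDS,
    CODON_INDEX,
    CODONS,
    NONSYN_SITES,
    STOP_CODONS,
    SYN_SITES,
)
from .model import CodonAlignment, CodonLikelihood, CodonModelParams, build_rate_matrix, expected_rate
from .model import _Spectral  # shared expm machinery

__all__ = ["SiteSelectionResult", "slac_site_test", "pathway_counts"]


@dataclass
class SiteSelectionResult:
    dn: np.ndarray  # per-site nonsynonymous changes per nonsynonymous site
    ds: np.ndarray
    omega_proxy: np.ndarray  # dn/ds, inf where ds == 0 and dn > 0, nan where both 0
    n_obs: np.ndarray  # observed nonsynonymous counts
    s_obs: np.ndarray
    p: np.ndarray

    def __len__(self) -> int:
        return len(self.p)


def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) changes between two codons, averaged
    over all minimal single-step pathways that avoid stop codons."""
    diffs = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in permutations(diffs):
        cur, s, n, ok = codon_a, 0, 0, True
        for p in order:
            nxt = cur[:p] + codon_b[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AMINO_ACIDS[CODON_INDEX[cur]] == AMINO_ACIDS[CODON_INDEX[nxt]]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            totals.append((s, n))
    if not totals:  # every pathway passes through a stop; count all as nonsyn
        return 0.0, float(len(diffs))
    s = sum(t[0] for t in totals) / len(totals)
    n = sum(t[1] for t in totals) / len(totals)
    return s, n


def _ancestral_map(engine: CodonLikelihood, params: CodonModelParams) -> dict[int, np.ndarray]:
    """MAP codon state per internal node per pattern (marginal posterior)."""
    tree = engine.tree
    pi = engine.pi
    kappa = params.kappa
    scale = params.branch_scale
    omega = (params.omega_by_class or {"background": 1.0}).get("background", 1.0)
    rate = expected_rate(kappa, pi, omega)
    spec = _Spectral(build_rate_matrix(kappa, pi, omega, scale=rate), pi)

    npat = engine.patterns.shape[1]
    # upward (pruning) partials per node
    up: dict[int, np.ndarray] = {}
    for node in engine.postorder:
        if node.is_leaf:
            up[node.index] = engine._leaf_partials[node.index]
        else:
            acc = np.ones((len(pi), npat))
            for ci in node.children:
                child = tree.nodes[ci]
                acc *= spec.expm(child.length * scale) @ up[ci]
            m = acc.max(axis=0)
            m[m == 0] = 1.0
            up[node.index] = acc / m
    # downward pass
    down: dict[int, np.ndarray] = {tree.root: np.tile(pi[:, None], (1, npat))}
    states: dict[int, np.ndarray] = {}
    for node in reversed(list(engine.postorder)):
        if node.is_leaf:
            continue
        post = up[node.index] * down[node.index]
        states[node.index] = np.argmax(post, axis=0)
        for ci in node.children:
            child = tree.nodes[ci]
            p = spec.expm(child.length * scale)
            sibs = np.ones((len(pi), npat))
            for cj in node.children:
                if cj == ci:
                    continue
                sib = tree.nodes[cj]
                sibs *= spec.expm(sib.length * scale) @ up[cj]
            msg = down[node.index] * sibs  # prob flowing into the child edge
            down[ci] = p.T @ msg
            m = down[ci].max(axis=0)
            m[m == 0] = 1.0
            down[ci] /= m
    return states


def slac_site_test(tree: PhyloTree, alignment: CodonAlignment,
                   fitted_params: CodonModelParams) -> SiteSelectionResult:
    """Counting-based per-site selection test under a fitted global model."""
    engine = CodonLikelihood(tree, alignment, pi=fitted_params.codon_frequencies)
    anc = _ancestral_map(engine, fitted_params)
    patterns = engine.patterns
    npat = patterns.shape[1]

    syn_counts = np.zeros(npat)
    nonsyn_counts = np.zeros(npat)
    syn_sites = np.zeros(npat)
    nonsyn_sites = np.zeros(npat)
    site_denominator = np.zeros(npat)

    def node_states(node) -> np.ndarray:
        if node.is_leaf:
            return patterns[engine._leaf_rank[node.index]]
        return anc[node.index]

    for node in engine.postorder:
        if node.parent is None:
            continue
        parent_states = node_states(engine.tree.nodes[node.parent])
        child_states = node_states(node)
        for s in range(npat):
            a, b = parent_states[s], child_states[s]
            if a < 0 or b < 0:
                continue
            sy, ns = pathway_counts(CODONS[a], CODONS[b])
            syn_counts[s] += sy
            nonsyn_counts[s] += ns
    # expected proportions from the codons observed/reconstructed at the site
    for node in engine.postorder:
        st = node_states(node)
        for s in range(npat):
            if st[s] >= 0:
                syn_sites[s] += SYN_SITES[st[s]]
                nonsyn_sites[s] += NONSYN_SITES[st[s]]
                site_denominator[s] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_syn = syn_sites / site_denominator
        mean_nonsyn = nonsyn_sites / site_denominator
        dn = np.where(mean_nonsyn > 0, nonsyn_counts / mean_nonsyn, 0.0)
        ds = np.where(mean_syn > 0, syn_counts / mean_syn, 0.0)
        omega_proxy = np.where(
            ds > 0, dn / ds, np.where(dn > 0, np.inf, np.nan)
        )

    p = np.ones(npat)
    for s in range(npat):
        total = syn_counts[s] + nonsyn_counts[s]
        if total <= 0:
            continue
        prob_nonsyn = mean_nonsyn[s] / (mean_nonsyn[s] + mean_syn[s])
        n_int = int(round(total))
        k_int = int(round(nonsyn_counts[s]))
        k_int = min(k_int, n_int)
        p[s] = stats.binomtest(k_int, n_int, prob_nonsyn, alternative="two-sided").pvalue

    inv = engine.pattern_inverse
    return SiteSelectionResult(
        dn=dn[inv], ds=ds[inv], omega_proxy=omega_proxy[inv],
        n_obs=nonsyn_counts[inv], s_obs=syn_counts[inv], p=p[inv],
    )
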