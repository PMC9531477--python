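"""The standard genetic code as index arrays over the 61 sense codons.

State space and precomputed structure shared by the rate-matrix builder,
the simulator and the counting-based site test: codon list/index, codon
translation, transition-vs-transversion and synonymous-vs-nonsynonymous
masks for all single-nucleotide codon changes, and Nei–Gojobori style
synonymous/nonsynonymous site counts per codon.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCS = "TCAG"
_table = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code

STOP_CODONS = frozenset(_table.stop_codons)
CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in product(NUCS, repeat=3) if "".join(c) not in STOP_CODONS
)
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO_ACIDS = tuple(_table.forward_table[c] for c in CODONS)

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES) and a != b


def _build_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    ts = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            single[i, j] = True
            ts[i, j] = is_transition(ci[p], cj[p])
            nonsyn[i, j] = AMINO_ACIDS[i] != AMINO_ACIDS[j]
    return single, ts, nonsyn


SINGLE_NT, TRANSITION, NONSYNONYMOUS = _build_masks()


def syn_nonsyn_site_counts(codon: str) -> tuple[float, float]:
    """Nei–Gojobori counts of synonymous and nonsynonymous sites.

    Each position contributes the fraction of its three possible
    single-nucleotide changes that are synonymous (changes into stop
    codons count as nonsynonymous).  Returns (S, N) with S + N = 3.
    """
    s = 0.0
    for p in range(3):
        syn = 0
        for n in NUCS:
            if n == codon[p]:
                continue
            alt = codon[:p] + n + codon[p + 1:]
            if alt not in STOP_CODONS and _table.forward_table[alt] == _table.forward_table[codon]:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


SYN_SITES = np.array([syn_nonsyn_site_counts(c)[0] for c in CODONS])
NONSYN_SITES = 3.0 - SYN_SITES


def codon_indices(seq: str) -> np.ndarray:
    """Map an in-frame nucleotide string to codon state indices.

    Gap codons (``---``) and codons with ambiguity characters map to -1
    (treated as missing data).  Stop codons raise.
    """
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3].upper()
        if codon in CODON_INDEX:
            out[k // 3] = CODON_INDEX[codon]
        elif codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at nucleotide position {k + 1}")
        else:
            out[k // 3] = -1
    return out


def f3x4_frequencies(sequences, floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies: products of per-codon-position nucleotide
    frequencies estimated from the data, renormalized over sense codons."""
    pos_counts = np.full((3, 4), floor)
    nuc_index = {n: i for i, n in enumerate(NUCS)}
    for seq in sequences:
        for k in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[k : k + 3].upper()
            for p, n in enumerate(codon):
                if n in nuc_index:
                    pos_counts[p, nuc_index[n]] += 1
    pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [pos_freq[0, nuc_index[c[0]]] * pos_freq[1, nuc_index[c[1]]] * pos_freq[2, nuc_index[c[2]]]
         for c in CODONS]
    )
    return pi / pi.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)
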