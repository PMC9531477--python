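"""Column-wise Shannon entropy of protein alignments.

Per-column variability of an olfactory-receptor alignment is measured as
H = -sum_a f_a log2 f_a over the residues observed in that column, gaps
excluded.  H is in bits, bounded by log2(20) ~ 4.32 for the amino-acid
alphabet.  Positions with H <= 1.0 bits are highly conserved and
positions with H >= 2.0 bits are variable (boundaries go to the more
extreme class); everything between is conserved.  Species-level
repertoire diversity is the mean +/- sample standard deviation across
columns, and two species sharing an alignment coordinate system are
compared column-by-column with a Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EntropyProfile",
    "column_entropy",
    "classify_position",
    "profile_alignment",
    "paired_entropy_test",
]

GAP_CHARS = set("-.")
MAX_H = math.log2(20.0)

VARIABLE_MIN = 2.0  # H >= this -> variable
HIGHLY_CONSERVED_MAX = 1.0  # H <= this -> highly conserved


@dataclass
class EntropyProfile:
    h: np.ndarray  # bits per retained column
    classes: list[str]
    mean: float
    sd: float

    def __len__(self) -> int:
        return len(self.h)

    def summary(self) -> str:
        return f"{self.mean:.3f} ± {self.sd:.3f}"


def column_entropy(column: Iterable[str], base: float = 2.0) -> float:
    """Shannon entropy of one alignment column, gaps excluded."""
    residues = [c.upper() for c in column if c.upper() not in GAP_CHARS]
    if not residues:
        raise ValueError("all-gap column has no defined entropy")
    counts = np.array(list(Counter(residues).values()), dtype=float)
    f = counts / counts.sum()
    h = float(-(f * (np.log(f) / np.log(base))).sum())
    return h + 0.0  # normalize -0.0 on invariant columns


def classify_position(
    h: float,
    variable_min: float = VARIABLE_MIN,
    highly_conserved_max: float = HIGHLY_CONSERVED_MAX,
) -> str:
    if h < 0:
        raise ValueError("entropy must be non-negative")
    if h >= variable_min:
        return "variable"
    if h <= highly_conserved_max:
        return "highly_conserved"
    return "conserved"


def profile_alignment(
    sequences: Iterable[tuple[str, str]] | Iterable[str],
    base: float = 2.0,
    variable_min: float = VARIABLE_MIN,
    highly_conserved_max: float = HIGHLY_CONSERVED_MAX,
) -> EntropyProfile:
    """Per-column entropy profile of an aligned protein set.

    Accepts (id, sequence) pairs or bare sequences; all sequences must
    have equal length.  Columns that are entirely gaps are dropped.
    """
    seqs = [s[1] if isinstance(s, tuple) else s for s in sequences]
    if not seqs:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    hs = []
    for col in zip(*seqs):
        if all(c.upper() in GAP_CHARS for c in col):
            continue
        hs.append(column_entropy(col, base=base))
    if not hs:
        raise ValueError("alignment has no non-gap columns")
    h = np.array(hs)
    classes = [classify_position(x, variable_min, highly_conserved_max) for x in h]
    sd = float(h.std(ddof=1)) if len(h) > 1 else 0.0
    return EntropyProfile(h=h, classes=classes, mean=float(h.mean()), sd=sd)


def paired_entropy_test(
    profile_a: EntropyProfile | Sequence[float],
    profile_b: EntropyProfile | Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on per-column entropy differences (B - A).

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without rank ties, otherwise the tie-corrected normal
    approximation.  ``alternative='greater'`` tests whether B tends to
    exceed A.  Returns (statistic, p).
    """
    a = np.asarray(profile_a.h if isinstance(profile_a, EntropyProfile) else profile_a, float)
    b = np.asarray(profile_b.h if isinstance(profile_b, EntropyProfile) else profile_b, float)
    if a.shape != b.shape:
        raise ValueError("profiles must share a column coordinate system")
    alternative = alternative.replace("_", "-")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"bad alternative {alternative!r}")
    d = b - a
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(ranks)) != len(ranks)
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method, correction=False)
    return float(res.statistic), float(res.pvalue)
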