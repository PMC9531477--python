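"""Per-gene selection-signature classification and evidence combination.

Three complementary tests are commonly run per gene against a foreground
lineage: a branch-model likelihood ratio test contrasting a single dN/dS
ratio (omega) with separate foreground/background ratios; a gene-wide
episodic positive-selection mixture test (BUSTED-style); and a selection
intensity test (RELAX-style) whose parameter k > 1 indicates intensified
and k < 1 relaxed selection on the foreground.  This module classifies
each method's printed statistics, combines them into a single call — a
positive signature corroborated by intensification is treated as true
positive selection, while a positive signature co-occurring with
relaxation is treated as relaxation — and summarizes a species table
into the gene sets a comparative study reports.

All significance thresholds are inclusive (q <= alpha): a q-value printed
exactly at the cutoff counts as significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneSelectionRecord",
    "SelectionCall",
    "SpeciesSummary",
    "CrossSpeciesComparison",
    "bh_fdr",
    "classify_paml",
    "classify_busted",
    "classify_relax",
    "combine_evidence",
    "classify_record",
    "summarize_species",
    "compare_species",
]

PAML_LABELS = ("positive", "relaxed", "intensified", "ns")
BUSTED_LABELS = ("positive", "ns")
RELAX_LABELS = ("relaxed", "intensified", "ns")
COMBINED_LABELS = (
    "positive_corroborated",
    "positive_uncorroborated",
    "relaxed",
    "intensified",
    "ns",
)


@dataclass(frozen=True)
class GeneSelectionRecord:
    """One gene's printed statistics from the three selection methods."""

    gene: str
    species: str
    paml_omega_bg: float  # one/two-ratio background omega (omega0)
    paml_omega_fg: float  # foreground omega (omega1)
    paml_p: float
    paml_q: float
    busted_p: float
    busted_q: float
    relax_k: float
    relax_p: float
    relax_q: float
    busted_omega3_fg_gt_bg: bool | None = None

    def __post_init__(self):
        for name in ("paml_p", "paml_q", "busted_p", "busted_q", "relax_p", "relax_q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.gene}: {name}={v} outside [0, 1]")
        for name in ("paml_omega_bg", "paml_omega_fg", "relax_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.gene}: {name} must be non-negative")


@dataclass(frozen=True)
class SelectionCall:
    gene: str
    paml_label: str
    busted_label: str
    relax_label: str
    combined_label: str
    conflict: bool = False  # relaxed-vs-intensified disagreement between methods


@dataclass
class SpeciesSummary:
    """Gene sets of a species table under the three-method rubric.

    The ``relaxed_*`` / ``intensified_*`` buckets cover only genes
    without a positive signature; genes that are positive by PAML or
    BUSTED are accounted for in the ``positive_*`` buckets (including
    their RELAX corroboration status).
    """

    species: str
    calls: dict[str, SelectionCall]
    positive_any: list[str] = field(default_factory=list)
    positive_paml_and_busted: list[str] = field(default_factory=list)
    positive_busted_only: list[str] = field(default_factory=list)
    positive_with_relax_intensified: list[str] = field(default_factory=list)
    positive_with_relax_relaxed: list[str] = field(default_factory=list)
    relaxed_paml_and_relax: list[str] = field(default_factory=list)
    relaxed_paml_only: list[str] = field(default_factory=list)
    relaxed_relax_only: list[str] = field(default_factory=list)
    intensified_paml: list[str] = field(default_factory=list)
    intensified_relax: list[str] = field(default_factory=list)
    intensified_both: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            name: len(getattr(self, name))
            for name in (
                "positive_any",
                "positive_paml_and_busted",
                "positive_busted_only",
                "positive_with_relax_intensified",
                "positive_with_relax_relaxed",
                "relaxed_paml_and_relax",
                "relaxed_paml_only",
                "relaxed_relax_only",
                "intensified_paml",
                "intensified_relax",
                "intensified_both",
            )
        }


@dataclass(frozen=True)
class CrossSpeciesComparison:
    shared_similar: list[str]
    shared_different: list[str]


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    clipped at 1.  Each q is >= its p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def classify_paml(record: GeneSelectionRecord, alpha: float = 0.05) -> str:
    """Branch-model call: positive / relaxed / intensified / ns.

    Positive requires foreground omega > 1 with q <= alpha; otherwise a
    significantly higher (lower) foreground than background omega is read
    as relaxed (intensified) selection on the foreground.
    """
    if record.paml_q > alpha:
        return "ns"
    w0, w1 = record.paml_omega_bg, record.paml_omega_fg
    if w1 > 1.0:
        return "positive"
    if w1 > w0:
        return "relaxed"
    if w1 < w0:
        return "intensified"
    warnings.warn(
        f"{record.gene}: significant branch-model q but omega_fg == omega_bg; "
        "treating as ns",
        stacklevel=2,
    )
    return "ns"


def classify_busted(record: GeneSelectionRecord, alpha: float = 0.05) -> str:
    """Episodic positive-selection call: positive iff q <= alpha and, when
    reported, the foreground omega3 exceeds the background's."""
    if record.busted_q <= alpha and record.busted_omega3_fg_gt_bg is not False:
        return "positive"
    return "ns"


def classify_relax(record: GeneSelectionRecord, alpha: float = 0.05) -> str:
    """Selection-intensity call: k > 1 intensified, k < 1 relaxed (q <= alpha).

    k exactly 1 is indistinguishable from the null and returns ns
    regardless of q.
    """
    if record.relax_q > alpha or record.relax_k == 1.0:
        return "ns"
    return "intensified" if record.relax_k > 1.0 else "relaxed"


def combine_evidence(paml_label: str, busted_label: str, relax_label: str) -> tuple[str, bool]:
    """Combine the three per-method labels into one call.

    Returns ``(combined_label, conflict)``.  A positive signature (by
    either the branch model or the episodic test) corroborated by RELAX
    intensification is truly positive; a positive signature co-occurring
    with RELAX relaxation is read as relaxation of constraint; positive
    with no RELAX signal stays positive but uncorroborated.  Without a
    positive signature, either method's relaxed (intensified) verdict
    carries, and a relaxed-vs-intensified disagreement between the branch
    model and RELAX is returned as ns with the conflict flag set.
    """
    if paml_label not in PAML_LABELS:
        raise ValueError(f"bad paml label {paml_label!r}")
    if busted_label not in BUSTED_LABELS:
        raise ValueError(f"bad busted label {busted_label!r}")
    if relax_label not in RELAX_LABELS:
        raise ValueError(f"bad relax label {relax_label!r}")

    positive = paml_label == "positive" or busted_label == "positive"
    if positive:
        if relax_label == "intensified":
            return "positive_corroborated", False
        if relax_label == "relaxed":
            return "relaxed", False
        return "positive_uncorroborated", False

    says_relaxed = "relaxed" in (paml_label, relax_label)
    says_intens = "intensified" in (paml_label, relax_label)
    if says_relaxed and says_intens:
        return "ns", True
    if says_relaxed:
        return "relaxed", False
    if says_intens:
        return "intensified", False
    return "ns", False


def classify_record(record: GeneSelectionRecord, alpha: float = 0.05) -> SelectionCall:
    pl = classify_paml(record, alpha)
    bl = classify_busted(record, alpha)
    rl = classify_relax(record, alpha)
    combined, conflict = combine_evidence(pl, bl, rl)
    return SelectionCall(record.gene, pl, bl, rl, combined, conflict)


def summarize_species(
    records: Iterable[GeneSelectionRecord], alpha: float = 0.05
) -> SpeciesSummary:
    """Classify every row of a single-species table and bin the genes."""
    records = list(records)
    if not records:
        raise ValueError("empty table")
    species = {r.species for r in records}
    if len(species) != 1:
        raise ValueError(f"mixed species in table: {sorted(species)}")

    summary = SpeciesSummary(species=species.pop(), calls={})
    for rec in records:
        call = classify_record(rec, alpha)
        summary.calls[rec.gene] = call
        pl, bl, rl = call.paml_label, call.busted_label, call.relax_label
        positive = pl == "positive" or bl == "positive"
        if positive:
            summary.positive_any.append(rec.gene)
            if pl == "positive" and bl == "positive":
                summary.positive_paml_and_busted.append(rec.gene)
            elif bl == "positive":
                summary.positive_busted_only.append(rec.gene)
            if rl == "intensified":
                summary.positive_with_relax_intensified.append(rec.gene)
            elif rl == "relaxed":
                summary.positive_with_relax_relaxed.append(rec.gene)
        else:
            if pl == "relaxed" and rl == "relaxed":
                summary.relaxed_paml_and_relax.append(rec.gene)
            elif pl == "relaxed":
                summary.relaxed_paml_only.append(rec.gene)
            elif rl == "relaxed":
                summary.relaxed_relax_only.append(rec.gene)
            if pl == "intensified":
                summary.intensified_paml.append(rec.gene)
            if rl == "intensified":
                summary.intensified_relax.append(rec.gene)
            if pl == "intensified" and rl == "intensified":
                summary.intensified_both.append(rec.gene)
    return summary


def compare_species(
    summary_a: SpeciesSummary, summary_b: SpeciesSummary
) -> CrossSpeciesComparison:
    """Compare combined calls for genes present in both species tables.

    A shared gene with the same non-ns combined label in both species is
    *similar*; differing non-ns labels are *different*.  Genes without a
    signature in either species are listed in neither set.
    """
    if summary_a.species == summary_b.species and summary_a is not summary_b:
        warnings.warn("comparing two summaries of the same species", stacklevel=2)
    shared = sorted(set(summary_a.calls) & set(summary_b.calls))
    similar, different = [], []
    for gene in shared:
        la = summary_a.calls[gene].combined_label
        lb = summary_b.calls[gene].combined_label
        if la == "ns" or lb == "ns":
            continue
        if la == lb:
            similar.append(gene)
        else:
            different.append(gene)
    return CrossSpeciesComparison(similar, different)
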