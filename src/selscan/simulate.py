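"""Synthetic inputs with known ground truth.

Three generators: codon alignments evolved under branch-wise omega
regimes on a fixed tree (exercising the selection tests end to end),
small genomes with olfactory-receptor genes planted at known coordinates
and categories (exercising the OR mining pipeline), and toy protein
alignments drawn column-wise from given residue profiles (exercising the
entropy profiler).  Every generator is a pure function of its
configuration, including the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .codon.code import (
    AMINO_ACIDS,
    CODONS,
    N_CODONS,
    STOP_CODONS,
    uniform_frequencies,
)
from .codon.model import CodonAlignment, CodonModelParams, MixtureParams, build_rate_matrix, expected_rate
from .codon.model import _Spectral
from .io import SequenceSet
from .tree import PhyloTree

__all__ = [
    "OneRatioRegime",
    "TwoRatioRegime",
    "BustedRegime",
    "RelaxRegime",
    "SimulationConfig",
    "simulate_codon_alignment",
    "PlantConfig",
    "PlantedGene",
    "SyntheticTruth",
    "plant_or_genome",
    "make_toy_alignment",
    "make_or_reference_proteins",
    "make_outgroup_gpcrs",
]


# ---------------------------------------------------------------------------
# codon alignment simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OneRatioRegime:
    omega: float


@dataclass(frozen=True)
class TwoRatioRegime:
    omega_bg: float
    omega_fg: float


@dataclass(frozen=True)
class BustedRegime:
    """Three-class site mixture; the foreground class is drawn
    independently of the background class per site, with its own
    omega3."""

    omegas: tuple[float, float, float]
    weights: tuple[float, float, float]
    fg_omega3: float


@dataclass(frozen=True)
class RelaxRegime:
    """Background three-class mixture; foreground omega = background
    omega ** k, same class per site on both partitions."""

    omegas: tuple[float, float, float]
    weights: tuple[float, float, float]
    k: float


Regime = OneRatioRegime | TwoRatioRegime | BustedRegime | RelaxRegime


@dataclass
class SimulationConfig:
    tree: PhyloTree
    n_codons: int
    regime: Regime
    kappa: float = 2.0
    pi_source: Literal["uniform", "dirichlet"] = "uniform"
    seed: int | None = None

    def __post_init__(self):
        if self.n_codons < 33:
            raise ValueError("n_codons must be >= 33 (99 nt minimum)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _draw_pi(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.pi_source == "uniform":
        return uniform_frequencies()
    pi = rng.dirichlet(np.full(N_CODONS, 5.0))
    return pi / pi.sum()


def _evolve(states: np.ndarray, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw child states given parent states under row-stochastic p."""
    cum = np.cumsum(p[states], axis=1)
    u = rng.random(states.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def simulate_codon_alignment(
    config: SimulationConfig,
) -> tuple[CodonAlignment, CodonModelParams]:
    """Evolve codon states down the tree under the configured regime.

    The root codon of each site is drawn from pi; each branch applies the
    matrix exponential of its class rate matrix (scaled so lengths are
    expected substitutions per codon at the background omega).  Returns
    the leaf alignment and the generating parameters.
    """
    rng = np.random.default_rng(config.seed)
    pi = _draw_pi(config, rng)
    regime = config.regime
    n = config.n_codons

    if isinstance(regime, OneRatioRegime):
        bg_omegas, weights = (regime.omega,), (1.0,)
        fg_omegas = bg_omegas
        independent_fg = False
        ref_omega = regime.omega
    elif isinstance(regime, TwoRatioRegime):
        bg_omegas, weights = (regime.omega_bg,), (1.0,)
        fg_omegas = (regime.omega_fg,)
        independent_fg = False
        ref_omega = regime.omega_bg
    elif isinstance(regime, BustedRegime):
        bg_omegas, weights = regime.omegas, regime.weights
        fg_omegas = (regime.omegas[0], regime.omegas[1], regime.fg_omega3)
        independent_fg = True
        ref_omega = float(np.dot(regime.weights, regime.omegas))
    elif isinstance(regime, RelaxRegime):
        bg_omegas, weights = regime.omegas, regime.weights
        fg_omegas = tuple(float(np.power(w, regime.k)) for w in regime.omegas)
        independent_fg = False
        ref_omega = float(np.dot(regime.weights, regime.omegas))
    else:
        raise TypeError(f"unknown regime {regime!r}")

    scale = expected_rate(config.kappa, pi, ref_omega)
    spec_bg = [_Spectral(build_rate_matrix(config.kappa, pi, w, scale=scale), pi)
               for w in bg_omegas]
    spec_fg = [_Spectral(build_rate_matrix(config.kappa, pi, w, scale=scale), pi)
               for w in fg_omegas]

    classes_bg = rng.choice(len(bg_omegas), size=n, p=np.asarray(weights))
    classes_fg = (
        rng.choice(len(fg_omegas), size=n, p=np.asarray(weights))
        if independent_fg
        else classes_bg
    )

    root_states = rng.choice(N_CODONS, size=n, p=pi)
    node_states: dict[int, np.ndarray] = {config.tree.root: root_states}
    leaf_seqs: dict[str, str] = {}
    order = [nd for nd in reversed(list(config.tree.postorder()))]
    for node in order:
        if node.parent is None:
            continue
        parent = node_states[node.parent]
        specs = spec_fg if node.foreground else spec_bg
        classes = classes_fg if node.foreground else classes_bg
        child = np.empty(n, dtype=np.int64)
        for c, spec in enumerate(specs):
            mask = classes == c
            if not mask.any():
                continue
            p = spec.expm(node.length)
            p = p / p.sum(axis=1, keepdims=True)
            child[mask] = _evolve(parent[mask], p, rng)
        node_states[node.index] = child
        if node.is_leaf:
            leaf_seqs[node.name] = "".join(CODONS[s] for s in child)

    taxa = config.tree.leaf_names()
    aln = CodonAlignment(taxa, [leaf_seqs[t] for t in taxa])

    if isinstance(regime, (OneRatioRegime, TwoRatioRegime)):
        fg = regime.omega if isinstance(regime, OneRatioRegime) else regime.omega_fg
        truth = CodonModelParams(
            kappa=config.kappa, codon_frequencies=pi,
            omega_by_class={"background": ref_omega, "foreground": fg},
        )
    else:
        mix = MixtureParams(
            tuple(sorted(bg_omegas)), tuple(weights),
            foreground_omega3=(regime.fg_omega3 if isinstance(regime, BustedRegime) else None),
        )
        truth = CodonModelParams(
            kappa=config.kappa, codon_frequencies=pi, mixture=mix,
            k=(regime.k if isinstance(regime, RelaxRegime) else None),
        )
    return aln, truth


# ---------------------------------------------------------------------------
# OR reference proteins and planted genomes
# ---------------------------------------------------------------------------

_KD_HYDROPHOBIC = "LIVF"
_LOOP_RESIDUES = "STNQDEKRGPHY"
_AA_CODONS: dict[str, list[str]] = {}
for _i, _c in enumerate(CODONS):
    _AA_CODONS.setdefault(AMINO_ACIDS[_i], []).append(_c)


def _random_protein_7tm(rng: np.random.Generator, n_tm: int = 7,
                        tm_len: int = 25, loop_len: int = 16) -> str:
    """A 7-transmembrane-like protein: strongly hydrophobic blocks
    separated by hydrophilic loops, Kyte–Doolittle-detectable."""
    parts = ["M", "".join(rng.choice(list(_LOOP_RESIDUES), size=loop_len - 1))]
    for i in range(n_tm):
        parts.append("".join(rng.choice(list(_KD_HYDROPHOBIC), size=tm_len)))
        tail = loop_len if i < n_tm - 1 else 10
        parts.append("".join(rng.choice(list(_LOOP_RESIDUES), size=tail)))
    return "".join(parts)


def make_or_reference_proteins(
    n_per_family: int = 2,
    families: Sequence[str] = ("OR14", "OR5", "OR2", "OR6"),
    seed: int = 0,
) -> SequenceSet:
    """Synthetic olfactory-receptor-like reference proteins.

    Labels follow ``<family>_<letter>``; the prefix before the underscore
    is the subfamily label used by subfamily assignment.  These are
    synthetic stand-ins for a curated OR reference set, not biological
    sequences.
    """
    rng = np.random.default_rng(seed)
    records = []
    for fam in families:
        for j in range(n_per_family):
            records.append((f"{fam}_{chr(97 + j)}", _random_protein_7tm(rng)))
    return SequenceSet(records)


def make_outgroup_gpcrs(n: int = 6, seed: int = 1) -> SequenceSet:
    """Synthetic non-OR GPCR outgroup sequences (Frizzled-like role):
    same broad 7TM architecture but independent sequence, so they
    cluster apart from any OR-derived candidate."""
    rng = np.random.default_rng(seed)
    return SequenceSet(
        [(f"FZD_{i + 1}", _random_protein_7tm(rng, tm_len=23, loop_len=18))
         for i in range(n)]
    )


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform seeded choice among synonymous codons (no usage bias)."""
    return "".join(rng.choice(_AA_CODONS[aa]) for aa in protein)


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    seq_id: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str
    category: str  # intact | partial | pseudo
    defects: tuple[str, ...]
    reference_id: str
    protein: str


@dataclass
class SyntheticTruth:
    genes: list[PlantedGene]

    def by_category(self) -> dict[str, list[PlantedGene]]:
        out: dict[str, list[PlantedGene]] = {}
        for g in self.genes:
            out.setdefault(g.category, []).append(g)
        return out


@dataclass
class PlantConfig:
    reference_proteins: SequenceSet
    n_intact: int = 10
    n_partial: int = 10
    n_pseudo: int = 10
    genome_length: int = 90_000
    gc: float = 0.42
    flank: int = 750
    seed: int | None = None
    partial_defects: tuple[tuple[str, ...], ...] = (("no_start",), ("no_stop",),
                                                    ("no_start", "no_stop"))
    pseudo_defects: tuple[tuple[str, ...], ...] = (("frameshift",), ("premature_stop",),
                                                   ("frameshift", "premature_stop"))

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")


_STOPS = sorted(STOP_CODONS)


def _apply_defects(cds: str, defects: tuple[str, ...],
                   rng: np.random.Generator) -> str:
    """Edit a clean ATG..stop coding sequence to carry the given lesions."""
    seq = list(cds)
    n = len(seq)
    for defect in defects:
        if defect == "no_start":
            seq[0:3] = list("CTG")
        elif defect == "no_stop":
            seq[-3:] = list("TAC")
        elif defect == "premature_stop":
            # replace a mid-gene codon, keeping clear of both ends
            codon_idx = int(rng.integers(n // 9, 2 * n // 9))
            pos = min(max(3, 3 * codon_idx), n - 6)
            pos -= pos % 3
            stop = _STOPS[int(rng.integers(len(_STOPS)))]
            seq[pos : pos + 3] = list(stop)
        elif defect == "frameshift":
            pos = int(rng.integers(n // 3, 2 * n // 3))
            if rng.random() < 0.5:
                del seq[pos]
            else:
                seq.insert(pos, "ACGT"[int(rng.integers(4))])
        else:
            raise ValueError(f"unknown defect {defect!r}")
        n = len(seq)
    return "".join(seq)


def _random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def plant_or_genome(config: PlantConfig) -> tuple[SequenceSet, SyntheticTruth]:
    """Build a genome with OR genes of known category at known loci.

    Intact genes are exact back-translations of reference proteins
    (ATG..stop); partial genes lack the start and/or stop codon; pseudo
    genes carry one or more frameshifts and/or in-frame premature stops.
    Planted loci are separated by at least two flank widths so ORF search
    windows never overlap; strand is drawn per gene.  Intergenic sequence
    is i.i.d. nucleotide noise at the configured GC content.
    """
    rng = np.random.default_rng(config.seed)
    refs = list(config.reference_proteins)
    plan = (
        [("intact", ()) for _ in range(config.n_intact)]
        + [("partial", config.partial_defects[i % len(config.partial_defects)])
           for i in range(config.n_partial)]
        + [("pseudo", config.pseudo_defects[i % len(config.pseudo_defects)])
           for i in range(config.n_pseudo)]
    )
    rng.shuffle(plan)

    genes = []
    for i, (category, defects) in enumerate(plan):
        ref_id, ref_prot = refs[int(rng.integers(len(refs)))]
        cds = back_translate(ref_prot, rng) + _STOPS[int(rng.integers(len(_STOPS)))]
        cds = _apply_defects(cds, defects, rng)
        genes.append((f"gene{i + 1:03d}", category, defects, ref_id, ref_prot, cds))

    spacing = 2 * config.flank
    total_gene = sum(len(g[5]) for g in genes)
    needed = total_gene + (len(genes) + 1) * spacing
    if config.genome_length < needed:
        raise ValueError(
            f"genome_length {config.genome_length} too short; need >= {needed}"
        )
    slack = config.genome_length - needed
    gaps = rng.multinomial(slack, np.full(len(genes) + 1, 1.0 / (len(genes) + 1)))

    chrom = _random_background(config.genome_length, config.gc, rng)
    truth = []
    cursor = 0
    for (gene_id, category, defects, ref_id, ref_prot, cds), gap in zip(genes, gaps):
        cursor += spacing + int(gap)
        strand = "+" if rng.random() < 0.5 else "-"
        insert = cds if strand == "+" else reverse_complement(cds)
        chrom[cursor : cursor + len(insert)] = np.frombuffer(
            insert.encode(), dtype="S1"
        )
        truth.append(
            PlantedGene(
                gene_id=gene_id,
                seq_id="synthetic_chr1",
                start=cursor + 1,
                end=cursor + len(insert),
                strand=strand,
                category=category,
                defects=tuple(defects),
                reference_id=ref_id,
                protein=ref_prot,
            )
        )
        cursor += len(insert)

    genome = SequenceSet([("synthetic_chr1", chrom.tobytes().decode())])
    return genome, SyntheticTruth(truth)


# ---------------------------------------------------------------------------
# toy protein alignments
# ---------------------------------------------------------------------------

def make_toy_alignment(
    n_seqs: int,
    n_cols: int,
    per_column_profiles: Sequence[dict[str, float]] | dict[str, float],
    seed: int = 0,
) -> SequenceSet:
    """Draw alignment columns independently from residue profiles.

    *per_column_profiles* is one profile per column (or a single profile
    reused for every column); each profile maps residues to
    probabilities.
    """
    rng = np.random.default_rng(seed)
    if isinstance(per_column_profiles, dict):
        per_column_profiles = [per_column_profiles] * n_cols
    if len(per_column_profiles) != n_cols:
        raise ValueError("need one profile per column")
    cols = []
    for profile in per_column_profiles:
        residues = list(profile)
        p = np.array([profile[r] for r in residues], dtype=float)
        p = p / p.sum()
        cols.append(rng.choice(residues, size=n_seqs, p=p))
    rows = ["".join(col[i] for col in cols) for i in range(n_seqs)]
    return SequenceSet([(f"seq{i + 1}", row) for i, row in enumerate(rows)])
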