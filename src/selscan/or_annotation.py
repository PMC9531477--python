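"""Olfactory-receptor repertoire mining.

The pipeline mirrors standard OR-gene annotation practice: candidate
loci are located by translated homology of reference OR proteins
against the genome (built-in six-frame seeded scanner, or an external
12-column search table); overlapping hits are reduced to a best hit per
locus; the open reading frame is reconstructed in a +/-750 bp window by
a frameshift-aware protein-to-DNA alignment; candidates are classified
intact / partial / pseudo from start, stop, frameshift and premature
stop evidence plus a length and seven-transmembrane requirement;
intact candidates clustering with non-OR GPCR outgroups on a
neighbor-joining tree are filtered out; and intact genes are assigned
to the subfamily of their most similar reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import HomologyHit, SequenceSet

__all__ = [
    "ORGeneCall",
    "OrfReport",
    "RepertoireReport",
    "scan_genome",
    "best_hit_per_locus",
    "reconstruct_orf",
    "predict_tm",
    "classify_or",
    "nj_filter",
    "assign_subfamily",
    "report_repertoire",
    "annotate_genome",
    "match_truth",
]

BLOSUM62 = substitution_matrices.load("BLOSUM62")
STOP_CODONS = {"TAA", "TAG", "TGA"}

# gapped Karlin–Altschul constants for BLOSUM62 (approximate E-values;
# the external-table route is the bit-compatible alternative)
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class ORGeneCall:
    seq_id: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str
    category: str  # intact | partial | pseudo
    defects: tuple[str, ...]
    protein: str
    subfamily: str | None
    best_hit_ref: str
    best_hit_evalue: float


@dataclass
class OrfReport:
    seq_id: str
    start: int  # 1-based inclusive forward-strand coding span
    end: int
    strand: str
    has_start: bool
    has_stop: bool
    frameshifts: tuple[int, ...]  # forward-strand genome positions
    premature_stops: tuple[int, ...]
    protein: str
    cds_length: int  # nucleotides, including the stop codon when present
    reference_id: str
    score: float


@dataclass
class RepertoireReport:
    n_intact: int
    n_partial: int
    n_pseudo: int
    pct_intact: float
    pct_partial: float
    pct_pseudo: float
    subfamily_intact_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.n_intact + self.n_partial + self.n_pseudo


# ---------------------------------------------------------------------------
# homology scanning
# ---------------------------------------------------------------------------

def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _bitscore(raw: float) -> float:
    return (_KA_LAMBDA * raw - np.log(_KA_K)) / np.log(2.0)


def _evalue(raw: float, m: int, n: int) -> float:
    return float(m * n * 2.0 ** (-_bitscore(raw)))


def _six_frames(seq: str):
    """Yield (strand, frame, translation) over all six reading frames."""
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            yield strand, frame, str(Seq(sub).translate())


def _seed_clusters(ref: str, frame_aa: str, word: int = 5,
                   band: int = 12, max_gap: int = 120):
    """Diagonal-banded clusters of exact word matches ref->frame."""
    index: dict[str, list[int]] = {}
    for i in range(len(ref) - word + 1):
        index.setdefault(ref[i : i + word], []).append(i)
    seeds = []  # (diag, tpos)
    for t in range(len(frame_aa) - word + 1):
        for q in index.get(frame_aa[t : t + word], ()):
            seeds.append((t - q, t))
    seeds.sort()
    clusters = []
    for diag, t in seeds:
        placed = False
        for cl in clusters:
            if abs(diag - cl["diag"]) <= band and abs(t - cl["tmax"]) <= max_gap:
                cl["tmin"] = min(cl["tmin"], t)
                cl["tmax"] = max(cl["tmax"], t)
                placed = True
                break
        if not placed:
            clusters.append({"diag": diag, "tmin": t, "tmax": t})
    return clusters


def scan_genome(
    genome: SequenceSet,
    reference_or_proteins: SequenceSet,
    evalue_cutoff: float = 10.0,
) -> list[HomologyHit]:
    """Translated homology search of reference OR proteins against a
    nucleotide genome: six-frame translation, exact-word seeding on
    diagonals, then local BLOSUM62 alignment around each seed cluster.
    Hits with E-value above the cutoff are dropped.  Coordinates are
    1-based inclusive on the forward strand.
    """
    if len(reference_or_proteins) == 0:
        raise ValueError("empty reference protein set")
    aligner = _local_aligner()
    search_space = sum(2 * len(s) // 3 for _, s in genome)
    hits: list[HomologyHit] = []
    for seq_id, seq in genome:
        L = len(seq)
        for strand, frame, frame_aa in _six_frames(seq):
            for ref_id, ref in reference_or_proteins:
                pad = 60
                for cl in _seed_clusters(ref, frame_aa):
                    lo = max(0, cl["tmin"] - pad)
                    hi = min(len(frame_aa), cl["tmax"] + len(ref) + pad)
                    window = frame_aa[lo:hi]
                    if not window:
                        continue
                    alns = aligner.align(ref, window)
                    if len(alns) == 0:
                        continue
                    best = alns[0]
                    raw = best.score
                    ev = _evalue(raw, len(ref), search_space)
                    if ev > evalue_cutoff:
                        continue
                    (qblocks, tblocks) = best.aligned
                    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
                    t0, t1 = int(tblocks[0][0]) + lo, int(tblocks[-1][1]) + lo
                    matches = sum(
                        1
                        for (qa, qb), (ta, tb) in zip(qblocks, tblocks)
                        for dq in range(qb - qa)
                        if ref[qa + dq] == window[ta + dq]
                    )
                    ncols = sum(qb - qa for qa, qb in qblocks)
                    # frame-local aa coords -> forward-strand nt coords
                    nt_start = frame + 3 * t0
                    nt_end = frame + 3 * t1  # exclusive
                    if strand == "+":
                        fstart, fend = nt_start, nt_end
                    else:
                        fstart, fend = L - nt_end, L - nt_start
                    hits.append(
                        HomologyHit(
                            query_id=ref_id,
                            subject_id=seq_id,
                            percent_identity=100.0 * matches / max(ncols, 1),
                            alignment_length=ncols,
                            query_start=q0 + 1,
                            query_end=q1,
                            subject_start=fstart + 1,
                            subject_end=fend,
                            evalue=ev,
                            bitscore=float(_bitscore(raw)),
                            subject_strand=strand,
                        )
                    )
    return hits


def best_hit_per_locus(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Merge overlapping same-strand hits to the single best one
    (smallest E-value, then larger bitscore, then leftmost start)."""
    groups: list[list[HomologyHit]] = []
    for hit in sorted(hits, key=lambda h: (h.subject_id, h.subject_strand,
                                           h.subject_start, h.subject_end)):
        placed = False
        for grp in groups:
            last = grp[-1]
            if (hit.subject_id == last.subject_id
                    and hit.subject_strand == last.subject_strand
                    and hit.subject_start <= max(g.subject_end for g in grp)):
                grp.append(hit)
                placed = True
                break
        if not placed:
            groups.append([hit])
    winners = [
        min(grp, key=lambda h: (h.evalue, -h.bitscore, h.subject_start))
        for grp in groups
    ]
    return sorted(winners, key=lambda h: (h.subject_id, h.subject_start))


# ---------------------------------------------------------------------------
# frameshift-aware ORF reconstruction
# ---------------------------------------------------------------------------

_NEG_INF = -1e12


def _dp_align(dna: str, protein: str, fs_penalty: float = 15.0,
              gap_codon: float = 12.0, gap_aa: float = 12.0):
    """Glocal DP: protein global, DNA local; codon steps of 1,2,3,4,5 nt.

    Returns (score, events) where events are (dna_start, dna_end, kind,
    prot_index) tuples in DNA order; kind in {codon, frameshift, del}.
    """
    n, m = len(dna), len(protein)
    aas = "ARNDCQEGHILKMFPSTWYVBZX*"
    aa_idx = {a: i for i, a in enumerate(aas)}
    sub = np.array([[BLOSUM62[a][b] for b in aas] for a in aas])
    # codon translations for every position: codon starting at i uses dna[i:i+3]
    codon_aa = np.full(n, aa_idx["X"], dtype=np.int64)
    table = {}
    for i in range(n - 2):
        codon = dna[i : i + 3]
        if codon not in table:
            if set(codon) <= set("ACGT"):
                aa = "*" if codon in STOP_CODONS else str(Seq(codon).translate())
            else:
                aa = "X"
            table[codon] = aa_idx.get(aa, aa_idx["X"])
        codon_aa[i] = table[codon]

    prot_idx = np.array([aa_idx.get(a, aa_idx["X"]) for a in protein])

    M = np.full((m + 1, n + 1), _NEG_INF, dtype=np.float64)
    M[0, :] = 0.0  # local in DNA: free start
    steps = (3, 1, 2, 4, 5)
    for j in range(1, m + 1):
        col = np.full(n + 1, _NEG_INF)
        # protein residue consumed against codon-ish DNA chunk
        for step in steps:
            prev = M[j - 1, : n + 1 - step]
            if step == 3:
                sc = sub[prot_idx[j - 1], codon_aa[: n + 1 - step]]
            else:
                sc = -fs_penalty
            cand = prev + sc
            col[step:] = np.maximum(col[step:], cand)
        # protein residue unmatched (deletion in DNA)
        col = np.maximum(col, M[j - 1, :] - gap_aa)
        # extra DNA codon (insertion): running chain col[i] >= col[i-3]-gap
        for r in range(3):
            sl = col[r::3]
            adj = sl + gap_codon * np.arange(sl.size)
            np.maximum.accumulate(adj, out=adj)
            np.maximum(sl, adj - gap_codon * np.arange(sl.size), out=sl)
            col[r::3] = sl
        M[j, :] = col

    end_i = int(np.argmax(M[m, :]))
    score = float(M[m, end_i])

    # traceback by recomputation
    events = []
    i, j = end_i, m
    while j > 0:
        moved = False
        cur = M[j, i]
        # codon-ish consumption
        for step in steps:
            if i - step < 0:
                continue
            sc = sub[prot_idx[j - 1], codon_aa[i - step]] if step == 3 else -fs_penalty
            if abs(M[j - 1, i - step] + sc - cur) < 1e-6:
                kind = "codon" if step == 3 else "frameshift"
                events.append((i - step, i, kind, j - 1))
                i, j = i - step, j - 1
                moved = True
                break
        if moved:
            continue
        if abs(M[j - 1, i] - gap_aa - cur) < 1e-6:
            events.append((i, i, "del", j - 1))
            j -= 1
            continue
        if i - 3 >= 0 and abs(M[j, i - 3] - gap_codon - cur) < 1e-6:
            events.append((i - 3, i, "ins", -1))
            i -= 3
            continue
        # numerical fallback: step back through the best predecessor
        j -= 1
        moved = True
    events.reverse()
    return score, events


def reconstruct_orf(
    genome: SequenceSet,
    hit: HomologyHit,
    reference_protein: str,
    flank: int = 750,
    reference_id: str | None = None,
) -> OrfReport:
    """Reconstruct the reading frame around a homology hit.

    The reference protein is aligned to the hit's +/-*flank* bp window
    with a frameshift-aware dynamic program; the report records coding
    coordinates, presence of an ATG start and canonical stop, frameshift
    and internal-stop positions, and the conceptual translation (internal
    stops rendered as X).
    """
    seq = genome.get(hit.subject_id)
    L = len(seq)
    w_start = max(0, hit.subject_start - 1 - flank)
    w_end = min(L, hit.subject_end + flank)
    if w_end - w_start < 90:
        raise ValueError("ORF window shorter than 90 nt")
    window = seq[w_start:w_end]
    if hit.subject_strand == "-":
        window = str(Seq(window).reverse_complement())

    score, events = _dp_align(window, reference_protein)
    consuming = [e for e in events if e[1] > e[0]]
    if not consuming:
        raise ValueError("alignment consumed no DNA")
    d_start, d_end = consuming[0][0], consuming[-1][1]

    frameshifts_local = []
    stops_local = []
    protein_chars = []
    for a, b, kind, j in events:
        if kind == "codon":
            codon = window[a:b]
            if codon in STOP_CODONS:
                stops_local.append(a)
                protein_chars.append("X")
            else:
                protein_chars.append(str(Seq(codon).translate()) if set(codon) <= set("ACGT") else "X")
        elif kind == "frameshift":
            frameshifts_local.append(a)
            protein_chars.append("x")
        elif kind == "del":
            pass
        # "ins" contributes no protein residue

    first = consuming[0]
    has_start = first[2] == "codon" and window[first[0]:first[1]] == "ATG"
    following = window[d_end : d_end + 3]
    has_stop = following in STOP_CODONS
    # a stop aligned as the final codon also terminates the frame
    internal_stops = list(stops_local)
    if internal_stops and consuming[-1][2] == "codon" and internal_stops[-1] == consuming[-1][0]:
        has_stop = True
        internal_stops = internal_stops[:-1]
        protein_chars = protein_chars[:-1]

    cds_length = (d_end - d_start) + (3 if has_stop else 0)

    def to_forward(pos_local: int) -> int:
        if hit.subject_strand == "+":
            return w_start + pos_local + 1
        return w_start + (len(window) - pos_local)

    if hit.subject_strand == "+":
        g_start, g_end = w_start + d_start + 1, w_start + d_end
    else:
        g_start, g_end = w_start + (len(window) - d_end) + 1, w_start + (len(window) - d_start)

    return OrfReport(
        seq_id=hit.subject_id,
        start=g_start,
        end=g_end,
        strand=hit.subject_strand,
        has_start=has_start,
        has_stop=has_stop,
        frameshifts=tuple(sorted(to_forward(p) for p in frameshifts_local)),
        premature_stops=tuple(sorted(to_forward(p) for p in internal_stops)),
        protein="".join(c for c in protein_chars if c != "x"),
        cds_length=cds_length,
        reference_id=reference_id or hit.query_id,
        score=score,
    )


# ---------------------------------------------------------------------------
# transmembrane prediction and classification
# ---------------------------------------------------------------------------

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def predict_tm(protein: str, window: int = 19, cutoff: float = 1.6,
               min_run: int = 15) -> list[tuple[int, int]]:
    """Kyte–Doolittle hydropathy segments.

    A transmembrane span is a run of at least *min_run* consecutive
    window centers whose mean hydropathy is >= *cutoff*; overlapping
    spans are merged.  Returns 0-based inclusive (start, end) residue
    coordinates.
    """
    values = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in protein.upper()])
    if values.size < window:
        return []
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    half = window // 2
    qualifying = means >= cutoff
    spans = []
    run_start = None
    for c, ok in enumerate(list(qualifying) + [False]):
        if ok and run_start is None:
            run_start = c
        elif not ok and run_start is not None:
            if c - run_start >= min_run:
                # report the run of qualifying window centers
                spans.append((run_start + half, c - 1 + half))
            run_start = None
    merged: list[tuple[int, int]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def classify_or(orf: OrfReport, tm_spans: list[tuple[int, int]],
                min_len: int = 650) -> ORGeneCall:
    """Bin a reconstructed candidate into intact / partial / pseudo.

    Frameshifts or premature stops take precedence (pseudo); otherwise a
    missing start and/or stop makes the gene partial; otherwise intact
    requires a coding length strictly greater than *min_len* nucleotides
    and exactly seven transmembrane spans, failing which the gene is
    partial with a short / tm_deficient defect.
    """
    defects: list[str] = []
    if orf.frameshifts:
        defects.append("frameshift")
    if orf.premature_stops:
        defects.append("premature_stop")
    if defects:
        category = "pseudo"
        if not orf.has_start:
            defects.append("no_start")
        if not orf.has_stop:
            defects.append("no_stop")
    else:
        if not orf.has_start:
            defects.append("no_start")
        if not orf.has_stop:
            defects.append("no_stop")
        if defects:
            category = "partial"
        elif orf.cds_length > min_len and len(tm_spans) == 7:
            category = "intact"
        else:
            category = "partial"
            if orf.cds_length <= min_len:
                defects.append("short")
            if len(tm_spans) != 7:
                defects.append("tm_deficient")
    return ORGeneCall(
        seq_id=orf.seq_id,
        start=orf.start,
        end=orf.end,
        strand=orf.strand,
        category=category,
        defects=tuple(defects),
        protein="" if category == "pseudo" else orf.protein,
        subfamily=None,
        best_hit_ref=orf.reference_id,
        best_hit_evalue=float("nan"),
    )


# ---------------------------------------------------------------------------
# NJ filtering and subfamily assignment
# ---------------------------------------------------------------------------

def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _pair_identity(aligner, a: str, b: str) -> tuple[float, int]:
    best = aligner.align(a, b)[0]
    qb, tb = best.aligned
    matches = sum(
        1
        for (qa, qe), (ta, te) in zip(qb, tb)
        for d in range(qe - qa)
        if a[qa + d] == b[ta + d]
    )
    ncols = max(len(a), len(b))
    return matches / ncols, ncols


def p_distance_matrix(seqs: list[tuple[str, str]]) -> np.ndarray:
    """Pairwise p-distances (1 - identity over a global alignment)."""
    aligner = _global_aligner()
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = _pair_identity(aligner, seqs[i][1], seqs[j][1])
            d[i, j] = d[j, i] = 1.0 - ident
    return d


def nj_tree(names: list[str], distances: np.ndarray):
    """Neighbor-joining tree (scikit-bio) from a distance matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(distances, ids=names)
    return nj(dm)


def nj_filter(
    candidate_proteins: SequenceSet,
    outgroup_gpcrs: SequenceSet,
    reference_or_proteins: SequenceSet | None = None,
) -> tuple[list[str], list[str]]:
    """Drop candidates that cluster with non-OR GPCR outgroups.

    Builds a neighbor-joining tree of candidates + outgroups (+ known OR
    references when provided, which anchor the OR side of the tree).
    Rooted away from the outgroups, every maximal clade that contains
    outgroup sequences but no reference OR is treated as the non-OR
    cluster; candidates inside it are removed.  Returns (kept_ids,
    removed_ids).
    """
    cands = list(candidate_proteins)
    outs = list(outgroup_gpcrs)
    refs = list(reference_or_proteins) if reference_or_proteins else []
    if not outs:
        raise ValueError("need at least one outgroup GPCR")
    if len(cands) + len(outs) + len(refs) < 4:
        raise ValueError("need at least four sequences for a neighbor-joining tree")
    seqs = cands + outs + refs
    names = [s[0] for s in seqs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names across candidate/outgroup/reference sets")
    cand_ids = {s[0] for s in cands}
    out_ids = {s[0] for s in outs}
    ref_ids = {s[0] for s in refs}

    tree = nj_tree(names, p_distance_matrix(seqs))
    removed: set[str] = set()
    if ref_ids:
        # root away from the outgroups; every maximal reference-free clade
        # around an outgroup is the non-OR side
        anchor = sorted(ref_ids)[0]
        tree = tree.root_at(tree.find(anchor).parent)
        for out_id in out_ids:
            cur = tree.find(out_id)
            while cur.parent is not None and not (
                {t.name for t in cur.parent.tips()} & ref_ids
            ):
                cur = cur.parent
            removed |= {t.name for t in cur.tips()} & cand_ids
    else:
        # no reference anchor: a candidate clusters with the outgroups when
        # its nearest tip by patristic distance is an outgroup
        for cand_id in cand_ids:
            node = tree.find(cand_id)
            dists = {
                t.name: node.distance(t) for t in tree.tips() if t.name != cand_id
            }
            nearest = min(dists, key=dists.get)
            if nearest in out_ids:
                removed.add(cand_id)
    kept = [c for c, _ in cands if c not in removed]
    if not kept and cands:
        warnings.warn("all candidates removed by the non-OR GPCR filter", stacklevel=2)
    return kept, sorted(removed)


def assign_subfamily(
    protein: str,
    reference_or_proteins: SequenceSet,
    min_identity: float = 0.30,
) -> str | None:
    """Subfamily of the highest-identity reference (global alignment).

    Reference identifiers carry the subfamily as the prefix before the
    first underscore.  Identity below *min_identity* returns None; ties
    break alphabetically by subfamily label.
    """
    aligner = _global_aligner()
    best: tuple[float, str] | None = None
    for ref_id, ref_seq in reference_or_proteins:
        ident, _ = _pair_identity(aligner, protein, ref_seq)
        fam = ref_id.split("_")[0]
        key = (round(ident, 9), fam)
        if best is None or key[0] > best[0] or (key[0] == best[0] and fam < best[1]):
            best = key
    if best is None or best[0] < min_identity:
        return None
    return best[1]


def report_repertoire(calls: list[ORGeneCall]) -> RepertoireReport:
    """Totals, one-decimal percentages and per-subfamily intact counts."""
    n_intact = sum(1 for c in calls if c.category == "intact")
    n_partial = sum(1 for c in calls if c.category == "partial")
    n_pseudo = sum(1 for c in calls if c.category == "pseudo")
    total = n_intact + n_partial + n_pseudo
    pct = lambda n: round(100.0 * n / total, 1) if total else 0.0  # noqa: E731
    fams: dict[str, int] = {}
    for c in calls:
        if c.category == "intact" and c.subfamily:
            fams[c.subfamily] = fams.get(c.subfamily, 0) + 1
    return RepertoireReport(n_intact, n_partial, n_pseudo,
                            pct(n_intact), pct(n_partial), pct(n_pseudo),
                            dict(sorted(fams.items())))


# ---------------------------------------------------------------------------
# pipeline driver and evaluation
# ---------------------------------------------------------------------------

def annotate_genome(
    genome: SequenceSet,
    reference_or_proteins: SequenceSet,
    hits: list[HomologyHit] | None = None,
    outgroup_gpcrs: SequenceSet | None = None,
    evalue_cutoff: float = 10.0,
    flank: int = 750,
    min_len: int = 650,
) -> list[ORGeneCall]:
    """Run the full OR mining pipeline on a genome.

    *hits* substitutes an externally produced 12-column search table for
    the built-in scanner.  When *outgroup_gpcrs* is given, intact
    candidates clustering with them on the NJ tree are discarded.
    """
    if hits is None:
        hits = scan_genome(genome, reference_or_proteins, evalue_cutoff)
    winners = best_hit_per_locus(hits)
    calls: list[ORGeneCall] = []
    for hit in winners:
        try:
            ref_seq = reference_or_proteins.get(hit.query_id)
            orf = reconstruct_orf(genome, hit, ref_seq, flank=flank)
        except (ValueError, KeyError):
            continue
        tm = predict_tm(orf.protein) if orf.protein else []
        call = classify_or(orf, tm, min_len=min_len)
        call = ORGeneCall(**{**call.__dict__, "best_hit_evalue": hit.evalue})
        calls.append(call)

    if outgroup_gpcrs is not None:
        intact_idx = [i for i, c in enumerate(calls) if c.category == "intact"]
        if intact_idx:
            cand_set = SequenceSet([(f"cand{i}", calls[i].protein) for i in intact_idx])
            kept, _removed = nj_filter(cand_set, outgroup_gpcrs, reference_or_proteins)
            kept_idx = {int(name[4:]) for name in kept}
            calls = [c for i, c in enumerate(calls)
                     if c.category != "intact" or i in kept_idx]

    out: list[ORGeneCall] = []
    for c in calls:
        if c.category == "intact":
            fam = assign_subfamily(c.protein, reference_or_proteins)
            c = ORGeneCall(**{**c.__dict__, "subfamily": fam})
        out.append(c)
    return out


def match_truth(calls: list[ORGeneCall], truth) -> dict:
    """Score pipeline calls against planted ground truth.

    A planted gene is detected when a call overlaps its locus on the
    same sequence; the category is correct when the overlapping call's
    bin matches the planted bin.  Returns detection and category-accuracy
    fractions plus the confusion table.
    """
    confusion: dict[tuple[str, str], int] = {}
    detected = 0
    correct = 0
    for gene in truth.genes:
        overlapping = [
            c for c in calls
            if c.seq_id == gene.seq_id and c.start <= gene.end and c.end >= gene.start
        ]
        if not overlapping:
            confusion[(gene.category, "missed")] = confusion.get(
                (gene.category, "missed"), 0) + 1
            continue
        detected += 1
        best = max(overlapping,
                   key=lambda c: min(c.end, gene.end) - max(c.start, gene.start))
        confusion[(gene.category, best.category)] = confusion.get(
            (gene.category, best.category), 0) + 1
        if best.category == gene.category:
            correct += 1
    n = len(truth.genes)
    return {
        "n_planted": n,
        "detected": detected,
        "detection_rate": detected / n if n else 0.0,
        "category_accuracy": correct / n if n else 0.0,
        "confusion": confusion,
    }
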