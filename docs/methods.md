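# Methods

## Selection rubric

Each gene carries nine statistics from three tests run against a
foreground branch: the branch-model background and foreground dN/dS
ratios (ω₀, ω₁) with LRT p and BH-FDR q; the episodic-test p and q; and
the selection-intensity parameter k with p and q. Classification rules:

- branch model: `ns` if q > α; else `positive` if ω₁ > 1; else
  `relaxed` if ω₁ > ω₀, `intensified` if ω₁ < ω₀. ω₁ = ω₀ exactly with
  a significant q cannot arise under the two-ratio alternative; it is
  classified `ns` with a warning.
- episodic test: `positive` iff q ≤ α (and, when reported, the
  foreground ω₃ exceeds the background's).
- intensity test: `ns` if q > α or k = 1 exactly; else `intensified`
  (k > 1) or `relaxed` (k < 1). The k = 1 tie-break only matters for
  non-significant rows in the packaged data and is documented rather
  than load-bearing.

Significance is **inclusive** (q ≤ α): one fixture row (HDAC1) prints
its q exactly at 0.05 and is marked significant in the source table.

Combination: a positive signature (either test) with RELAX
intensification → `positive_corroborated`; positive with RELAX
relaxation → `relaxed` (relaxation inflates apparent positive
signatures); positive alone → `positive_uncorroborated`. Without a
positive signature, either method's relaxed/intensified verdict
carries; a relaxed-vs-intensified disagreement between the branch model
and RELAX yields `ns` with a conflict flag. Species summaries bin
non-positive genes into relaxed/intensified buckets; positive genes are
reported with their corroboration status. Cross-species comparison is
restricted to genes present in both tables and to genes with a non-`ns`
combined label in both.

Classification consumes the tables' printed q-values and does not
recompute them: the original FDR family was the full 216-gene vision
set while the tables print only a subset, so re-running BH on the
printed rows would change the q-values. `bh_fdr` (step-up with
monotonicity enforcement) is provided for new analyses.

Known discrepancy in the source tables: the *C. cochlearius* prose
claims "13 additional genes" under relaxed selection including CCDC66
and PDE6B, but the table shows CCDC66 as non-significant under RELAX
and has no PDE6B row; counts derived from the table give 12. The
package follows the table.

Gene symbols are matched case-sensitively after whitespace trimming.

## Codon engine

Model: GY94 with HKY nucleotide exchange — rate(i→j) = π_j ·
κ^[transition] · ω^[nonsynonymous] for codon pairs differing at one
nucleotide, zero otherwise — over the 61 sense codons of the standard
nuclear code. Codon frequencies default to F3x4 estimated from the
alignment (position-specific nucleotide frequencies, floored at 1e-6
and renormalized). The chain is reversible, so transition probabilities
come from a symmetric eigendecomposition; eigenvalues are clipped at
zero to keep extreme-ω matrices from overflowing. Matrices are scaled
so branch lengths are expected substitutions per codon at the
background ω (for mixtures: at the weight-averaged background ω, which
equals the weighted average of class rates because the expected rate is
linear in ω).

Likelihood: Felsenstein pruning over unique site patterns with
per-site rescaling; gap/ambiguous codons are missing data. Stop codons
anywhere in an alignment are rejected with their position. Alignments
shorter than 99 nt after dropping all-gap codon columns are rejected
(the study's minimum-length filter, boundary inclusive: 99 nt passes).

Fits optimize κ, the model's ω parameters and a **single global
branch-length scale** (not per-branch lengths — the deliberate
desk-scale simplification) by L-BFGS-B on transformed coordinates:
logs for κ/ω/scale/k, logits for the ω₁ ≤ ω₂ ≤ 1 constraint and the
simplex weights, 1 + exp(·) for ω₃ ≥ 1. Convergence tolerance 1e-8 on
the objective; restarts jitter the start deterministically under the
seed (3 by default; the large simulation studies use 1, which the
calibration results support). Alternative models additionally start
from the null optimum, which guarantees the nesting inequality up to
tolerance; an alternative lnL below the null by more than 1e-4 is an
optimizer-failure error, smaller deficits are clamped to a zero LRT
statistic.

- **Branch model**: one ω vs background/foreground ω pair; χ²₁ LRT.
- **Episodic model**: three classes ω₁ ≤ ω₂ ≤ 1 ≤ ω₃ with shared
  weights; foreground and background classes are drawn independently
  per site (a 3×3 product mixture) and the foreground has its own ω₃;
  the null pins foreground ω₃ = 1. The p-value uses the conservative
  ½χ²₀ + ½χ²₁ boundary mixture. Synonymous rate variation is not
  modelled.
- **Intensity model**: background three-class distribution; foreground
  ω = background ω^k with one k ∈ [0, 50] (null k = 1), same class on
  both partitions; χ²₁ LRT. General branch partitions beyond one
  foreground set are out of scope.

SLAC-style site test: marginal (up-down) ancestral reconstruction
under the fitted one-ratio model, MAP codon per internal node;
synonymous/nonsynonymous changes counted per site along branches,
averaging over equally weighted minimal pathways (pathways through
stops excluded; if all pathways hit a stop the changes count as
nonsynonymous); expected nonsynonymous proportion from Nei–Gojobori
site counts of the codons at the site; two-sided binomial test. The
test is deliberately conservative at low divergence — with few changes
per site the binomial cannot reach small p-values.

## OR repertoire mining

Scanning: six-frame translation; exact 5-mer seeds grouped on diagonals
(band 12, gap 120); local BLOSUM62 alignment (open −11, extend −1)
around each cluster; bit scores and E-values from gapped Karlin–
Altschul constants (λ = 0.267, K = 0.041) with the translated-genome
search space. These E-values are approximate; externally produced
12-column tables can be substituted where bit-compatibility with a
standard search tool matters. The default cutoff E ≤ 10 is
deliberately permissive, as in OR mining practice; it admits spurious
low-scoring loci which downstream classification bins as pseudo.
Overlapping same-strand hits reduce to the best (smallest E, then
larger bit score, then leftmost).

ORF reconstruction: the best reference protein is aligned to the hit
±750 bp by a dynamic program whose states consume 3 nt per residue
(BLOSUM62 on the translated codon, stops scored as `*`), 1/2/4/5 nt per
residue (frameshift, penalty 15), or codon/residue gaps (penalty 12);
global in the protein, free start/end in the DNA. The report records
ATG-start and canonical-stop presence, frameshift and internal-stop
positions, and the conceptual translation (internal stops as X).
Coding length includes the stop codon when present.

Classification precedence: frameshift/premature stop → pseudo (the
stronger lesion, following standard OR-mining practice, since the
source rules are not mutually exclusive); else missing start/stop →
partial; else intact requires coding length **strictly** > 650 nt and
exactly seven transmembrane segments; clean genes failing length or
7-TM are binned partial with a `short`/`tm_deficient` defect (the
source assigns every candidate to one of the three bins).

TM prediction: Kyte–Doolittle hydropathy, window 19, reporting runs of
at least 15 consecutive window centers with mean ≥ 1.6 (all three
constants configurable; no specific predictor is canonical for the
7-TM criterion).

NJ filter: p-distances from pairwise global alignments (one minus
identity over the longer sequence), neighbor joining via scikit-bio.
The tree is rooted at a reference OR; every maximal clade containing an
outgroup GPCR but no reference OR counts as the non-OR side, and
candidates inside it are removed. Without reference anchors the rule
degrades to nearest-tip-by-patristic-distance. Pairwise rather than
joint multiple alignment is the package's choice for determinism; with
the highly divergent outgroups involved the p-distance ranking is
insensitive to this.

Subfamily: highest global-alignment identity against the labelled
references (prefix before the first underscore), floor 30%, ties
alphabetical.

## Entropy

H = −Σ f log₂ f per column, gaps excluded before counting, all-gap
columns dropped. Base 2 (bits) makes the 1.0/2.0 thresholds attainable
(max log₂ 20 ≈ 4.32) and matches the residue-variability literature;
the base is configurable. The source's threshold statements overlap at
the boundaries; boundaries go to the more extreme class (H = 2.0 →
variable, H = 1.0 → highly conserved), configurable. The summary sd is
the sample standard deviation (n − 1). The between-species test is a
Wilcoxon signed-rank on per-column differences of profiles sharing a
column coordinate system (zero differences dropped; exact null for
n ≤ 25 without rank ties, else tie-corrected normal approximation).
Column pairing on a joint alignment is the package's reading of the
comparison; per-gene pairing would be an alternative.

## Synthetic data

Codon alignments: root codons drawn from π (uniform over the 61 sense
codons by default, or a seeded Dirichlet), states evolved down each
branch by the matrix exponential of the branch's class matrix. Mixture
regimes draw a class per site; the episodic regime draws the foreground
class independently; the intensity regime applies ω^k to the same
class. Branch lengths are expected substitutions per codon at the
regime's mean background ω, so simulation and fitting use the same time
scale.

Planted genomes: intact genes are exact back-translations of reference
proteins (uniform seeded choice among synonymous codons — no
codon-usage bias) with ATG…stop; partial genes have the start mutated
to CTG and/or the stop to a sense codon; pseudo genes carry seeded
1-nt indels and/or mid-gene in-frame stops. Genes are placed on random
strands, separated by at least two flank widths (1500 bp) so ORF
windows never overlap, in i.i.d. intergenic sequence at GC 0.42 (a
bird-like convenience value, not a claim). The bundled reference set is
**synthetic**: 7-TM-architecture proteins (~300 aa, hydrophobic blocks
separated by hydrophilic loops) labelled with OR subfamily prefixes —
they exercise the pipeline's geometry, not OR biology. What passing
recovery tests show is that the mining machinery is correct on clean
substrates; they do not probe assembly gaps, diverged paralogs, split
genes or repeat-rich intergenic sequence, which real genomes have.

## Problem sizes and defaults

The packaged seven-taxon tree carries desk-scale branch lengths (total
≈ 0.85 expected substitutions per codon). The calibration study uses
300-codon alignments, 200 null replicates (type-I error of the
two-ratio LRT at nominal 0.05) and 400 two-ratio replicates at
ω_bg = 0.2, ω_fg = 1.5 (foreground-ω recovery); the planted-genome
study uses the 30-gene default (10 per category, 90 kb). These sizes
give stable Monte-Carlo estimates (binomial SE ≈ 0.015 at n = 200;
SE of the mean ω̂ ≈ 0.02 at n = 400) while keeping a full run in
minutes on one CPU.

The foreground-ω estimator is right-skewed at this design: the
foreground is one short terminal branch (0.04 expected substitutions
per codon, ~12 substitution events over 300 codons), so ω̂_fg behaves
roughly log-normally, with large spread and a mean slightly above the
generating value of 1.5. This is the familiar finite-sample behaviour of
ratio-type MLEs on sparse branches, not an engine defect — the
estimate is consistent (the shift vanishes as alignment length grows),
and the median sits close to the truth. The recovery replicate count
is chosen so the reported mean measures this expectation rather than
Monte-Carlo noise.

## Known limitations

- Branch lengths are re-scaled by one global multiplier, never
  re-estimated per branch; fits on data whose true lengths deviate
  non-proportionally from the input tree will absorb the error into ω.
- The episodic test omits synonymous rate variation.
- The built-in scanner's E-values are approximate (fixed gapped
  Karlin–Altschul constants, no edge-effect correction).
- The SLAC counting test uses MAP ancestral states, ignoring
  reconstruction uncertainty.
- The fixture tree topology within the non-heron Pelecaniformes is a
  transcription choice constrained only by the heron relationships and
  the outgroup; analyses conditional on that topology should treat the
  non-heron branching order as conventional.
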