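# Methods

`ta3scan` re-implements, at desk scale, the computational workflow used to
discover and characterize type III toxin–antitoxin (ToxIN) systems: homology
screening and clustering of ToxN-like toxins, annotation of the upstream
locus architecture (promoter, tandem antitoxin repeat array, intrinsic
terminator, toxin ORF), H-type pseudoknot prediction for the antitoxin
repeat with an imino-proton count, cleavage-consensus digestion of the
precursor antitoxin RNA, and one-/two-site ITC isotherm modelling with full
thermodynamic bookkeeping. This note records the models, the defaults and
why they hold, and the known limits.

## Homology screening and clustering

Candidate toxins are screened by optimal local alignment (Smith–Waterman,
affine gaps) under BLOSUM-45, with hits accepted at E-value < 1e-4 **and**
query coverage > 60% — both strict inequalities. Gap costs follow the BLAST
convention (a gap of length k costs `open + k·extend`); the defaults are
open 10 / extend 1, a standard BLOSUM-45 pairing, and both are exposed.
Residue `X` is accepted and scored 0 against everything.

E-values are estimated from a shuffle null rather than analytic
Karlin–Altschul statistics: each subject is shuffled
(composition-preserving), realigned to the query, a Gumbel distribution is
fitted to the null scores, and E = database size × exceedance probability.
This needs no precomputed λ/K and is seeded and deterministic; it
approximates BLAST E-values well enough for thresholding but is not
calibrated to them (fifty shuffles is the floor; the default is 100 in the
API and 50 in the pipeline, where the null is refitted per genome).

Families are delimited by single-linkage clustering of pairwise
global-alignment identities: connected components of the graph with an edge
wherever identity ≥ threshold. The identity denominator is the number of
aligned (both non-gap) columns, which excludes terminal overhangs. The
default threshold is 0.90; published cluster boundaries in this family were
drawn by expert inspection, so the threshold is a first-class parameter,
not a constant.

## Locus annotation

A functional type III locus is expected to show, in order on the toxin
strand: promoter < repeat array < terminator < ORF start, with the repeat
array downstream of the −10 box. `classify_locus` applies exactly that
test and returns machine-readable failure reasons otherwise. The annotator
scans the forward strand first and falls back to the reverse complement;
all coordinates are reported on the ORF strand (internally 0-based
half-open; GFF3 output is 1-based inclusive).

**Promoter.** σ70 consensus boxes TTGACA (−35) and TATAAT (−10), at most 2
mismatches per box, spacer 15–19 nt. Score = total consensus matches (max
12), best-first, ties to the leftmost placement. All five knobs are
configurable.

**Tandem repeats.** Scoring follows the Tandem Repeat Finder convention:
match +2, mismatch −7, indel −7, reporting threshold 50 (inclusive — an
array scoring exactly 50 is reported). Candidate periods are proposed from
exact 7-mer recurrences at each distance; each candidate region is aligned
to its majority consensus (ties to the earliest-occurring base) by
wraparound local dynamic programming, the consensus is rebuilt from the
aligned interval (anchored at the array start) and the alignment is run
once more — the same iterative refinement idea TRF uses. Copy number =
aligned length / period, rounded to one decimal; fractional arrays (e.g.
4.6 copies = 165 nt of a 36-nt unit) are the normal case. Overlapping
reports are resolved greedily by score, then leftmost, then shorter period.

Two detection limits are intrinsic and worth stating. First, a span
covering barely one period matches its own consensus trivially (score =
2 × length with no periodicity evidence), so reported arrays must span at
least two periods (`min_copies=2.0`); a single-copy "array" is undetectable
in principle, by this or any other tandem-repeat finder. Second, the exact
7-mer proposal stage can miss a short diverged array when substitutions
interrupt every exact 7-mer recurrence; the DP scoring itself is verified
against exhaustive enumeration wherever a candidate is proposed.

**Terminator.** An intrinsic (rho-independent) terminator is modelled as a
hairpin with a maximally extended stem ≥ 4 bp (Watson–Crick plus G·U/G·T
wobble), loop 3–8 nt, followed within 5 nt by at least 3 U/T. Score =
3·(G:C) + 2·(A:U) + 1·(G:U) over the stem. This is a structural scan, not a
nearest-neighbour free-energy model: adequate for the short, GC-rich
designed hairpins it must find, and auditable by brute force. One hit is
reported per hairpin window (a wider-loop/shorter-stem reading of the same
window is suppressed).

**ORFs.** ATG/GTG start to the first in-frame stop, either strand, default
minimum 30 codons; lengths count the stop codon. Nested starts yield nested
ORFs; the pipeline collapses overlapping homology hits to the longest ORF.

## Pseudoknot prediction and imino counting

The antitoxin repeat uses the field's numbering: positions −3…0 (4-nt 5′
overhang), 1…25 (core), 26…32 (3′ overhang); position 0 exists, so index =
position + 3. `ToxIRepeat` carries this mapping explicitly.

An H-type pseudoknot is two crossing helices S1 and S2 whose strands occur
in the order a1 < a2 < b1 < b2. Prediction is an exhaustive search over all
ordered pairs of base-disjoint crossing helices (every contiguous helix of
≥ 3 bp under {G:C, A:U, G:U}), scored by weighted pair counts G:C 3, A:U 2,
G:U 1. Ties break toward more total base pairs, then the 5′-most S1. At
repeat scale (≤ ~40 nt) this is exact and fully auditable; weighted counts
stand in for nearest-neighbour energetics deliberately — the goal is
reproducible architecture recovery, not folding thermodynamics. A
branch-and-bound cut (sorted helix scores) keeps the search fast to the
100-nt input bound.

Noncanonical pairs (the U·U pair closing stem S2 in the crystal structure)
are annotation-only: they are added explicitly and never predicted, because
their identification is crystallographic, not computational. Minimum helix
length for prediction is 3 bp to suppress spurious crossings; 2-bp helices
enter only via annotation.

Hydrogen-bonded imino protons (the 1D ¹H NMR observables) are counted per
pair geometry: G:C and A:U contribute one protected imino each (G N1-H, U
N3-H), G·U and U·U contribute two. On the crystal-derived scheme — S1 = 4
canonical pairs, S2 = 3 canonical + U12·U22 — this predicts nine iminos.
Spectra of such repeats can show more peaks than predicted when more than
one conformation is populated; conformational heterogeneity is outside this
counting model.

## Cleavage and digestion

The toxin's cleavage consensus is a short A-rich motif with a fixed scissile
position; shipped presets are GAA↓AU (the *E. coli* cluster-1/2 consensus,
default), AA↓AU and AAA↓AA. Scanning reports all, possibly overlapping,
occurrences; digestion applies non-overlapping cuts greedily left to right
(k cuts → k+1 fragments whose concatenation equals the input). End
chemistry is tracked: each internal cut leaves a 2′,3′-cyclic phosphate on
the upstream fragment and a 5′-OH downstream. An optional mask of paired
positions (e.g. from the pseudoknot module) can protect sites; no kinetic
model is attempted.

## ITC isotherm models

The antitoxin RNA sits in the cell and is titrated with toxin protein.
Three variants are implemented: one-site (n equivalent sites, closed-form
quadratic), two independent site classes, and sequential two-step binding
M + X ⇌ MX, MX + X ⇌ MX₂. Both two-site forms reduce to a cubic in the free
titrant concentration, solved by a vectorized Cardano formula with Newton
polish to relative tolerance 1e-10 (verified against bisection to 1e-8).
The sequential variant is the default two-site model, consistent with the
stepwise assembly picture (the 3′ site binds first, ring closure follows
via the 5′ site); which variant the original Origin analysis used is not
recoverable, so both are provided and recovery tests generate and fit with
the same variant. The independent-sites likelihood is invariant under site
exchange, so its fitted steps are reported weakest-affinity first.

Simulation uses constant-volume perfusion bookkeeping (VP-ITC style, 1.4 mL
cell default): each injection of dV displaces a fraction dV/V₀ of the cell
content, totals are diluted accordingly, and the heat of injection i is
q_i = V₀·(H_i − (1−f_i)·H_{i−1}) with H the ΔH-weighted complex
concentration. Heats are reported raw (μcal) and normalized (kcal per mol
of injectant); exothermic is negative. Temperature defaults to 288.15 K
(15 °C) with R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹, so ΔG = RT·ln K_D and
TΔS = ΔH − ΔG close exactly by construction.

Fitting is multi-start weighted least squares in log₁₀ K_D space (16
seeded starts over K_D ∈ [10⁻¹¹, 10⁻⁵] M; the first start uses a
deterministic mid-range guess), with per-step ΔH free and stoichiometry
fixed at 1 per step by default (the cyclic complex is 1:1 per protomer),
freeable by flag. Standard errors come from the least-squares covariance;
a fit whose covariance is unavailable or whose log₁₀ K_D error exceeds 2
decades is flagged non-identifiable rather than silently returned.

Model selection compares one-site vs two-site fits by small-sample
corrected AIC, with two guards: data that no binding model explains better
than a constant baseline is returned as "non-identifiable", and a two-site
fit flagged non-identifiable (a phantom second site pinned at a parameter
bound) is not counted as evidence for two sites.

**Identifiability at the published conditions.** With ~2 nM dissociation
constants at 3 μM cell concentration, the Wiseman parameter c = [M]/K_D is
≈ 1500: the isotherm is nearly stoichiometric and the K_D information lives
in a transition-rounding signal of ~0.01 μcal rms (after the fitted ΔH
values absorb what they can) against 0.1 μcal noise. The Cramér–Rao bound
then allows only factor-≈3 precision per K_D from a single titration, and
the recovery tests show exactly that scatter; noiseless round trips recover
all parameters to four significant figures, so the limit is statistical,
not algorithmic. The step ordering (second step tighter than the first) is
recovered robustly. The one-site case at K_D 47.3 nM (c ≈ 63) sits in the
classic well-conditioned window and recovers within a few percent.

## Synthetic data

The generators define the study conditions; their defaults are fixed, not
tuned.

**Families.** Each cluster descends from one ancestor; ancestors diverge
from a common root at disjoint mutated position sets, and members mutate
further disjoint sets, so realized within- and between-cluster identities
equal their targets exactly up to rounding (substitution-only — no indels —
so identity is analytically controllable). The reference cohort is five
3-member clusters plus two singletons at 97%/80% identity, 150 residues.

**Loci.** A locus is assembled as pad, −35 box, spacer, −10 box, gap,
repeat array, gap, terminator hairpin with U-tract, gap, ORF, pad.
Fractional copy numbers are realized as floor(copies × unit length)
nucleotides tiled from the start of the unit; promoter boxes carry exactly
the requested number of mismatches. The default 36-nt repeat unit is a
designed sequence (no full repeat sequence is published in machine-readable
form) with the authentic architecture: 5′ overhang starting AU, core
folding into S1 = 4 bp / S2 = 3 canonical bp + an annotatable U12·U22 pair,
3′ overhang ending GAA — so the GAA↓AU cleavage site spans consecutive
repeats and the cut falls exactly on the unit boundary, releasing uniform
36-nt fragments from a precursor array.

Because the unit length is a multiple of 3, a repeat array has only three
reading frames, all periodic; the unit carries stop codons in those frames
and the −10/array spacer carries stops in all three frames, so the array
can neither host nor transmit a decoy ORF. Three bases flanking the array
break the repeat phase so detected boundaries coincide with construction.
Remaining random-pad accidents (a decoy ORF as long as the planted one, a
higher-scoring promoter, a competing terminator) are rejected by redrawing
the pads from the same seeded stream — the generator emulates a clean,
unambiguous locus. Consequently, what the end-to-end tests demonstrate is
correct recovery of planted architecture from unambiguous loci; they do not
measure robustness to overlapping genes, promoter-like decoys, diverged
repeat units or sequencing error, none of which the generator emulates.

**ITC datasets.** Noiseless simulation plus i.i.d. Gaussian noise (sd in
μcal) on the raw heats, seeded; normalized heats recomputed consistently.

## Numerical and convention choices

- Coordinates: 0-based half-open internally; GFF3 1-based inclusive;
  between-nucleotide cut coordinates for cleavage sites.
- Repeat consensus ties go to the earlier-occurring base; array boundaries
  are the maximal-scoring alignment span, with the array start at the first
  full-period match by construction of the refinement anchor.
- Alignment tie-breaks: smallest query start, then shortest alignment
  (among up to 64 co-optimal tracebacks).
- Equilibrium solves scale concentrations to μM for conditioning; roots are
  clipped to [0, X_total] before polish.
- Problem sizes in the test-suite oracles: alignments ≤ 12 residues,
  pseudoknots ≤ 14 nt (100 randomized cases), promoter/terminator windows
  ≤ 80/60 nt, repeat windows ≤ 60 nt — sizes at which exhaustive
  enumeration is exact.

## Known limitations

- E-values approximate BLAST's; absolute values differ from Karlin–Altschul
  statistics though thresholding behaviour matches.
- The terminator model is structural, not thermodynamic; it will rank
  hairpins differently from a free-energy model when stems differ in
  composition.
- Single-copy repeat "arrays" are undetectable in principle; arrays whose
  substitutions erase every exact 7-mer recurrence are missed by the
  proposal stage.
- Two-site K_D estimates from a single titration at c ≈ 1500 carry
  factor-≈3 uncertainty (see above); the published ±30% error bars on such
  constants should be read as fit-conditional, not experiment-to-experiment.
- The pseudoknot score is not a free energy; competing structures within a
  few score points are not meaningfully ranked.
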