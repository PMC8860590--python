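# ta3scan

Desk-scale discovery and characterization of **type III toxin–antitoxin
(ToxIN) systems** in bacterial genomes. A type III system pairs an
endoribonuclease toxin (ToxN) with a noncoding RNA antitoxin (ToxI)
transcribed as a tandem array of repeats; the toxin processes the precursor
array into unit repeats, each repeat folds into an H-type pseudoknot, and
toxin and repeats assemble into an inactive cyclic complex. `ta3scan` is for
computational biologists who want a tested, scriptable re-implementation of
the full analysis workflow around such a system:

- **homology screen & clustering** — Smith–Waterman under BLOSUM-45 with
  affine gaps, shuffle-null Gumbel E-values, hits kept at E < 10⁻⁴ and
  query coverage > 60%, single-linkage clustering of pairwise identities;
- **locus annotation** — σ70 promoter boxes (TTGACA/TATAAT, ≤ 2 mismatches,
  spacer 15–19 nt), tandem repeat arrays under Tandem-Repeat-Finder scoring
  (match 2, mismatch 7, indel 7, min score 50) with wraparound dynamic
  programming and fractional copy numbers, intrinsic terminator hairpins,
  ORFs — and the four-element functional classification
  (promoter < repeats < terminator < ORF);
- **RNA structure** — exhaustive H-type pseudoknot prediction (two crossing
  stems S1/S2, loops L1/L2, the −3…32 repeat numbering), annotation of
  noncanonical pairs, and prediction of the hydrogen-bonded imino protons
  observable by 1D ¹H NMR;
- **cleavage** — consensus-site scanning (GAA↓AU and related motifs) and
  in-silico digestion of precursor arrays with 2′,3′-cyclic-phosphate /
  5′-OH end bookkeeping;
- **ITC** — one-site and two-site (independent or sequential) isotherm
  simulation with perfusion bookkeeping, multi-start least-squares fitting,
  AICc model selection, and ΔG = RT·ln K_D / TΔS = ΔH − ΔG accounting;
- **synthetic data** — seeded generators for protein families with
  controlled identity structure, complete TA loci with ground-truth
  coordinates, and noisy titrations, so every stage is testable offline.

## Worked example

Fit a two-step binding model to a simulated titration of antitoxin RNA
(3 μM in the cell) with toxin protein (40 μM in the syringe), using the
published two-step parameters and 0.1 μcal Gaussian noise:

```python
from ta3scan import BindingModel, TitrationSetup, IsothermModel, make_itc_dataset

truth = BindingModel.two_site_sequential(2.08e-9, 0.18e-9, -30.25, -44.38)
setup = TitrationSetup.uniform(cell_conc_uM=3.0, syringe_conc_uM=40.0)
data = make_itc_dataset(truth, setup, noise_sd=0.1, seed=7)
res = IsothermModel(data, setup, "two_site_sequential").fit(starts=16, seed=7)
print(res.summary())
```

```
Isotherm fit summary
====================
variant:            two_site_sequential
injections:         30
temperature (K):    288.15
chi-square (ucal^2): 0.1857
AICc:               -142.9
identifiable:       True

step     K_D (nM)   +/- (nM)  dH (kcal/mol)  dG (kcal/mol)  TdS (kcal/mol)      n
   1        1.631      0.511         -31.83         -11.59          -20.25   1.00
   2        0.303     0.0747         -43.08         -12.55          -30.53   1.00
```

Both dissociation constants come back nanomolar with the second step
tighter than the first (the ring-closing site), the enthalpies land near
the generating −30.25/−44.38 kcal/mol, and ΔG/TΔS close exactly by
construction. At these concentrations the isotherm is nearly
stoichiometric (c = [RNA]/K_D ≈ 1500), so individual K_D estimates carry
factor-level uncertainty — see `docs/methods.md` for the identifiability
analysis.

The designed antitoxin repeat folds into the expected pseudoknot:

```python
from ta3scan import (ToxIRepeat, predict_h_pseudoknot, annotate_noncanonical,
                     count_iminos, to_bracket, DEFAULT_REPEAT_UNIT_RNA)

rep = ToxIRepeat(DEFAULT_REPEAT_UNIT_RNA)
s = predict_h_pseudoknot(rep.sequence)
s = annotate_noncanonical(s, [(rep.index(12), rep.index(22))])  # U12-U22
print(rep.sequence); print(to_bracket(s))
print("hydrogen-bonded iminos:", count_iminos(s).total)
```

```
AUCAAGGCCAUUGCAUGCCUGAAAGUUGCCCUUGAA
....((((....[[[{)))).....}]]].......
hydrogen-bonded iminos: 9
```

Stem S1 has four canonical pairs `()`, stem S2 three canonical pairs `[]`
plus the annotated noncanonical U·U pair `{}`; seven Watson–Crick pairs at
one protected imino each plus two from the U·U pair predict nine imino
peaks.

## Command line

```bash
ta3scan simulate --what locus --out sim/        # synthetic TA locus + GFF3
ta3scan annotate --genome sim/locus.fasta --out annotated.gff3
ta3scan cluster --fasta toxins.fasta --threshold 0.90 --out clusters/
ta3scan pseudoknot --rna toxi.fasta --annotate-pairs U12:U22
ta3scan digest --rna precursor.fasta --motif GAAAU --cut 3
ta3scan itc-sim --kd 2.08 --kd 0.18 --dh -30.25 --dh -44.38 --out iso.csv
ta3scan itc-fit --csv iso.csv --model two_site_sequential
ta3scan run --genomes genomes.fasta --queries toxn.fasta --out results/
```

Exit codes: 0 success, 2 input error, 3 stage failure. All randomness flows
from `--seed`.

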