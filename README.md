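# sdabkit

Toolkit for designing, simulating and quality-controlling synthetic
single-domain antibody (sdAb/VHH-style) libraries, plus surface plasmon
resonance single-cycle-kinetics (SCK) analysis with a 1:1 Langmuir model.

## What it does

- **`sdabkit.scaffold`** — model a single-domain scaffold as
  FR1–CDR1–FR2–CDR2–FR3–CDR3–FR4 with a scaffold-local 1-based region map;
  derive per-column consensus frameworks, apply rule-based humanization
  (hallmark framework-2 positions 42/49/50/52 and Q103 are inviolable), and
  graft CDR loops (CDR1/CDR2 fixed at 7 aa; CDR3 in {9, 12, 15, 18} aa).
- **`sdabkit.diversity`** — rational CDR diversity: per-position amino-acid
  profiles with residue bans (no Cys in CDRs) and a proportional cap on
  hydrophobic mass; whole-codon (trinucleotide) mixes that realize each
  profile *exactly* at the DNA level with no stop codons; exact
  sequence-space counting and birthday-collision probabilities; designed vs
  observed profile comparison by total-variation distance.
- **`sdabkit.simulate`** — in-silico libraries drawn from a design, with a
  four-class defect taxonomy (in-frame stop, single-base frameshift,
  excised CDR1 or CDR1–FR2–CDR2 region, empty/stuffer clone), a packaged
  315-clone colony-sequencing QC fixture (13 defective under the pinned
  seed), a read simulator with substitution/indel/strand-flip errors, and
  synthetic cytometry event tables and panning-pool trajectories.
- **`sdabkit.qc`** — anchor reads to the scaffold frameworks by tolerant
  (Myers bit-parallel) alignment on both strands, extract CDRs, classify
  defects with a fixed precedence, and aggregate defect fractions, CDR3
  length mixtures, positional profiles, unique-clone collapsing and clonal
  dominance into a `QCReport`.
- **`sdabkit.kinetics`** — closed-form single-cycle sensorgram simulation
  (sequential ascending injections, no regeneration), reference-channel
  subtraction, and log-space nonlinear least-squares fitting of
  (kon, koff, Rmax) with KD = koff/kon.
- **`sdabkit.assay`** — knockdown percentage as the ratio of GFP medians
  between mCherry-gated subpopulations, control normalization, and
  differential ELISA positivity calling.

## CLI

Every module is exposed under the `sdabkit` entry point:

```sh
sdabkit scaffold graft --cdr1 GSIFSIN --cdr2 TISGSGS --cdr3 ARDLGYSSGWYD
sdabkit simulate sanger-fixture --out fixture.fasta --truth-out truth.tsv
sdabkit qc report fixture.fasta
sdabkit kinetics simulate --kon 1.66e4 --koff 4.88e-5 --out trace.csv
sdabkit kinetics fit trace.csv
sdabkit assay knockdown events.tsv --mcherry-threshold 700
```

Run `sdabkit <group> --help` for the full option list; all stochastic
subcommands take `--seed`.

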