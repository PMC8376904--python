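# Methods

## The screening problem

A FRET kinase biosensor reports phosphorylation of its substrate peptide as
a change in the ECFP/FRET emission ratio. `fretseq` implements the
computational side of a sort-seq strategy for improving such biosensors:
a library of substrate variants (three residues next to the consensus
tyrosine randomized with NNK codons) is expressed in mammalian cells fused
to either an active kinase domain (KA) or a kinase-dead mutant (KD), cells
are FACS-sorted into high- and low-ratio tails, and the sorted pools are
deep-sequenced. A desired biosensor is phosphorylation-switchable: high
ratio with the active kinase, low ratio with the dead kinase. Variants are
scored by enrichment of their read frequency in each sorted pool relative
to the unsorted input.

## Enrichment model

For variant v with read count c_v in a pool, the frequency is

    f_v = c_v / Σ_k c_k

and the enrichment ratio of a sorted pool against its input is

    E_v = f_v,sorted / f_v,input .

Selection requires, with strict inequalities,

    E_v(KAH) > 1,  E_v(KDL) > 1,  E_v(KAL) < 1,  E_v(KDH) < 1,

and candidates are ranked by the product E_v(KAH)·E_v(KDL), calibrated
against the parental (WT) variant's product. For plotting, E_v is mapped to
E_vn = log10(E_v) for E_v > 1 and E_v − 1 for E_v ≤ 1; the base-10 choice
only rescales the plot axis and cannot change any selection decision.

Counts with input CPM (counts per million) not strictly above 10 leave E_v
undefined; such variants are excluded rather than smoothed. No pseudocounts
are used anywhere: the CPM filter is what removes the spurious low-count
variants created by sequencing errors inside the unfiltered variable
region. Whether the CPM filter should also apply to the sorted pools is
ambiguous in the protocol; we require it on the input pool (where it
controls the E_v denominator) and report per-pool CPM for inspection.

Enrichment is computed at the amino-acid level after summing synonymous
DNA variants; DNA-level tables remain available for diagnostics.
Aggregating counts after computing DNA-level enrichment would give a
different (read-weighted) answer; the canonical path here is always
aggregate first, then Eq. 1–2. Stop-codon variants (the amber TAG is the
single stop reachable through NNK) are counted and kept in frequency
denominators but are never candidates.

## Read QC

A 50-bp single-end read covers constant flanks, the TAC codon of the
consensus tyrosine, and the 9-nt variable region at a fixed offset. A read
is accepted iff it has the exact amplicon length, Phred > 20 (strict, so
Q20 fails) at every constant position and at the three TAC bases, exact
base identity over the constant flanks, and TAC — not a synonymous TAT —
at the tyrosine codon. Variable-region qualities are deliberately not
filtered. Reads with N in any scored position are rejected as ambiguous.
Counting is single-pass and order-independent; a vectorized numpy path
(`count_fastq`) and a per-read reference path (`count_reads`) are
cross-checked for exact agreement in the tests.

## The generative simulator

`SimulationConfig`/`simulate_experiment` generate a complete experiment
with known truth so every pipeline stage is testable without real
sequencing data. Choices, and what they do and do not emulate:

* **Library skew** — variant abundances are log-normal (default sigma 1.0,
  a typical skew for a cloned plasmid library after amplification),
  normalized to sum to 1. Variants are distinct stop-free tripeptides, each
  spelled by one randomly chosen synonymous NNK codon triple; real
  libraries also contain synonymous duplicates and stop variants, which the
  counting layer handles but the default truth omits so that amino-acid
  truth labels are unambiguous.
* **Per-cell ratio model** — a cell's ECFP/FRET ratio is its variant's
  context mean plus Gaussian noise (default sd 0.15), truncated above
  zero. The real per-cell distribution is unknown; Gaussian is the
  simplest model that reproduces the overlap between sorted tails.
* **Variant classes** — neutral variants draw basal ratio N(1.0, 0.15) and
  have no kinase response. Responsive (desired) variants draw a tight low
  off-state N(0.80, 0.05) plus a kinase-dependent shift N(0.60, 0.10)
  clipped at 0, applied only in the KA context. The coupling of a low
  off-state with responsiveness is part of what "desired biosensor" means
  in this assay — it must sort low with the dead kinase — and mirrors the
  observation that KA and KD constructs of a working biosensor have
  clearly separated basal ratios. Misfolded variants (default 2%) draw
  basal N(1.5, 0.1) with zero shift: high in both contexts, the canonical
  sort-seq false positive that the kinase-dead arm exists to remove.
* **Sorting** — the floor(0.05·n) highest- and lowest-ratio cells form the
  high/low pools (top/bottom ~5% against the population median); ties
  break by stable cell order for reproducibility. KA and KD populations
  are independent cell libraries sharing the same truth, each sequenced
  with its own input pool (six FASTQ files per run).
* **Sequencing** — reads sample cells uniformly from a pool; substitution
  errors are iid per base (default 0.001, typical for a modern short-read
  run), uniform over the three alternative bases; no indels by default
  (the fixed-length QC would discard them), with an optional per-read
  deletion rate and an optional low-quality-base rate provided purely to
  exercise the QC filters. Base qualities are the Phred score implied by
  the error rate. PCR amplification bias, adapter read-through and
  quality-by-cycle decay are not modeled, so passing tests say nothing
  about those artifacts; the enrichment statistics are ratio-based and
  first-order insensitive to them.
* **Determinism** — all randomness derives from one seed through
  `numpy.random.SeedSequence` spawning; identical configs give
  byte-identical FASTQ.

Default problem sizes (500 variants, 10% responsive, 50,000 cells per
context, 200,000 reads per pool) keep a five-seed end-to-end study at
roughly half a minute while leaving ~40 expected input reads for the rarest
variant, comfortably above the CPM > 10 cutoff; they are the package's
reference study conditions, not tuned per-test knobs.

"Strongly responsive" in recovery metrics means shift ≥ the configured
shift mean (0.60 by default); weaker responders sit near the E_v = 1
boundary and their recovery is abundance- and noise-limited by design.

## Evaluation

Against simulation truth, positives are responsive non-misfolded variants;
precision/recall are plain set arithmetic. The 1D→4D sweep applies the
criteria cumulatively in the order KAH, KDL, KAL, KDH (KAH first, its
product partner second; the order affects only intermediate stages, never
the 4D endpoint) over the universe of variants with all four E_v defined.
Against tested-clone tables, the success rate is the fraction of clones
whose measured dynamic range strictly beats the WT, computed over all
clones or only over clones whose enrichment product exceeds the WT product
(the calibration threshold); an empty threshold set reports NaN
(not applicable).

## Drug-screen scoring

For the saFRET high-throughput screen, single-cell time courses are
normalized to each cell's pre-stimulation mean (idempotent; the normalized
pre-stimulation mean is exactly 1). Endpoint screens compare well means to
the pooled solvent (DMSO) control of the same biosensor context:
100·(treated − control)/control. The counter screen classifies a compound
as *nonspecific* whenever the kinase-dead biosensor also dropped by at
least the nonspecific threshold (default 10%), regardless of the active
arm; as a *hit* when the active-kinase change is ≤ −hit threshold (default
15%) with an acceptable dead arm; otherwise *inactive*; compounds without
a counter-screen measurement are *unevaluable*. The thresholds are
parameters because the underlying protocol ranks inhibitors rather than
fixing a numeric cutoff; compounds are reported sorted by active-arm
change, strongest apparent inhibition first. A ≥20% assay window advisory
(`assay_window_ok`) flags biosensors too insensitive for plate screening.

## Numerical notes and limitations

* Frequencies and enrichments are double-precision ratios of exact integer
  counts; tests compare them to big-integer rational arithmetic at
  1e-12 relative tolerance.
* All selection inequalities (Phred > 20, CPM > 10, E_v vs 1, product vs
  WT product) are strict; boundary values fail.
* Ranking ties break lexicographically on the amino-acid string.
* Degenerate inputs: empty pools raise; an empty candidate set yields NaN
  precision, which is reported as not-applicable rather than 0.
* The simulator does not model multi-variant cells (infection at MOI 0.1
  leaves ~95% of infected cells single-variant; `poisson_infection_profile`
  quantifies this but the cell sampler assigns exactly one variant per
  cell), nor sorter impurity, nor RNA-extraction bottlenecks between
  sorting and sequencing beyond uniform read sampling.
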