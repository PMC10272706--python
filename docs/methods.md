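# Methods

## Generative model

`bcrsim` simulates one heavy-chain rearrangement per record, in five stages.

**Locus.** A simulated individual genotype is drawn once per run from the
germline allele set: one allele per gene (haploid), up to two distinct
alleles per gene (diploid, the default), or every allele (`all`). Keeping a
genotype fixed within a run mimics the fact that a real repertoire comes
from one individual's allele complement.

**Segment selection** is a two-stage categorical draw per segment: family
from P(family), restricted to families present in the locus and
renormalized; then gene from P(gene | family), likewise restricted; then an
allele uniformly within the gene. Segments are drawn independently — V–J
pairing correlations are deliberately not modelled, so clustering statistics
over V/J combinations are outside what this simulator claims to reproduce.
Flat-gene and flat-family modes replace the empirical draw with uniform
choices for sensitivity analyses.

**Trimming** draws a length per site (V 3′, D 5′, D 3′, J 5′) from the
site's per-IMGT-family probability vector (families without a vector use the
recorded pooled vector). Order is fixed: V 3′, D 5′, D 3′, J 5′. Clamping is
by *truncation-renormalization*, not resampling: the vector is cut at the
admissible maximum and renormalized, so the conditional shape of the
distribution is preserved. D trims are jointly clamped to leave ≥ 1 nt of D.
In productive-only mode, V and J trims are additionally clamped to preserve
the 2nd-CYS and J anchor codons; in the default mode an extreme V (or J)
trim may remove an anchor, in which case the junction fields are empty and
the record is non-productive — reflecting that such a rearrangement has no
defined junction.

**NP insertion.** NP1/NP2 lengths are independent draws from their length
distributions. Bases follow a first-order, position-indexed Markov chain:
base 0 from `first_base`, base p from the 4×4 row-stochastic matrix at
position p (positions at or beyond the table reuse the last matrix). Two
matrix sets exist — non-mutated and mutated — chosen by whether SHM is on,
compensating at the composition level for the impossibility of knowing which
inserted bases were later hypermutated in real data. N and P nucleotides are
not distinguished; the insertion model absorbs both.

**Somatic hypermutation.** A frequency f is drawn from a binned per-sequence
distribution (uniform within the chosen bin); m = round(f·L) capped at L.
Position weights are mutability(5-mer centered at the position) ×
region_factor(region label), with sequence termini N-padded (N-containing
5-mers take the table mean). m distinct positions are drawn without
replacement proportionally to the weights, and each center base is
substituted via the per-5-mer substitution table (uniform over the other
three bases when absent). The junction, its translation, and productivity
are re-evaluated on the mutated sequence.

*Static vs sequential context.* By default weights are computed once on the
unmutated sequence ("static"): ground truth is then independent of the order
mutations are applied and exactly matched by an independent sliding-window
oracle. A "sequential" policy (`--shm-policy sequential`) re-evaluates
contexts on the current sequence after each mutation; it is slower and makes
realized rates depend on mutation order. NP positions are mutable with
region factor `np` (default 1.0).

## Coordinates, junction, productivity

All internal coordinates are 0-based half-open; conversion to the AIRR
convention (1-based inclusive) happens only at TSV serialization. The
junction runs from the 2nd-CYS codon (IMGT codon 104 of V) through the
J-TRP/J-PHE anchor codon inclusive; CDR3 is the junction minus the two
anchor codons. Productive requires: junction length divisible by 3,
junction translation starting with C and ending with W or F, and no stop
codon in the V-anchored reading frame of the full mutated sequence.
Productive-only simulation uses rejection sampling (never repair), so
conditional distributions are preserved; a rejection rate above 99% over a
10,000-attempt window aborts with a diagnostic.

## Randomness and determinism

Record i of a run with seed s is generated from an independent substream
keyed by (s, i, attempt) using numpy's `default_rng` seed sequences. Output
is therefore byte-identical across runs with equal flags and invariant to
generation order (serial, reversed, or parallel). The locus draw uses its
own substream of the run seed.

## Reference bundle and file formats

All distributions are long-format TSVs (`usage.tsv`, `trimming.tsv`,
`np_lengths.tsv`, `markov_nonmut.tsv`, `markov_mut.tsv`, `shm_freq.tsv`,
`fivemer_mutability.tsv`, optional `fivemer_substitution.tsv`,
`region_factor.tsv`) plus `manifest.json` (provenance, usage mode, content
checksum). Numbers are serialized with 12 significant digits, giving
bit-exact save/load round trips under the content checksum. Maximum trim
length, NP length and Markov position count are data-driven, never
hard-coded, so user bundles are not truncated. Loading validates every
invariant (non-negativity, normalization to 1e-9, row-stochastic matrices,
complete 5-mer coverage) and reports *all* violations at once.

## Synthetic reference

The built-in reference (also available via `bcrsim make-reference`) defines
the default study conditions:

- **V alleles** (default 12 genes over 4 families, every second gene with a
  second allele): 312 IMGT-gapped columns, gap codons at the ends of CDR1
  and CDR2, non-stop codons throughout the reading frame, codon 104 =
  TGT/TGC, plus a 2–6 nt germline CDR3 tail (ungapped length ≈ 295–310 nt).
- **D alleles** (8 genes, 3 families): random 10–37 nt.
- **J alleles** (4 genes): 40–60 nt with a W-G-x-G anchor motif 12–18 nt
  from the 5′ end and a non-stop, frame-aligned FR4.
- **Usage**: gamma(2)-weighted gene probabilities, aggregated to families.
- **Trimming**: geometric vectors with per-family means drawn from
  [1.5, 4.5] nt; maxima 9 (V 3′), 8 (D 5′/3′), 10 (J 5′) nt.
- **NP lengths**: Poisson shapes with means 4.8 (NP1) and 5.2 (NP2),
  support 0–20 — mode 4–5 nt as seen in heavy-chain junctions.
- **Insertion chains**: Dirichlet rows around a GC-biased base composition
  (GC 0.56 non-mutated, 0.64 mutated), 10 positions.
- **Per-sequence mutation frequency**: gamma(2.5, 0.02) discretized into 25
  bins on [0, 0.25]; mean ≈ 0.05 mutations/nt, typical of class-switched
  memory repertoires.
- **5-mer mutability**: WRC/GYW hotspots at 8× background, SYC/GRS coldspots
  at 0.25×, with a mild lognormal jitter (σ = 0.25, mean-preserving) on
  every weight so the table is near-continuous, as empirically derived
  mutability tables are.
- **Region factors**: CDRs elevated (1.6–1.8), FWRs reduced (0.7–0.8),
  NP 1.0.
- **Substitution**: transitions favoured 2:1 over each transversion.

What the synthetic reference does **not** emulate: real human gene-specific
usage and trimming values, allele polymorphism structure, V–J pairing
correlations, indels from SHM, clonal lineages, or sequencing error.
Passing tests on it demonstrates that the machinery reproduces whatever
distributions it is given and that ground truth is exact — not that the
default output is distributionally indistinguishable from any particular
human dataset; for that, learn a bundle from your own data with
`build-reference`.

## Reference builder estimators

From an annotated AIRR TSV: usage = normalized gene/family counts; trim
histograms per family (families under `min_count`, default 50, fall back to
the pooled histogram — unstable tails otherwise); NP-length histograms;
insertion matrices = position-indexed transition counts over NP1+NP2
strings with Laplace +1 smoothing (sparse high positions stay stochastic),
positions ≥ 10 sharing the last matrix, split into non-mutated/mutated by
`shm_count == 0` vs > 0; per-sequence frequency = 100-bin histogram of
`shm_freq` over [0, max]; 5-mer mutability = mutated-position counts over
occurrence counts on the SHM-reverted sequences, normalized to mean 1
(unobserved 5-mers = 1); region factors = per-region rate over overall
rate. No substitution table is learned (uniform fallback applies). Note the
recovered mutability confounds region effects and the without-replacement
saturation of hot positions, so the recovered hotspot/background ratio is
expected a little below the generating one (≈ 6.6 vs 8 at default
settings) — a property of the estimator, shared by comparable
repertoire-based mutability estimates.

## Numerical and design choices

- Trim chi-square checks use truncation-adjusted expectations: each record
  contributes the truncated-renormalized vector its draw actually came from.
- Goodness-of-fit bins are merged until every expected count ≥ 5.
- "Unique recombinations" counts distinct ground-truth tuples in the run
  log; duplicates are never removed, since deduplication would distort the
  sampled distributions.
- `--shm-freq-mean` rescales the frequency bin edges multiplicatively to
  hit the requested mean, preserving the distribution's shape.
- Degenerate inputs: a trim vector whose admissible mass is zero falls back
  to no trimming; an all-zero SHM weight vector is an error; a requested
  mutation count above the number of mutable positions is clamped with a
  warning.

## Problem sizes

The test suite exercises the statistical guarantees at the sizes they are
stated for: 10,000 sequences for ground-truth integrity and SHM frequency
calibration, 20,000 for distribution/Markov recovery, per-position
correlation, and builder closure. These sizes give comfortable
signal-to-noise for the chi-square and total-variation tolerances while
keeping a full run of suite plus acceptance script in a few minutes on one
CPU.

## Known limitations

Heavy chain only (no IGK/IGL or TCR loci, though nothing beyond defaults is
human-IGH-specific); no novel-allele inference; no SHM indels or selection
pressure; no clonal/lineage structure; no sequencing-error or quality
simulation; independent segment usage (no V–J pairing); P nucleotides not
modelled separately from N insertions.
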