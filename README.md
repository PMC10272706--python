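# bcrsim

Simulation of human B cell receptor (BCR) heavy-chain repertoires with
complete, per-sequence ground truth.

Benchmarking AIRR-seq annotation tools (V/D/J callers, junction analyzers,
SHM estimators) requires datasets where every recombination decision is
known. `bcrsim` generates such data: it replicates the immunoglobulin
heavy-chain rearrangement process — usage-weighted V(D)J segment selection
from a simulated individual locus, exonucleolytic trimming of segment ends,
non-templated (NP) nucleotide insertion at the V–D and D–J junctions, and
somatic hypermutation — and records every step. Output is a FASTA file of
sequences (ready as input for the tool under test) plus a TSV that closely
follows the AIRR Standards rearrangement schema, extended with ground-truth
columns (exact trim lengths and every mutation event), so that each output
sequence can be reconstructed byte-for-byte from its annotation row.

## Model

For each sequence:

1. **Segment selection.** A family is drawn per segment from the usage
   distribution P(family), then a gene from P(gene | family), then an allele
   uniformly among that gene's alleles in the simulated locus (haploid,
   diploid, or all-allele genotypes).
2. **Trimming.** Trim lengths at the four sites (V 3′, D 5′, D 3′, J 5′) are
   drawn from per-IMGT-family distributions, clamped by renormalized
   truncation so a D segment always retains ≥ 1 nt.
3. **NP insertion.** NP1/NP2 lengths come from empirical length
   distributions; the inserted bases follow a position-dependent first-order
   Markov chain, `P(b_p | b_{p-1})`, with separate transition matrices for
   mutated and non-mutated simulations.
4. **Somatic hypermutation.** A per-sequence mutation frequency f is drawn
   from a binned distribution and m = round(f·L) positions are selected
   without replacement with probability ∝ mutability(5-mer) ×
   factor(region), where the 5-mer is centered on the candidate position and
   the region is its IMGT label (FWR1–FWR4, CDR1–CDR3, or NP). Substitutions
   follow a per-5-mer table (uniform fallback).

The junction is reported from the conserved 2nd-CYS codon of V through the
J-TRP/J-PHE anchor codon, and productivity requires an in-frame junction
with intact C…W/F anchors and no stop codon in the V-anchored reading frame.

All distributions live in a **reference bundle** — a directory of editable
TSV files — and can be **learned from any annotated AIRR TSV** with
`bcrsim build-reference`, so you can simulate repertoires that mimic your
own data. A deterministic synthetic reference (germline alleles plus a full
bundle) is built in, so the tool runs with no external downloads.

## Worked example

```
bcrsim simulate -n 1000 --shm --seed 7 -o demo --verify
```

writes `demo.fasta`, `demo.tsv` and `demo.log`. The log is key=value:

```
version=0.1.0
seed=7
n=1000
shm=T
productive_only=F
heterozygosity=diploid
bundle_checksum=427fd7534488fe641ee4f648e934f14658b118591e6cee1dd2be2a9f7f158cd4
rejections=0
attempts=1000
unique_recombinations=1000
productive=46
```

`unique_recombinations=1000` means every ground-truth tuple (calls, trims,
NP strings) was distinct; `productive=46` is the count of in-frame,
stop-free rearrangements (without `--productive-only`, non-productive
sequences are kept, as in real pre-selection repertoires). `--verify`
re-derives every sequence from its TSV row alone and confirms
`verify passed: 1000/1000 rows reconstruct`.

A TSV row carries the standard AIRR columns (`v_call`, `junction`,
`np1_length`, 1-based segment coordinates, …) plus ground truth:
`v_trim_3p=3 d_trim_5p=1 d_trim_3p=5 j_trim_5p=2 shm_count=19`
and `shm_events=12:A>G;57:C>T;...` (1-based positions).

Other subcommands:

```
bcrsim make-reference --seed 3 --out ref/        # synthetic germline + bundle
bcrsim simulate -n 500 --germline ref/germline --reference ref/bundle -o run
bcrsim build-reference --input run.tsv --out learned/   # learn from data
bcrsim summarize --input run.tsv --out run_summary      # usage/trim/NP tables
bcrsim verify --input run.tsv                           # integrity check
```

Benchmark-oriented knobs: `--flat-usage {gene,family}`, `--no-trim
{v3,d5,d3,j5,all}` (repeatable; `--no-trim d5 --no-trim d3` leaves D genes
untrimmed), `--no-np`, `--shm-freq-mean 0.02`, `--productive-only`,
`--het {haploid,diploid,all}`.

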