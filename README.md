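# pamprospector

Toolkit for discovering and characterizing the protospacer-adjacent-motif
(PAM) specificity of Cas9 nucleases — the short DNA motif (5′-NGG-3′ for
SpyCas9, 5′-NAAN-3′ for adenine-dinucleotide recognizers such as
SmacCas9-derived hybrids) that a type II-A CRISPR enzyme must see next to
its target before it will cut. Because AA is the most abundant dinucleotide
in AT-rich genomes, an adenine-dinucleotide PAM opens sequence space that
GC-requiring nucleases cannot reach; this package implements the
computational workflow that finds such enzymes and quantifies what they
recognize.

It is aimed at protein engineers and CRISPR bioinformaticians who have
ortholog FASTA files, CRISPR spacers and phage genomes, reporter-sort trace
tables, or gel densitometry tables, and want the analysis chain between
those inputs and a PAM call.

## Pipeline stages

1. **Ortholog mining** (`pamprospector.ortholog`) — global alignment of
   ortholog proteins to a reference under BLOSUM62 with affine gaps
   (gap of length L costs 11 + L), filtering at a percent-of-self-score
   threshold (default ≥ 70%), and residue-conservation profiling around the
   PAM-contacting positions: `IC_j = log2(20) − H_j` bits per column.
   Orthologs that swap the contact arginines for glutamines are the
   candidates for adenine-PAM recognition. Includes hybrid-design
   bookkeeping (PAM-interacting-domain grafts plus verified point
   mutations).
2. **PAM inference** (`pamprospector.pam_inference`) — Hamming matching of
   CRISPR spacers against phage genomes on both strands, extraction of the
   8-nt flank 3′ of each protospacer, a position frequency matrix with
   `IC_j = 2 − H_j` bits, and an IUPAC consensus call.
3. **Reporter enrichment** (`pamprospector.enrichment`) — per-position
   `log2((post + ε)/(pre + ε))` between pre-sort and GFP-sorted base
   fractions of a randomized PAM library; bases at ≥ 2-fold enrichment are
   called, IUPAC-coded.
4. **Cleavage quantification** (`pamprospector.cleavage`) — cleaved
   fraction = product bands / all bands per gel lane; 4×4 NAAN matrices
   with replicate mean ± sd; first-order kinetics fits
   `f(t) = A(1 − e^(−kt))`.
5. **PAM landscape** (`pamprospector.landscape`) — PAM-site enumeration
   with candidate protospacers (BED output) and motif density: the fraction
   of windows matching the motif on either strand.
6. **Synthetic data** (`pamprospector.synthetic`) — seeded generators with
   truth records for every stage, so the full pipeline runs and validates
   offline.

## Worked example

Generate a synthetic phage cohort with a planted NAAN-profile PAM behind 40
protospacers, then infer the motif back from the spacers alone:

```bash
pamprospector simulate phages --seed 11 --out sim/
pamprospector infer-pam --spacers sim/spacers.fa --genomes sim/phages.fa --out pam/
# 40 hits, 40 flanks; consensus NAANNNNN
cat pam/consensus.json
```

```json
{
  "consensus": "NAANNNNN",
  "ic_bits": [0.1035, 1.381, 1.6636, 0.0267, 0.0112, 0.0649, 0.0105, 0.0072],
  "n_observations": 40.0,
  "low_confidence": false
}
```

The consensus reads 5′-NAAN-3′ over the PAM-proximal positions: the two
adenine positions carry 1.4–1.7 bits of information (out of 2 possible for
DNA), while every other flank position is near 0 bits — unconstrained, as
planted. A kinetics round trip works the same way:

```bash
pamprospector simulate timecourse --seed 4 --out tc/
pamprospector quantify-gel --lanes tc/lanes.tsv --mode kinetics --out kin/
cat kin/kinetics.json
# {"enzyme|TAAG": {"k_per_min": 0.312, "plateau": 0.884, "rss": 0.0026, "converged": true}}
```

The fitted rate 0.31/min and plateau 0.88 recover the generator's truth
(k = 0.3/min, plateau 0.9) from the 2%-noise time course.

Other entry points: `mine-orthologs` (filter + contact-residue profile),
`enrich` (pre/post trace comparison), `scan-pam` (site enumeration and
density statistics). Every command is a thin wrapper over the library
functions, which are the stable API.

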