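# memscan

Deep mutational scanning of membrane-span energetics: a reusable pipeline
from NNS single-site saturation-library design and simulated
selection/sequencing, through paired-end variant counting and apparent
free-energy landscapes, to membrane-depth insertion profiles, amino-acid
propensities, atomic-solvation-parameter inference, and insertion-corrected
self-association landscapes with structural interface filtering.

## How it works

A selection experiment plates a saturation library of a single-pass
membrane segment on a reference and on selective media. Deep sequencing of
each population yields per-variant counts; the pipeline converts them to
apparent free energies:

1. `p_i,j = count_i,j / count_wildtype` per population,
2. `s_i,j = p_selected / p_reference` (selection coefficient),
3. `ddG_i,j = -RT ln(s_i,j)` at T = 310 K.

Variants with fewer than 100 reference counts are masked; variants with
zero selected reads are censored (their stored value is a pseudocount-based
lower bound). Landscapes re-referenced to alanine are smoothed along the
span (window of 5), the membrane mid-plane is located at the trough of the
hydrophobic (Leu/Ile/Met/Phe) profiles, and 4th-order polynomials are fit
per amino acid over depth `Z = (position - midplane) * 1.5 A`. Downstream:
Boltzmann per-position propensities; the apparent atomic-solvation
parameter as the OLS slope of ddG against computed delta-SASA for
aliphatic-to-aliphatic substitutions in the membrane core (-9 A < Z < 13 A)
on an ideal helix model; and self-association landscapes corrected by
subtracting twice the insertion contribution, with likely/unlikely
interface labels used to filter candidate C2 homodimer structures.

A fully seeded synthetic-data module (clonal-representation bias, Boltzmann
selection under a known truth landscape, per-base sequencing error, paired
FASTQ emission) makes every stage testable without external data.

## CLI

```sh
memscan design-primers --construct human_CLS --out primers.fasta
memscan simulate --construct human_CLS --outdir sim/ --seed 1 --fastq
memscan count --construct human_CLS --r1 R1.fastq --r2 R2.fastq \
    --population reference --out counts_reference.tsv
memscan ddg --reference counts_reference.tsv --selected counts_selected.tsv \
    --out landscape.tsv
memscan profiles --landscape landscape.tsv --out profile.json
memscan propensities --landscape landscape.tsv --out propensities.tsv
memscan solvation --landscape landscape.tsv --sequence PLFIPVAVMVTAFSGLAFIIWLA \
    --first-position 295 --midplane 311 --out solvation.json
memscan dimer-correct --landscape measured.tsv --profile profile.json \
    --midplane 82.5 --out dimer.tsv
memscan classify --landscape measured.tsv --profile profile.json \
    --midplane 82.5 --out labels.tsv
memscan filter-models --labels labels.tsv --out decisions.tsv model*.pdb
memscan run-insertion --config run.yaml
memscan run-association --config run.yaml
```

Built-in constructs: `human_CLS`, `GpA`, `ErbB2`. Custom constructs are
flat YAML files (name, dna, span, numbering_start, flanks).

A run config for the pipelines looks like:

```yaml
construct: human_CLS
populations:
  reference: {r1: ref_R1.fastq, r2: ref_R2.fastq}   # or {counts: ref.tsv}
  selected: {counts: selected.tsv}
outdir: out/
min_count: 100
seed: 1
```

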