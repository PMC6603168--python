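# bcrpipe

B-cell receptor (BCR) repertoire analysis for UMI-tagged paired-end Ig
amplicon sequencing, built around one question: how do you pull the
antigen-experienced **memory** B-cell signal out of a blood draw dominated by
naïve cells?  Peripheral-blood (PBMC) heavy-chain repertoires are >90% IgM
with near-germline sequences; after polyclonal stimulation the same donor's
repertoire becomes IgG-dominated (IgG1 above all) with several-fold higher
somatic hypermutation (SHM) and large clonal expansions.  `bcrpipe`
implements the full computational workflow needed to process and compare
such repertoires, plus a ground-truth simulator so every stage is testable.

## What it does

1. **Preprocessing** — mean-Phred quality filtering, 5′/3′ primer
   annotation, excision of mixed-length (8/12 nt) unique molecular
   identifiers standardized to an 8-nt prefix, grouping of read pairs by the
   combined 16-nt UMI signature, quality-weighted consensus per UMI,
   paired-end assembly, constant-region isotype/subtype calling, and
   collapse of identical sequences of the same isotype with a
   ≥2-reads-per-UMI filter (an all-unique-reads view is also exposed).
2. **Annotation** — simplified germline V/D/J assignment by semi-global
   alignment (match +1, mismatch −1, gap −4), framework/CDR region
   projection, junction (CDRH3) extraction, and SHM as
   `100 × mismatched aligned columns / aligned columns` over the V segment,
   junction excluded.
3. **Clonal inference** — distance-to-nearest distributions on the junction
   within (V gene, J gene, junction length) partitions; per-sample optimal
   threshold at the kernel-density valley between the clone-mate and
   background modes (fallback 0.12); single-linkage clustering; and the
   constant-threshold mode, where the cross-sample constant is the rounded
   median of per-sample optimized thresholds — the bundled published
   per-replicate values give **12%**.
4. **Statistics** — per-isotype sequence/clone counts and mean SHM at the
   sequence and clone level, V-gene usage, isotype/subtype proportions, the
   subsampling Repertoire Dissimilarity Index (RDI) on V-gene usage, and
   Holm–Šidák-adjusted t comparisons of SHM distributions.
5. **Longitudinal analysis** — persistent sequences (nucleotide-identical
   over the Kabat-12..136 trimmed core in *every* timepoint, with a
   cross-sample UMI-disjointness contamination check and a strict >1%-SHM
   "mutated" classification), monoclonal-antibody-to-repertoire clonal
   matching at the 12% constant threshold, germline-rooted
   minimum-spanning-tree parsimony lineages with mutational-step edge
   labels, and the immunodominance grid (clone read abundance × mean SHM).
6. **Simulation** — V(D)J recombination with junctional trimming and
   N-insertions, power-law clone sizes, per-compartment isotype profiles and
   SHM rates, per-transcript UMIs, configurable reads per transcript and
   per-base error, multi-timepoint plans with planted persistent clones, and
   a full truth table for every read.

## Worked example

Simulate a PBMC-like and a stimulated-like sample from one donor and push
both through every stage:

```python
from bcrpipe.experiments import enrichment_experiment

result = enrichment_experiment(seed=7, n_cells=1000)
for label in ("pbmc", "stim"):
    s = result[label]
    print(f"{label}: n={s['n_sequences']} IgG={s['igg_fraction']:.3f} "
          f"SHM IgM={s['shm_igm_percent']:.2f}% IgG={s['shm_igg_percent']:.2f}%")
```

prints

```
pbmc: n=863 IgG=0.071 SHM IgM=0.77% IgG=2.87%
stim: n=979 IgG=0.724 SHM IgM=2.80% IgG=5.53%
```

i.e. the stimulated sample is read back by the pipeline as IgG-dominated
(72% vs 7%) with elevated hypermutation in both isotype classes — the
class-switch and SHM enrichment the workflow is designed to detect, and the
numbers agree with the planted simulation truth to a fraction of a
percentage point.

The same pipeline is scriptable from the shell, stage by stage or end to
end:

```bash
bcrpipe all --config run.yaml          # simulate → … → longitudinal
bcrpipe map-mabs --airr sample.tsv --mabs mabs.fasta --threshold 0.12 --out hits.tsv
```

where `run.yaml` lists samples, reference paths and stage parameters
(`q_mean`, `min_reads_per_umi`, `constant_threshold_percent`, seed, …).
Outputs are AIRR-style TSV rearrangement tables, clone tables, threshold and
persistence reports, Newick lineages, and a JSON run report with per-stage
read accounting.

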