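# ntermkit

An analysis toolkit for **protein N-terminomics** — the study of protein N
termini, the neo-N-termini created by proteases, and their co- and
posttranslational modifications. The package implements the computational
layer of a two-workflow, two-channel degradomics experiment: in silico
protease-specific identifiability of N-terminal peptides, classification and
isotopic quantification of enriched N-terminal peptides, staged winnowing of
putative caspase-3 cleavage sites, and discovery of posttranslational
neo-N-terminal acetylation events. A ground-truth simulator makes every stage
testable end to end without any external data.

It is written for proteomics bioinformaticians analyzing negative-selection
N-terminomics data (LysN- or ArgC-style workflows with isotopic dimethyl
labeling) and for method developers who need a controlled benchmark for such
pipelines.

## The model

**Identifiability.** Negative-selection N-terminomics blocks primary amines
and depletes internal peptides, so the observable N-terminal peptide of a
terminus at residue *s* is fixed by the digestion chemistry:

* **LysN workflow (LATE)** — LysN cleaves N-terminally to Lys; the peptide
  runs from *s* to the residue before the first K strictly after *s*.
* **ArgC-like workflow (HYTANE)** — lysines are dimethyl-blocked before
  trypsin digestion, leaving ArgC-like specificity; the peptide runs from
  *s* through the first R at or after *s*, inclusive.

A terminus is *identifiable* by a workflow when that peptide's length falls
in a configurable window, by default 7–35 residues. Because the two
workflows terminate on different basic residues, each can reach termini the
other cannot — the package quantifies this complementarity over any proteome
and any cleavage motif (the canonical caspase-3 motif is DEVD↓X, Asp at P1
in Schechter–Berger notation).

**Quantification.** Treated and control samples carry light
(+28.0313 Da, C₂H₄) and heavy (+34.0631 Da, ¹³C₂D₄) dimethyl labels. Per MS
run, PSM-level log₂(treated/control) ratios are median-centered; PSMs
sharing (protein, start, N-terminal state) are aggregated by summing peak
areas per channel; a record is *significant* when its ratio meets a fixed
2-fold threshold (log₂ ≥ 1, inclusive) or was observed only in the treated
channel.

**Winnowing.** Candidate cleavage sites are filtered by monotone, logged
stages: ratio-or-treated-only, P1 ∈ {D} (optionally {D,E}), minimum
evidence (≥ 2 PSMs pooled across workflows), and annotation against known
cleavage-site tables. A parallel workflow routes acetylated N termini into
ORF (cotranslational) acetylations, known-processing-derived acetylations
(e.g. after mitochondrial transit-peptide removal), and candidate
posttranslational neo-Nt-acetylation events, flagging the caspase-linked
subset.

## Worked example

```python
import ntermkit as nk

# 1. simulate a small ground-truth experiment (two workflows, two channels)
config = nk.SimConfig(seed=7, n_proteins=400, n_caspase_sites=60,
                      n_background_cleavages=20, n_treated_only=5,
                      n_processing=4, n_neo_acetylation=5, n_alt_init=3)
dataset, results = nk.pipeline_from_simulation(config)

# 2. what did the pipeline see?
print(results["classified"]["category"].value_counts().to_string())

# 3. staged caspase winnow
print(results["caspase_log"].as_frame().to_string(index=False))

# 4. how well were the spiked cleavages recovered?
print(nk.score_recovery(results["winnowed_caspase"], dataset.truth,
                        event_types=("caspase",)))
```

prints

```
category
ORF_start2    1372
neo            584
ORF_start1     516
internal       215
                stage  n_in  n_out
ratio_or_treated_only    89     64
              p1_in_D    64     64
       min_evidence_2    64     64
{'n_predicted': 64, 'n_true': 59, 'true_positives': 59,
 'precision': 0.922, 'recall': 1.0}
```

Reading the numbers: most PSMs are ORF N termini (start 1 with the
initiator Met, or start 2 after Met excision — here ~70% of proteins, the
human-typical rate); 584 PSMs map to neo-N-termini and 215 are residual
internal digestion peptides. Of the 89 quantified neo keys, 64 pass the
ratio-or-treated-only stage and all of those have Asp at P1. Every spiked
caspase site observable by at least one workflow is recovered
(recall 1.0); the five extra predictions are the simulated caspase-linked
neo-acetylation events — real planted cleavages of a different truth class,
not false background.

The acetylation router on the same run:

```
                 stage  n_in  n_out
      acetylated_nterm   627    249
        drop_orf_start   249     12
split_known_processing    12      8
         drop_alt_init     8      5
```

leaving exactly the five planted posttranslational neo-Nt-acetylation
candidates, each an acetylated neo peptide with P1 = D, absent from the
processing annotations — the structural signature of acetylation on a
caspase-generated neo-N-terminus.

## Command line

```bash
ntermkit simulate --seed 1 --out sim/                  # ground-truth dataset
ntermkit digest-coverage --proteome sim/proteome.fasta --motif DEVD \
    --window 7:35 --out coverage.tsv                   # per-site identifiability
ntermkit winnow --proteome sim/proteome.fasta \
    --psms sim/psms_LATE.tsv --psms sim/psms_HYTANE.tsv \
    --annotations sim/annotations.tsv --alt-init sim/alt_init.tsv \
    --known sim/known_sites.tsv --outdir out/          # full pipeline
ntermkit logo --sites out/winnowed_caspase_sites.tsv \
    --proteome sim/proteome.fasta --out logo.tsv       # P4-P4' logo matrix
```

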