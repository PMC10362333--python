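# Methods

## Coordinate conventions

Residue indices are 1-based and inclusive throughout. A cleavage site is
identified by its P1 residue index; the scissile bond lies between residues
`p1` and `p1 + 1`, so the neo-N-terminal peptide starts at `p1 + 1`. In
Schechter–Berger notation the eight residues P4–P1 / P1′–P4′ flank the bond;
windows at protein termini are `-`-padded. Sequences use the 20 canonical
amino acids; X/U/B/Z are tolerated in input but never match a protease
specificity residue or a motif position — a deliberately conservative choice
that can only under-call, never fabricate, cleavage sites. FASTA records
with identical accessions are a hard error; isoform entries are independent
records.

## Digestion and identifiability

A protease is a (side, residue-set, blocked-set) triple: cleavage C-terminal
(trypsin, ArgC-like) or N-terminal (LysN) to a recognized residue, with an
optional set of P1′ residues that suppress cleavage (proline for trypsin).
At zero missed cleavages the peptides tile the protein exactly; with *m*
missed cleavages every contiguous union of ≤ *m* + 1 adjacent fragments is
emitted. The engine is checked against an independent per-bond brute-force
splitter on a thousand seeded random proteins.

The observable N-terminal peptide of a terminus at *s*:

* LysN workflow: *s* … (first K strictly after *s*) − 1;
* ArgC-like workflow: *s* … first R at or after *s*, inclusive.

"Identifiable" is operationalized purely as peptide length ∈ [7, 35]
(configurable); no charge, hydrophobicity or detectability model is applied,
because peptide size is the one hard constraint the enrichment chemistry
imposes. A peptide with no terminating residue runs to the C terminus and is
flagged `runs_to_end`; it is still judged by its length. Coverage reports
are computed at zero missed cleavages — the nearest terminating residue
defines the peptide each workflow would nominally observe. The per-site
partition (LATE-only / HYTANE-only / both / neither) always sums to the
number of scanned sites, and widening the window can only grow the
identifiable set; both properties are tested.

Motif scanning is exact-set matching over 1–4 positions anchored at P1. A
match whose P1 is the protein's last residue is rejected: with no downstream
residue there is no neo-N-terminus to observe.

## PSM ingestion

The reference interchange format is a ten-column TSV
(spectrum/run/sample ids, peptide, N-terminal and lysine modification delta
masses, enzyme, probability, two channel areas), chosen over pepXML as the
canonical model because search-pipeline exports vary; a pepXML reader with
the same record contract is provided (totals are converted to deltas by
subtracting the proton or lysine residue mass). Rows below a probability
floor (default 0.95, standing in for an upstream <1% peptide-FDR filter —
the FDR computation itself is out of scope) are dropped with a count; the
readers guarantee `rows = kept + dropped + rejected`.

Modification deltas are named by nearest match within 0.01 Da:
dimethyl-light +28.031300 (C₂H₄), dimethyl-heavy +34.063117 (¹³C₂D₄),
acetyl +42.010565 (C₂H₂O), free 0. The tolerance is ~600× smaller than the
6.0318 Da spacing of the dimethyl isotopologues; an observed mass within
tolerance of two registry entries is an error, and unmatched masses are
retained as "unknown" rather than guessed. `raw_ratio` is fixed at
heavy/light here; which channel is the treated sample is a per-experiment
configuration applied at aggregation, because labeling orientation commonly
swaps between experiments.

## Classification

Peptides are mapped by exact substring search (optional I/L folding, since
the two are isobaric in MS/MS); a concatenated-haystack index makes
whole-proteome matching linear per query. Categories:

* `ORF_start1` / `ORF_start2` — start 1, or start 2 of a Met-initiated
  protein (Met excision inferred). Start 2 of a non-Met protein is **neo**:
  without an initiator Met there is no excision event to explain the
  position.
* `internal` — the N terminus coincides with a cleavage point of the
  sample-preparation protease **and** the α-amine is free/unlabeled. These
  are ordinary digestion products that enrichment should deplete.
* `neo` — everything else with start > 2 (labeled or acetylated α-amine, or
  a free α-amine off any enzymatic boundary).
* `ambiguous` — multi-protein matches whose per-match categories disagree;
  agreeing multi-matches keep their category with the multiplicity
  recorded.

Two precedence rules are deliberate design choices, not data-derived: ORF
wins over internal at starts 1/2 even for free α-amines (a position-1/2
free terminus is a genuine unmodified ORF terminus), and a free α-amine at
an enzymatic boundary is internal rather than neo (the protease explanation
is the parsimonious one; the alternative would inflate neo counts with
ordinary digestion products).

Labeling-efficiency QC reports the fraction of PSM α-amines that are
dimethylated or acetyl-blocked and the fraction of lysine side chains
dimethylated — the two numbers that establish N-terminal-specific labeling
chemistry worked (high α, low ε).

## Quantification

Order of operations: per-run median centering of PSM-level log₂ ratios
first, then aggregation. Normalization divides each heavy area by the run's
median ratio, so area-sum aggregation inherits the normalization exactly;
this also makes the removal of a global channel-mixing factor exact (an
injected 1.5× bias shifts the median by exactly log₂ 1.5 and cancels,
verified to 1e-9). Runs with fewer than 3 quantified PSMs pass through
unnormalized with a warning — a median over one or two points is noise.
Internal peptides participate in the run median when present; the median of
log ratios is the scale-free center of the run.

Aggregation keys are (accession, start, N-terminal state); the ratio is
Σ treated-area / Σ control-area over the key's PSMs — summing areas rather
than averaging ratios weights each PSM by its signal. Keys observed in one
channel only become directional singletons (`treated_only` /
`control_only`); no pseudo-ratio is ever imputed, which keeps infinities
and imputation artifacts out of downstream statistics. Significance is a
fixed fold threshold, inclusive (ratio ≥ 2, i.e. log₂ ≥ 1) by default with
a strict-mode alternative, plus treated-only singletons; no hypothesis test
is performed at this stage by design.

The ORF-level analyses — acetylated/free form pairing per terminus and the
susceptibility table grouped by N-terminal state × literal D/E presence in
the peptide — operate on the same aggregated records.

## Winnowing

Every stage maps a record set to a subset and logs (stage, in, out); a
stage that grows the set is a programming error and raises. The caspase
winnow keeps records that pass the ratio threshold or are treated-only
singletons, then requires P1 ∈ {D} (or {D,E} to admit the rarer
post-glutamate cleavages). Minimum evidence counts PSMs pooled across
workflows and runs (default ≥ 2); per-run distinctness is reported but not
required, since pooled counting is the weakest reading of "identified at
least twice" and therefore the least presumptive.

Reported/novel annotation is exact-position matching against known-site
tables, with protein-level novelty when the accession appears in no table.
A ±1-position tolerance mode exists but is off by default: cleavage-site
databases disagree on P1 vs P1′ indexing, and the tolerance mode documents
that hazard rather than silently absorbing it.

A known-processing match is a neo start at (signal/transit/propeptide
end + 1) or at the start (> 1) of an annotated chain. The acetylation
router applies, in order: keep acetylated termini → drop ORF starts →
split off known-processing matches → drop alternative-initiation matches →
remainder are candidates, with the caspase-linked subset flagged by
intersection with the caspase winnow output. Placing the alt-init filter
after the processing split is a declared ordering choice (the stages
commute only for records matching both). The alt-init exclusion consumes a
user-supplied (accession, position) table; no database is bundled.

## Cleavage-context statistics

Differential amino-acid-usage logo matrices subtract a single background
frequency vector (from a proteome or supplied directly) from the per-column
foreground frequencies, ×100. Padded slots are excluded from both numerator
and denominator rather than counted as a 21st symbol, which preserves the
column-sum-zero property exactly. Nearest-basic-residue distance histograms
count the start residue as distance 1, so for {R} the distance equals the
ArgC-workflow peptide length; sites with no such residue are censored into
a > max bin and counted outside the window.

Secondary-structure / relative-solvent-accessibility context summaries
consume externally precomputed per-residue annotations (per accession, a
code string and a [0,1] RSA vector). Two site groups are contrasted by
difference of median RSA with a seeded label-permutation p-value (default
10,000 permutations, plus-one corrected). The permutation contrast is this
package's choice of statistic for comparing accessibility distributions;
its null uniformity is checked empirically in the tests.

## The simulator

The generator emulates the statistical structure of a two-channel
treated-vs-control N-terminomics experiment; its defaults are the package's
reference study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 2500 | proteome size; lengths uniform 150–450 aa, Swiss-Prot-like residue frequencies, all Met-initiated |
| `p_met_excision` | 0.70 | per-protein initiator-Met removal |
| `p_orf_acetylation` | 0.74 | per-protein cotranslational Nt-acetylation |
| `n_caspase_sites` | 500 | spiked cleavage events, P1 = D, planted DEVD context |
| `effect_log2` | 2.0 | true log₂(treated/control) of spiked events |
| `n_background_cleavages` | 150 | non-D/E-P1 cleavages at true log₂ 0 (the null set) |
| `n_treated_only` | 25 | caspase events emitted in the treated channel only |
| `psm_per_event`, `psm_per_orf` | 4 | PSMs per event per observing workflow |
| `ratio_noise_sigma` | 0.3 | per-PSM normal noise on the log₂ ratio (log-normal on the ratio) |
| `internal_fraction` | 0.08 | internal-peptide share of each workflow's rows (post-enrichment regime) |
| `observability_mix` | 50/20/20/10 | both / LATE-only / HYTANE-only / neither classes among planted sites |

The Met-excision and acetylation rates are the proportions typical of the
human N-terminome; the effect size, noise level and PSM depth define the
recovery benchmark the tests assert against. Each planted site overwrites
the local sequence: the motif at P4–P1 and a 45-residue downstream zone
with K and R placed to realize the requested observability class. The truth
table's `observable_by` column is then **recomputed** through the digestion
engine, never set by hand, so simulator and engine cannot drift apart
silently. Processing events plant a transit-peptide annotation and an
acetylated neo terminus at its end + 1; alternative-initiation events
(an event class added to the truth vocabulary for routing tests) are
recorded in the exclusion table the router consumes. Light areas are
log-normal; heavy = light × 2^(true log₂ + bias + noise). The simulator
writes the same PSM TSV dialect the ingestion module reads, so the pipeline
is exercised end to end through its public interfaces only; all floats are
written at fixed precision, making repeated runs byte-identical under a
seed.

What the simulator does **not** model — and what passing tests therefore do
not show about real data: spectrum-level effects (no m/z peaks, no search
engine, no FDR behavior), retention time and detectability beyond the
length window, missed cleavages in observed peptides, shared-peptide
ambiguity beyond chance collisions of random sequences, biological
covariance between cleavage susceptibility and sequence context, and any
real secondary-structure/RSA signal. Results on simulated data validate the
pipeline's arithmetic, bookkeeping and selection logic, not instrument- or
search-level robustness.

## Problem sizes and numerical choices

The reference configuration (2500 proteins, 500 spiked keys, 4 PSMs/key,
σ = 0.3) runs the full pipeline in a few seconds and gives a recovered-mean
standard error of ~0.007 log₂ units — comfortably inside the ±0.15
recovery band the tests assert. The spiked events are kept a minority
(~13% of quantified rows) so the run median sits in the null population;
median normalization then biases the recovered effect by under 0.1 log₂
units, which is part of what the recovery tolerance absorbs — the same
trade-off any median-normalized experiment with a minority of true changes
makes. Null false-positive calls at the 2-fold threshold are binomially
negligible at these settings (key-level σ ≈ 0.15 against a log₂ ≥ 1 cut).
Degenerate inputs are handled explicitly: empty proteomes, empty window
sets and empty observation lists raise; zero-area-both-channels keys are
dropped with a count; sparse runs skip normalization with a warning.

## Known limitations

* Classification trusts exact sequence matches; peptides from unrepresented
  isoforms or variants mis-map or vanish silently (beyond the logged
  no-match count).
* The identifiability model is length-only; real detectability also depends
  on ionization, hydrophobicity and co-elution.
* `known_processing_match` requires exact feature coordinates; UniProt
  features with uncertain ends will not match.
* The pepXML reader covers the Comet + PeptideProphet + XPRESS layout; other
  quantification engines need the TSV route.
* Aggregation keys include the start position only; a terminus observed
  with different C-terminal extents (missed cleavages) aggregates together
  by design, which is usually wanted but hides extent-specific effects.
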