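# Methods

## Seed-site model

A mature miRNA of length ≥ 8 defines three target-strand patterns from its
seed (positions 2–8, 1-based from the 5' end):

| class   | target pattern (5'→3')     | length |
|---------|----------------------------|--------|
| 7mer-A1 | revcomp(positions 2–7) + A | 7      |
| 7mer-m8 | revcomp(positions 2–8)     | 7      |
| 8mer    | revcomp(positions 2–8) + A | 8      |

The terminal adenosine is treated as a literal target A, not as a pair to
miRNA position 1 — the canonical convention.  Only exact Watson–Crick
complementarity counts (no G:U wobble), and only the sense strand of the
supplied transcript is scanned, since mRNA targeting is single-stranded.
DNA input is normalized to RNA (T→U) before scanning, so DNA and RNA forms of
the same transcript give identical results.

Every 8-nt window is classified with priority 8mer > 7mer-m8 > 7mer-A1, so a
window yields at most one call and each site carries a single class, and any
7mer call whose span lies inside a reported 8mer span is suppressed.  One
consequence of the fixed 8-nt window: a 7mer-A1 heptamer starting at the very
first transcript base, or a 7mer-m8 heptamer ending at the very last base,
has no covering window and is not reported.  These single-base boundary cases
are irrelevant in practice (sites at the extreme transcript termini are not
functional) and the brute-force reference scanner used in the tests shares
the contract.

Sites are localized by the region containing the whole matched span: 5'UTR =
[0, cds_start), CDS = [cds_start, cds_end), 3'UTR = [cds_end, length), all
0-based half-open in transcript coordinates (reports use 1-based inclusive).
Spans straddling a boundary are labelled `junction` and excluded from the
CDS/3'UTR distribution denominator; 5'UTR sites are detected and reported but
excluded from the headline distributions by default (configurable), since
functional sites overwhelmingly lie in CDS and 3'UTR.  Noncoding transcripts
are rejected at input: the analysis is defined for protein-coding targets.

## Differential expression

The mimic-vs-NC contrast uses a mean-ratio log2 fold change with pseudocount,
log2FC = log2((mean mimic + ε)/(mean NC + ε)), ε = 1 TPM.  This is exact and
deterministic with one sample per condition — the design this pipeline
addresses has no replicate structure to support a dispersion-modelling test,
and direction calls are pure fold-change thresholds without p-values.  The
1.5-fold call threshold is applied symmetrically (|log2FC| ≥ log2 1.5 ≈
0.585, boundary inclusive); "shared" sets require the same direction in every
cell line and the "strong down" table additionally requires log2FC < −0.9 in
every line, ranked by mean log2FC ascending with gene-id tie-breaks.

## Targeting-preference statistics

* site-presence fraction: genes with ≥ 1 site over all shared-down genes
  (genes without a summary count as site-free);
* mode distribution: proportions of the three classes over all (non-5'UTR)
  sites of shared-down genes;
* region distribution: proportions over sites in {CDS, 3'UTR} only;
* dose–response: Spearman rank correlation of per-gene log2FC against total
  site count within shared-down genes, per cell line, with its two-sided p;
  constant site counts or fewer than 3 genes give a flagged not-applicable
  result rather than a number.

Over-representation of a regulated set in user GMT pathways is the one-sided
hypergeometric upper tail P[X ≥ k] for X ~ Hypergeom(N, K, n) with the
expression-table genes as the default universe, Benjamini–Hochberg adjusted
across pathways.  No pathway content is bundled; users supply their own GMT.

## Cohort screen

Endpoints and tests, chosen to be standard nonparametric procedures matching
the screen's discovery character:

* **survival** — expression dichotomized at the cohort median (ties to the
  low group, deterministically); two-group log-rank test; sign `+` when the
  high-expression group's Kaplan–Meier median survival is longer (favorable).
  When a median is undefined or tied the event-rate comparison breaks the
  tie.  Effect = signed −log10 p (for volcano plots).
* **T stage / pathological stage** — Spearman correlation with the ordinal
  stage 1–4 (sub-stages collapse to their integer; TX/MX are missing);
  effect = rho.
* **M stage** — two-sided Mann–Whitney U between M0 and M1; the exact U
  distribution is used for small tie-free groups (both ≤ 25), the normal
  approximation otherwise; effect = rank-biserial correlation, sign by the
  median difference.

Signs are gated at raw p < α = 0.05 with no multiple-testing correction by
default — the screen is a discovery filter whose output is meant to be
validated downstream; per-endpoint BH adjustment is available
(`bh_correct=True`).  A miRNA enters the screen only if detected (> 0) in
more than `min_expressed_samples` patients (default 300, matching a
≈ 390-patient cohort; the demo mode scales this to half its simulated cohort
size).  Classification requires ≥ 2 significant endpoints of one orientation
(oncogenic: survival −, stage +, M +; suppressor mirrored); mixed significant
orientations yield `none` with a conflict flag; `promising` requires all
three endpoint groups (survival; T or pathological stage; M) to agree.
Missing clinical fields reduce the per-test n and are never imputed.

## Synthetic data

`make_transcriptome` plants sites on a uniform-composition background
(GC content configurable).  Backgrounds are rejection-sampled and every
finished transcript is re-scanned; a transcript is accepted only when the
scan equals the plan exactly, so the truth table is exhaustive — no
accidental site survives.  Guard bases prevent a planted 7mer from extending
into a stronger class (a non-A base after a 7mer-m8; a base other than the
8mer pattern's first nucleotide before a 7mer-A1).  Defaults mirror the
observed targeting profile: 60% of genes carry 1–3 sites, the three classes
are equally weighted, and regions split 86% 3'UTR / 14% CDS.

`make_mimic_experiment` draws per-gene log-normal NC abundance
(log2 mean 7, SD 1.5, floored at 2^3 so every simulated gene is solidly
expressed) and multiplies the mimic sample by 2^(δ·1[has sites] + noise)
under saturation (default) or 2^(δ·site count + noise) in dose-dependent
mode, δ = −1, noise SD σ = 0.1.  The saturation default encodes the empirical
finding that repression depth does not scale with site count.

`make_cohort` draws i.i.d. Gaussian log2 expression per miRNA (plus a couple
of rarely-detected miRNAs to exercise the prevalence filter) and generates
clinical data from the planted effects: exponential survival with hazard
λ_i = λ0 · ∏ HR^(dir·z_i) (λ0 = 1/1000 days, HR = 2 per SD of expression),
independent exponential censoring tuned to the requested censoring fraction
(default 0.33; a rate ≥ 1 censors everyone), proportional-odds T and
pathological stages (base distribution 10/25/40/25%, log-odds shift 0.8 per
SD), and logistic metastasis status (prevalence 12%, shift 1.2 per SD).
`dir` is +1 for a planted oncogenic miRNA and −1 for a suppressor.  These
effect sizes give well over 80% per-endpoint power at the default 391 (or
300) patients, so recovery simulations run in seconds.  A small fraction
(2%) of stage/metastasis fields is blanked to exercise missing-data paths.

What the generators do *not* emulate: correlated miRNA co-expression,
batch/library-size artifacts, isoform mixtures, non-exponential hazards, and
stage–survival confounding beyond what the shared latent predictors induce.
Passing the planted-recovery tests therefore demonstrates correctness of the
algorithms under the stated generative model, not performance on real
cohorts.

## Numerical and design notes

* All generators are pure functions of a `SimulationSpec` (integer-seeded
  `numpy` PCG64); identical specs give byte-identical output files.
* Problem sizes in the test-bed runs — 1000 random scanner pairs, 100
  knockdown replicates at 200 genes, 200 cohort replicates at 300 patients —
  are the package's chosen simulation scale; they estimate the Monte Carlo
  rates to ≈ 2–3 percentage points.
* Spearman and Mann–Whitney p-values follow scipy's conventions; the
  hypergeometric tail is exact (`hypergeom.sf(k−1, N, K, n)`), verified
  against exhaustive enumeration for all N ≤ 12.
* Degenerate inputs are flagged, not guessed: all-censored survival, constant
  stage, empty M groups, constant site counts and empty gene sets all return
  explicit not-applicable results or raise typed errors.
* Coordinates are 0-based half-open internally and 1-based inclusive in every
  written report; the annotation TSV documents its convention in a header
  comment.
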