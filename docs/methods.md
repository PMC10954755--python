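# Methods

This note records the models, conventions, and design choices behind
`readthru`, in the spirit of a statistical methods appendix.

## Coordinates and the extension region

Transcripts are spliced mRNAs partitioned into 5'-UTR / CDS / 3'-UTR, with
the stop codon counted as part of the 3'-UTR (`cds_len` covers sense codons
only). Internally all coordinates are 0-based half-open; user-facing
tables are 1-based inclusive. The extension region starts at the first
base after the canonical stop and ends at the first in-frame stop codon
downstream (exclusive). When no in-frame stop exists before the
transcript end, the region runs to the last complete in-frame codon
boundary and the record carries `has_downstream_stop = False`, so such
records can be excluded downstream if desired. Sequences are normalised
to RNA (T→U); any character outside A/C/G/U/N invalidates a record, and an
N inside a requested feature window excludes the record from modelling
(explicitly, with a reason, never silently).

## Readthrough efficiency

RPKM is reads / (region length in kb) / (mapped reads in millions). For
one transcript, log2 RE = log2(RPKM_ext / RPKM_CDS); the library size
cancels, so the ratio is a length-normalised count ratio. The
detectability filter removes records with RPKM_CDS < 5 **or** RPKM_ext <
0.5: the thresholds are quoted jointly in the literature this follows, but
a record failing either is unusable (zero extension signal has no defined
log ratio), so the union is applied and the per-reason counts are
reported. Extreme labelling takes exactly floor(0.15 n) records per side,
with ties broken on (log2 RE, transcript id) so results are invariant to
input order.

## Feature schema (full-v1)

The 75-feature composition is: context (21) = stop codon, nt −1..−9,
nt +4..+12 (stop bases are +1..+3, so +4 is the first 3'-UTR base), P-site
codon, P-site amino acid; tunnel (10) = fraction positive/negative/
aromatic/proline/glycine/polar/small residues, net charge, mean
Kyte–Doolittle hydropathy, and the C-terminal residue's charge class, all
over the last 30 encoded residues (the nascent-peptide stretch spanning
the exit tunnel); other (44) = nt −10..−30 (21), nt +13..+30 (18), the
three region lengths, and the E-site codon/amino acid. The two negative
controls (uniform integer 1–100; uniform letter A/C/G/U) sit outside the
75 and are keyed on (seed, transcript id), so their assignment is
order-invariant and independent of all biology. Positions that run off
the annotated regions take the explicit level `NA_short`.

The exact published feature list this mirrors is not enumerated anywhere
in print; this composition is the unique arithmetic fit to the documented
group counts (21 + 10 + 44 = 75) and is versioned so alternative
compositions can be swapped in as `custom` schemas.

Variant schemas for model comparison: **reduced** = context features plus
every non-tunnel feature counted as important; **assay** = reduced minus
3'-UTR length and all other non-context features, i.e. exactly the 21
features a reporter insert carries; **mock1–3** = seeded random subsets
of low-importance features, size-matched to reduced. Because the scaled
permutation importance is a t-like statistic, the two negative-control
scores alone make a noisy cutoff (about half of the uninformative
features exceed their maximum by chance); a feature therefore counts as
important only when its score exceeds both the larger negative-control
score and 2 (nominal significance), and a feature is mock-eligible when
its score is at most max(larger negative-control score, 0) — a
non-positive permutation importance is uninformative by definition even
when both controls happen to land below zero. Without an importance
table, reduced falls back to context + 3'-UTR length.

## Random forests

Forests are explicit bagged ensembles of scikit-learn decision trees with
our own bootstrap, because the importance statistics are defined on
out-of-bag (OOB) samples and need per-tree bag bookkeeping. Defaults
follow the classic tool: 100 trees; minimum leaf size 5 for regression
and 1 for classification; mtry (features tried per split) tuned by 5-fold
cross-validation over {1, ⌈p/10⌉, ⌈p/3⌉, ⌈√p⌉, ⌈p/2⌉}, minimising NRMSE
(regression) or maximising AUROC (classification); variant-schema models
skip tuning and use the task heuristic (p/3, √p). Fold NRMSEs are
normalised by the full training-response range so folds are comparable.
Categorical features enter trees as integer codes over frozen,
alphabetically ordered level registries (a documented deviation from
native categorical splitting; the registry travels with the model, and
unseen levels at prediction time map to the NA bucket with a warning).

Permutation importance: for each tree and feature, the feature's values
are permuted among that tree's OOB samples and the OOB error (MSE or
misclassification rate) is recomputed; the across-tree mean increase
divided by its standard error is the reported score (the %IncMSE / MDA
scaling convention), with the unscaled mean stored alongside. Constant
features score 0 by definition. AUROC is computed by midranks
(equivalent to all-pairs concordance with half-credit ties).

## Statistics

Group-median analysis compares each group against the full sample
("sample median" convention; the complement comparison is available by
flag), using the two-tailed Wilcoxon rank-sum test — exact when both
groups are ≤ 50 and tie-free, otherwise the normal approximation with
continuity correction — with BH correction within each grouping family.
Groups below 5 members are reported but flagged. The stop × nt+4 table
uses Pearson's χ² with independence expectations (margin products);
adjusted standardized residuals (O−E)/√(E(1−p_row)(1−p_col)) are referred
to N(0,1) per cell, with raw Pearson residuals also emitted. An
equal-frequency expectation variant is available because the two readings
of the published analysis differ. Spearman correlations use midranks;
the length-restricted variant applies strict bounds 100 < L < 5000 nt.

## 3'-UTR folding

The quantity used downstream is the lowest local MFE per 3'-UTR (stop
codon included by default, configurable), with 0 assigned when nothing
folds. The `viennalocal` backend parses RNALfold (`-L 150`) output and
takes the most stable reported local structure. The `builtin` backend is
a deterministic banded dynamic program over the same span limit with a
simplified energy model — pairs G-C −3, A-U −2, G-U −1 kcal/mol, −1 per
stacked pair, hairpin loops ≥ 3 nt — reporting the best single *closed*
structure (one exterior pair with any nested content), not the best
additive combination over a window. It exists so the MFE–length–RE
correlation analysis is runnable and testable without external software;
it is exact for its own model (verified against exhaustive enumeration on
short sequences) and deliberately does **not** reproduce Turner/RNALfold
energies.

## PTC contexts

Alleles are specified in transcript space (codon index + stop identity),
avoiding genome-build ambiguity. The native record truncates the CDS at
the PTC; everything downstream (former CDS remainder + native 3'-UTR)
becomes the new 3'-UTR and the extension region is re-derived from the
PTC (the next in-frame stop usually falls inside the former CDS). The
reporter record embeds PTC ± 3 codons between a stop-less upstream gene
and a start-less downstream gene; all features outside the insert derive
from the backbone and are constant across alleles under one construct
(the E-site codon is the one "other"-group feature inside the insert).
The shipped backbone generator produces random luciferase-sized genes and
is labelled synthetic — real constructs can be supplied as sequences.

## Dual-luciferase processing

Well-level readthrough is firefly/Renilla × 100 (scale-invariant).
Replicate-well outlier handling: while SD/mean × 100 > 25% and more than
two wells remain, the well farthest from the current mean is removed and
the criterion recomputed; every exclusion is logged with before/after
dispersion. The published rule names the trigger but not the removal
procedure; iterative farthest-from-mean removal is the smallest
intervention achieving the stated criterion, and a single-pass mode is
available. Wells are technical replicates within an experiment, so the
G418 response is computed from per-experiment condition means:
log2(mean treated / mean untreated), averaged over independent
experiments. Stop-group comparisons are the three pairwise two-sample
Student's t-tests with BH over the three p-values; an exactly constant,
exactly equal pair of groups is reported as p = 1 rather than NaN.

## Synthetic data: what it emulates, and what it does not

The generator draws transcripts with stop-codon usage 49/27/24%
(UGA/UAG/UAA, the transcriptome-wide reference composition), nt +4
frequencies favouring A and G (0.32 each) over C (0.24) with U depleted
(0.12), uniform-random sense codons elsewhere, uniform 5'-UTR lengths
(50–300 nt), uniform CDS lengths (40–400 codons), and log-normal 3'-UTR
lengths (median 300 nt, ln-σ 1.0, minimum 36 nt). The latent truth is

    log2 RE = intercept + b_stop + b_nt4 + b_len·log10(L_3'UTR) + b_psite + ε

with defaults: intercept −6 (≈1.6% basal readthrough), b_stop = +0.6 /
0 / −0.4 (UGA/UAG/UAA), b_nt4 = +0.3 / +0.1 / −0.2 / −0.2 (C/U/A/G),
b_len = 0.8 per log10 nt, b_psite = +0.3 for UGG and −0.2 for AAG, and
ε ~ N(0, 1). With ln-σ = 1.0 the log10 length SD is 0.434, so the
length term contributes SD 0.35 against total SD ≈ 1.16, giving a latent
length–RE Spearman correlation of ≈ 0.30 — the planted value the
correlation analyses recover. Counts are gamma-Poisson: CDS counts
around coverage (0.5 reads/nt default) × log-normal expression × length,
extension counts scaling the per-nt CDS rate by 2^(log2 RE); one shared
library size. At the default depth roughly a third of transcripts fall
below the extension-region threshold, reproducing the detection-bias
regime the filter exists for.

For model-variant comparisons a `strong_signal_config` (doubled context
effects, σ = 0.5) is the stated condition: at the default signal-to-noise
the full-vs-mock NRMSE separation is smaller than the ≈0.05 gap those
comparisons are about (the explainable variance share must exceed ~55%
for the gap to open), so the comparison is run where it is resolvable.
Scheme-agreement analyses use the strong config with b_len = 0 so all
planted effects live in the context window shared by native and reporter
presentations.

The generator does not emulate footprint-level reads (no 3-nt
periodicity, no P-site offsets), isoform structure, codon-usage or
tRNA-adaptation covariates, programmed readthrough genes, or any
structure→RE coupling (the planted MFE–RE correlation is zero). Passing
recovery tests therefore demonstrates that the pipeline measures what it
claims under its stated noise model — not that real HEK293T data would
yield the same effect sizes.

## Problem sizes and numerical conventions

The study-scale analyses run at n = 3,000 transcripts with 20-seed
replication for recovery properties; folding analyses default to 1,000
UTRs with the builtin backend. All randomness flows from explicit seeds
through named substreams (derived with `SeedSequence`, kept below 2³¹);
reruns of any CLI subcommand with the same seed are byte-identical (run
manifests contain no timestamps). Ties are broken deterministically
everywhere (extreme labels, level registries, mtry grid preferring the
smaller value on ties).

## Known limitations

- The integer coding of categoricals lets trees exploit the registry
  order; with 100 trees and tuned mtry this did not distort the
  negative-control baseline in testing, but native categorical splitting
  would be preferable if the tree backend offered it.
- NRMSE normalises by the observed response range, which grows slowly
  with n; comparisons across very different sample sizes should use the
  same normalisation base (the trainer stores the training range).
- The builtin folding model has no loop entropies or dangles; its MFE
  scale is not comparable to RNALfold's, only its ordering behaviour.
- Leave-k-out outlier scanning in scheme comparison is brute force and
  intended for reporter-panel sizes (tens of alleles), not thousands.
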