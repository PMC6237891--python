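# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Sequence features

**Composition.** Codons are counted over the coding frame with the terminal
stop excluded and the initiator Met included; percentages are on a 0–100
scale, and both blocks (20 amino acids, 61 sense codons) sum to 100 per
protein. All 61 codon columns are always emitted, zeros included, so feature
matrices from different cohorts align. Lowercase input and RNA U are
normalized to uppercase/T on ingest. Malformed CDSs (length not divisible by
3, ambiguous bases, internal stops) raise typed errors naming the offending
position rather than being silently skipped.

**GC3.** Two scopes are exposed. `all_codons` is the descriptive statistic:
the percent of sense codons ending in G or C. `tunable_only` removes Met
(ATG) and Trp (TGG) from numerator and denominator, because their wobble base
cannot be changed synonymously; this is the designer's target scale — without
the exclusion a 0% design would be unreachable for any Met/Trp-containing
protein, since both forced codons end in G. A Met/Trp-only protein has no
tunable codons and yields NaN, not an error.

**Synonymous subgroups.** The wobble analysis unit is the set of codons of
one amino acid sharing their first two nucleotides: 21 subgroups, with Leu,
Arg and Ser each contributing a pair and a quadruplet. Met and Trp belong to
no subgroup (they offer no synonymous contrast) but are still wobble-classed
(both G-ending). Every subgroup contains at least one G/C-ending and one
A/U-ending member, so the class contrast is always defined.

**Physicochemistry.** Molecular weight, isoelectric point (bisection on the
net-charge curve) and GRAVY (mean Kyte–Doolittle hydropathy) are computed by
Biopython's ProtParam port, whose pKa set is therefore the frozen reference.
The aliphatic index follows Ikai's mole-percent formula with relative
side-chain volumes 2.9 (Val) and 3.9 (Ile/Leu); a poly-Ala chain scores
exactly 100. The N-terminal identity is the residue at position 2 of the
translated protein — the residue exposed after initiator-Met processing —
with Met retained in the sequence; Met-cleavage itself is not modelled, as
its outcome is substrate-dependent and hard to predict.

**Feature tiers.** `composition` is exactly 81 columns. `sequence` adds the
3 × 81 structure-stratified composition blocks (helix/sheet/coil percentages
computed within each class; empty classes yield zero blocks and are flagged),
the five physicochemical scalars, and a 20-column one-hot of the N-terminal
residue. `all` appends binary annotation terms that mark at least 10 proteins
(configurable); rarer terms carry too little support for stable estimates.
Any feature identical to or trivially derived from the response being
predicted (e.g. `length` when predicting protein length) is dropped and
logged. Annotation matrices are generic term × protein indicators rather than
a reconstruction of any particular GO/PFAM release, which would be
database-version-dependent.

## Association screens

Responses are used as provided; an optional natural-log transform is exposed
because lifetime-like quantities are sometimes analysed on a log scale, but it
is off by default. Per-feature Pearson r is computed per dataset over the
id intersection (datasets sharing fewer than 3 proteins are skipped with a
warning) and aggregated as an unweighted mean with s.e.m. = sd/√n over
datasets — datasets are treated as exchangeable studies, not pooled, and no
sample-size weighting is applied. A pooled mode would conflate within- and
between-study variance in the error bars.

The wobble summary averages the per-dataset r over each subgroup's G/C-ending
members and over its A/U-ending members, then compares the two per-dataset
mean vectors with a two-sample Student's t-test (equal variances by default,
matching s.e.m.-over-datasets error bars; Welch available). With no planted
effect the GC-greater direction is a per-subgroup coin flip, so the expected
count is ≈ 10.5 of 21 — the suite checks this null behaviour as well as the
21/21 recovery under a planted effect.

Motif scans use point-biserial correlation (Pearson r against a 0/1 carrier
indicator) with Benjamini–Hochberg adjustment reported alongside raw p;
motifs present in all or no proteins are undefined (constant regressor) and
excluded from the adjustment. The N-end-rule check correlates a user-supplied
residue → stability table (the table is input data, not hard-coded) with the
response and reports r².

## Prediction harness

**Split.** A seeded permutation assigns 20% of ids (rounded) to a held-out
test set; the remaining 80% receives balanced fold labels (sizes differ by at
most one) independently for each of 10 repeats of 10-fold CV. One fold is 8%
of the total, giving the 72/8/20 train/CV/test proportions. Test ids never
enter tuning; `evaluate` asserts disjointness by id bookkeeping.

**Preprocessing.** Columns are centered and scaled using means/sds fit on the
training block only. The optional redundancy filter removes (in order)
zero-variance columns, near-zero-variance columns (frequency ratio > 19 and
unique fraction < 10%), columns that are exact linear combinations of earlier
ones (greedy rank test), and one member of each pair with |r| > 0.95 (the
member with the larger mean absolute correlation is dropped). All removals
are recorded on the fitted transform. On the planted cohorts, filtering on
vs off moves test RMSE by well under 10%.

**Learners and grids.** Three families: a random-forest regressor (captures
non-linearity; grid over `max_features` ∈ {sqrt, 0.33}, 200 trees by
default), an elastic net (grid over penalty strength 1e-4…1e-1 × l1 ratio
{0.2, 0.95}, Gram-precomputed), and an in-package greedy forward–backward
sparse linear learner (forward additions by residual-correlation, backward
deletions when removal costs less than ν = 0.5 of the last gain; capacity
grid k ∈ {1,…,64}). Hyperparameters minimise the mean RMSE over all
folds × repeats; ties break toward the simpler model (fewer features /
stronger penalty / smaller feature subsample), and an optional
one-standard-error rule picks the simplest model within one s.e. of the best
("tolerance" model). The winner is refit on the full train-CV block.

**Reporting.** Test metrics are RMSE and r² defined as the squared Pearson
correlation of predicted vs observed (the invariant r² = r² to machine
precision is asserted). `percent_of_max` = 100 · r²(model) / r²(inter-study),
rounded half away from zero for display with the raw value retained; the
inter-study r² is the reproducibility ceiling a model cannot be expected to
exceed.

**Importances.** Random-forest importances are the mean decrease in node
impurity. For the linear learners the raw importance is |mean coefficient| /
sd of the coefficient over 30 cross-validation refits on the train-CV block
(a t-statistic; the 30 refits leave out one of 30 disjoint folds each).
Importances are scaled 0–100 (top feature exactly 100 — the scaling is
invariant to any positive rescaling of the raw values) and may be summed over
amino-acid classes: small hydrophobic (A,I,L,V), negatively charged/polar
(D,E,N,Q), positively charged (K,R), potentially phosphorylated (S,T),
unusually shaped/bonded (P,W,C); codon features inherit the class of their
encoded amino acid, everything else falls in "other".

## Synonymous designer

The number of G/C-ending codons among the n tunable codons is
round(target/100 · n), half away from zero; the residual quantum (100/n %) is
the attainable resolution. Positions are chosen by a seeded uniform draw
(default) or evenly spaced; the seed is recorded on the variant. Within the
chosen wobble class the codon is the highest-weighted under an optional usage
table, falling back to the alphabetically first codon for determinism. The
designer may cross six-fold subgroup boundaries freely (e.g. Leu CTG vs TTA)
since only the wobble class is targeted. The stop codon (default TAA) is
excluded from all GC3 accounting. Every variant is auditable by an
independent per-codon scan that re-verifies translation identity — a mismatch
raises, as it can only be a designer bug. mRNA folding energy is not
computed; designed sequences can be exported for an external folding engine.

## Decay kinetics

The fitted model is I(t) = background + f₀ · exp(−(k_deg + k_div) · t), a
single exponential over a background with the division (dilution) rate adding
to degradation — label leaves the cell pool both ways. Fits are non-linear
least squares with all parameters constrained non-negative, initialised from
a log-linear slope estimate; non-convergence is flagged on the result, not
raised. Both t½ = ln2/k_deg (degradation-corrected) and the composite
ln2/(k_deg + k_div) are reported, labelled. A k_deg estimate at the
non-negativity boundary (< 1e-12/h) is reported as an infinite half-life
flag. The fit r² is 1 − SSres/SStot on intensities.

`k_div` is normally a supplied constant measured externally (e.g. from
nuclear counts); fitting it jointly from a single curve is possible but
poorly identified, since one curve constrains only the sum k_deg + k_div.
Likewise `background` can be fixed to a measured value (control wells):
leaving it free makes slow-decay fits over a finite chase window
ill-conditioned — with a 24 h chase and 5% noise, free-background fits of
sensors with multi-day half-lives show ~40% median t½ error, versus ~10% with
the background supplied. Replicate-mean intensities are fitted; weighting by
per-point s.e.m. is available but off by default, since s.e.m. estimates from
n = 3 wells are themselves noisy.

## Synthetic cohorts: what is and is not emulated

The generator exists so that every downstream stage has an input with known
ground truth. Its defaults encode the study conditions the analyses assume:

- **Cohort size** 2000 proteins of 50–300 residues (uniform lengths) for
  recovery tests; the association and prediction suites operate at this n.
- **Codon-usage heterogeneity**: each protein's codon distribution is a
  Dirichlet draw around a global usage table with concentration parameter α
  (default 20; smaller α → larger between-protein GC3 variance). The default
  global table is uniform within each synonymous family; a measured usage
  table (e.g. a species-specific one) can be supplied but is not shipped.
- **Planted responses**: a linear combination of composition features plus
  Gaussian noise calibrated so the explainable variance equals `target_r2`
  exactly in population (sd_noise = sd_signal·√((1−r²)/r²)); `target_r2 = 1`
  gives the noiseless signal, `target_r2 = 0` gives pure noise. The Gaussian
  error model is a choice — the measurement-error distribution of lifetime
  assays is not characterised here.
- **Replicate datasets** share one signal with independent noise at
  explainable fraction `replicate_r`, so any two replicates have expected
  pairwise Pearson r = `replicate_r` (closed form). The default 0.69 mirrors
  typical inter-study agreement for in-vivo lifetime datasets; eight
  replicates stand in for eight datasets from independent studies.
- **Wobble effect**: `wobble_effect_map(δ)` puts +δ on every G/C-ending and
  −δ on every A/U-ending codon percentage (default δ = 0.5 in the recovery
  suites), the planted analogue of G/C-ending codons tracking longer
  lifetimes.
- **Structures** are i.i.d. per-residue H/E/C draws at configurable
  proportions (default 35/20/45) — no spatial autocorrelation, no relation to
  the sequence. **Annotations** are terms marking exactly k random proteins —
  no co-occurrence structure.
- **Decay curves** are the fitted model plus Gaussian noise. The simulated
  experimental design is 9 time points over a 24 h chase
  (0,2,4,6,8,12,16,20,24 h), noise 5% of f₀, and sensor half-lives of 0.25–2
  days — half-lives beyond roughly twice the chase window are not resolvable
  from such an experiment and are excluded from the recovery grid.

Because the generator is this idealised, passing recovery tests demonstrate
that the estimators are correct and calibrated *under the planted model* —
linear signal, Gaussian noise, independent structures — not that real
proteomes satisfy those assumptions. In particular the generator makes no
attempt to mimic real codon-usage tables, gene-length distributions,
annotation co-occurrence, or the spatial statistics of secondary structure.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and derives all internal
randomness from it; equal seeds give byte-identical outputs (asserted for
cohorts, splits and CLI runs). The shipped suites use n = 2000 cohorts for
recovery, n = 5000 for the calibration-convergence check, 50-seed grids for
decay recovery, and small cohorts (n = 200–800) for structural checks —
sizes at which the sampling error of each tested quantity is comfortably
below the asserted tolerance.

## Known limitations

- Secondary structure is consumed, never predicted; degron motif lists and
  N-end-rule tables are user inputs, not curated resources.
- The harness's CV RMSE is an internal selection criterion; only test-set
  metrics should be quoted.
- The greedy forward–backward learner is a faithful but simple
  implementation; for p ≫ 10³ its per-step least-squares refits become the
  bottleneck.
- Joint (k_deg, k_div) fitting from one curve is structurally
  under-determined (see above); trust the split only when k_div is supplied.
- The elastic-net coefficient t-statistics from 30 refits understate
  uncertainty for strongly correlated features, as coefficients swap freely
  between collinear columns.
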