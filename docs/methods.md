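# Methods

## Profiles and the weighted cosine

Adverse-event reports are joined on their report ID from the quarterly
DRUG/REAC file pair (`$`-delimited with a header; delimiter and column
names are configurable because real layouts drifted across quarters).
Only drug entries with suspect roles PS or SS are kept — concomitant
(C) and interacting (I) medications say little about which drug caused
the event. Keywords are compared case-insensitively after whitespace
trimming. A keyword's frequency d_k is the fraction of all retained
reports mentioning it; keywords with d_k above `max_freq` (default
0.001) or appearing in fewer than `min_reports` reports (default 5) are
dropped. Both the frequency denominator and the mean σ are computed
after role filtering and after keyword filtering respectively; the
alternative orderings are possible but change little at realistic
scales.

The AERS-freq profile codes, per drug, the fraction of that drug's
reports mentioning each keyword (drug-conditional denominator; a
global-denominator variant is available). Conditioning on the drug
makes profiles comparable between blockbuster drugs with thousands of
reports and niche drugs with dozens. AERS-bit codes presence/absence.

The weight function w_k = exp(−d_k²/(hσ)²) is one concrete member of
the family "smooth, positive, strictly decreasing in d_k, scaled by the
mean frequency σ with bandwidth h" (h defaults to 1). It is pluggable
(`keyword_weights(form=...)`) so alternatives with the same qualitative
behaviour can be swapped in. Profiles with zero weighted norm (drugs
whose every keyword was filtered) get similarity 0 to everything,
including themselves — the same convention used for drugs missing from
a data source entirely, whose kernel rows are zeroed when matrices are
aligned onto an entity union.

## Surrogate chemical and sequence kernels

Chemical similarity is the Tanimoto coefficient on binary
fingerprints; sequence similarity is the Smith–Waterman local alignment
score normalized as SW(a,b)/√(SW(a,a)·SW(b,b)) (BLOSUM62, gap open 11,
extend 1 by default; the scheme is recorded in the output metadata).
Alignment scores are computed with Biopython's `PairwiseAligner`; the
test suite checks them against an independent affine-gap Gotoh dynamic
program. Both kernels sit behind the same `SimilarityMatrix` type as
the pharmacological kernel, and precomputed matrices from external
tools can be loaded from TSV instead.

## Pairwise kernel regression

The interaction label matrix Z holds 1 for known pairs and 0 for
unknown or held-out pairs (held-out positives are explicitly forced to
0 during training). The unregularized weights B = K_x⁻¹ Z K_y⁻¹ are
computed by two symmetric positive-definite solves (Cholesky), never by
explicit inversion; `condition_kernel` adds a diagonal jitter (default
1e-6) and can also shift an indefinite spectrum, making the solve
well-posed for rank-deficient similarity matrices. The low-rank variant
replaces Z by its rank-q SVD truncation before solving.

Two identities pin the implementation down numerically: (i) on
positive-definite kernels the unregularized fit reconstructs Z to
machine precision, and (ii) predictions agree with an explicit
least-squares model on the (n_x n_y) × (n_x n_y) tensor-product kernel
— the factorization that makes the method tractable at scale. Both are
exercised on randomized instances in the tests and the acceptance
script.

Exact reconstruction has a practical consequence: in pair-wise
cross-validation the in-sample score of a masked pair is exactly its
masked label (0), so the unregularized model cannot generalize to held-
out pairs at all. Rank regularization is therefore not a luxury but the
mechanism of generalization there — rank-q truncation of the masked Z
fills the held-out entries from the low-rank interaction structure.
The rank q is tuned per fold by AUC on a nested validation split (a
third of the training pairs, or of the training drugs in the
block-wise design) over a roughly logarithmic grid capped at the full
rank. Fixed-q runs are supported (`run_cv(q=...)`) and every tuned run
records its configuration.

## Cross-validation designs

Pair-wise CV partitions the full drug × target grid into folds of
near-equal size; test positives are masked to 0 in the training labels,
the model is fitted on the full kernels, and test pairs are scored and
labelled by gold-standard membership (non-gold pairs count as
negatives). Block-wise CV partitions drugs; the model is trained on the
training drugs' kernel submatrix and a held-out drug is scored through
its kernel row against the training drugs, so no information about the
test drugs' interactions is available. Per-fold AUC/AUPR are averaged
within a repeat (pooling across folds is available as an option), and
means and SDs are reported over repeats, each repeat drawing fresh
folds from a seeded substream of the master seed. AUC is the
Mann–Whitney rank statistic with ties counted one half; AUPR is the
non-interpolated descending-score sweep (equal to average precision),
with tied scores processed as one block so the value is
permutation-invariant.

## Single-linkage representative selection

Benchmark gold standards contain families of near-identical derivative
drugs; splitting twins across folds makes prediction trivially easy.
Cutting the single-linkage dendrogram at similarity t is exactly the
connected components of the graph with edges where similarity is
strictly greater than t, which is how the partition is computed
(scipy's sparse connected components; an independent BFS traversal
serves as the test oracle). One representative per cluster is drawn
uniformly with a seeded generator that depends only on the sorted
cluster membership, so results are invariant to input order. Sweeping
t over 0.1–1.0 in steps of 0.1 gives nested partitions, hence
non-decreasing representative counts.

## The synthetic world

The generator emulates the statistical structure the method exploits —
drugs sharing targets share side-effect spectra, similar proteins bind
similar ligands — at a desk scale where everything is checkable against
retained ground truth. Defaults: 5 drug classes × 8 drugs, 4 target
families × 5 targets (so one family serves two classes and the
interaction matrix has rank 4), 2000 keywords, 50 reports per drug,
world seed 42.

Each report names one primary-suspect drug (with occasional SS
classmates and C/I co-medications to exercise the role filter) and
draws keywords from a three-component mixture: with probability 0.8 a
class-independent shared pool of 200 common adverse events with
heavy-tailed popularity, with probability 0.15 the drug's 12 private
idiosyncratic keywords, otherwise the class's 40-keyword signature, on
top of a sparse power-law background over the whole vocabulary. The
dominance of common, class-independent symptoms mirrors real
spontaneous-report data — it is exactly the regime the rarity weight
w_k is designed for — and is what makes the block-wise task genuinely
harder than the pair-wise one: a held-out drug's kernel row is ambiguous
while a held-out pair can still lean on its drug's other interactions.
The mixture also drives both keyword-filter branches on the generator's
scaled thresholds (`max_freq` 0.05, `min_reports` 5 at ~2000 reports):
the production-scale defaults 0.001/5 assume millions of reports and would
empty a desk-scale vocabulary, so the world carries its own filter
settings chosen once to fire both removal rules.

Interactions link each drug to each target of its class's assigned
family independently with probability `class_target_fidelity` (default
0.95); fidelity 1 yields an exactly block-structured matrix, and no
off-block edges are generated. Fingerprints combine a common bit block,
a class-specific block and per-drug noise flips sized to hit the
configured within/between Tanimoto bands approximately; protein family
members are per-site mutated copies (rate 0.05) of a family ancestor of
length 300. Degree-preserving label shuffling (repeated double-edge
swaps) provides the permutation null. Everything is a deterministic
function of the seed, including byte-identical fixture files.

What passing tests on this world do **not** show: robustness to
duplicate or mis-attributed reports, MedDRA-style keyword synonymy,
drug-name ambiguity, reporting biases over time, or realistic report
volumes — none of which the generator attempts to model.

One known property of the degree-preserving null is worth noting: with
five classes on four families, one family's targets retain about twice
the degree of the others after rewiring, so target popularity alone
carries some signal (a pure popularity scorer reaches AUC ≈ 0.62 on
the null). The fitted model exploits this only weakly (shuffled-label
AUCs stay within 0.05 of 0.5 in both CV designs), but a perfectly
popularity-calibrated scorer would not.

## Numerical choices and limitations

* Kernels are conditioned with jitter 1e-6 by default; raise it if a
  Cholesky failure is reported.
* Ranked prediction lists break score ties lexicographically by
  (drug_id, target_id) for deterministic output. Report thresholds are
  configurable as absolute scores or score quantiles; with 0/1 labels
  the score scale is data-dependent, so quantiles are the safer
  default.
* Problem sizes in the shipped experiments (40 × 20 grid, 2000 reports,
  3-fold CV × 5 repeats) were chosen so the full pipeline and its
  cross-checks run in seconds; all components scale to thousands of
  entities, where kernel assembly (O(n²) alignments) dominates.
* No duplicate-report deduplication, disproportionality statistics
  (PRR/ROR), probabilistic score calibration, or alternative learners
  are included.
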