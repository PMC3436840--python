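# pharmlink

Predicting drug–target interactions from adverse-event side-effect
profiles with pairwise kernel regression.

## The problem

Most drugs bind proteins besides their intended target, and those
off-targets drive both side effects and drug-repositioning
opportunities. For thousands of marketed drugs no target is known at
all. Spontaneous adverse-event reporting systems (the FDA's AERS/FAERS)
record which side effects co-occur with which drugs at a scale no
curated package-insert resource matches — and drugs that share targets
tend to share side-effect spectra. `pharmlink` turns raw quarterly
report files into drug side-effect profiles, measures drug–drug
pharmacological similarity with a rarity-weighted cosine, and predicts
unknown drug–target interactions by regression on the tensor-product
kernel of a drug similarity and a protein sequence similarity.

## The model

Each drug is a profile **x** = (x₁,…,x_K)ᵀ over K retained side-effect
keywords (frequency-valued, "AERS-freq", or binary, "AERS-bit").
Keywords appearing in more than 0.1 % of reports or fewer than 5
reports are removed. Pharmacological similarity is the weighted cosine

    s(x, x′) = Σₖ wₖ xₖ x′ₖ / (√(Σₖ wₖ xₖ²) √(Σₖ wₖ x′ₖ²)),
    wₖ = exp(−dₖ² / (h σ)²),

where dₖ is keyword k's reporting frequency, σ the mean frequency over
retained keywords and h a bandwidth (default 1): rare keywords (variant
angina, aspergillosis) say more about a drug than ubiquitous ones
(nausea, dizziness) and are weighted up.

A drug–target pair (x, y) is scored by pairwise kernel regression (PKR):

    f(x, y) = Σᵢⱼ βᵢⱼ k_x(x, xᵢ) k_y(y, yⱼ)

with k_x a drug kernel (pharmacological, chemical Tanimoto, or their
sum) and k_y a normalized Smith–Waterman protein kernel. Because the
pairwise kernel factorizes, the nₓn_y weights fold into a matrix B with
the closed form

    B = K_x⁻¹ Z K_y⁻¹,

Z being the 0/1 interaction matrix — no (nₓn_y)×(nₓn_y) pairwise kernel
is ever built. Replacing Z by its rank-q SVD truncation U_q D_q V_qᵀ
regularizes the fit; q is tuned by AUC on nested validation splits.
Evaluation uses 3-fold cross-validation in two designs: **pair-wise**
(split pairs; simulates finding extra targets of known drugs) and
**block-wise** (split drugs; simulates drugs with no known target — much
harder), with single-linkage clustering of chemically similar drugs to
select diverse representatives.

## Worked example

```python
from pharmlink import (
    WorldSpec, generate_world, filter_suspect_drugs, build_vocabulary,
    build_profiles, pharm_similarity_matrix, seq_similarity_matrix, run_cv,
    CVPlan,
)
from pharmlink.similarity import align_to
from pharmlink.evaluation import default_q_grid

truth = generate_world(WorldSpec())          # synthetic AERS-like world
reports = filter_suspect_drugs(truth.reports)  # keep PS/SS drug entries
vocab = build_vocabulary(reports, max_freq=0.05, min_reports=5)
profiles = build_profiles(reports, vocab, mode="freq")
Kx = align_to(pharm_similarity_matrix(profiles, vocab), truth.drug_ids)
Ky = seq_similarity_matrix(sorted(truth.sequences.items()))
grid = default_q_grid(Kx.n, Ky.n)
pw = run_cv(Kx, Ky, truth.interactions, CVPlan("pairwise", 3, 5, seed=11), q_grid=grid)
bw = run_cv(Kx, Ky, truth.interactions, CVPlan("blockwise", 3, 5, seed=11), q_grid=grid)
print(f"pair-wise  AUC {pw.mean_auc:.3f} (SD {pw.sd_auc:.3f})")
print(f"block-wise AUC {bw.mean_auc:.3f} (SD {bw.sd_auc:.3f})")
```

prints

```
pair-wise  AUC 0.973 (SD 0.021)
block-wise AUC 0.941 (SD 0.014)
```

Pair-wise CV scores high because a held-out pair's drug still has other
known targets anchoring its row of Z; block-wise CV is harder because
the model knows nothing about a held-out drug beyond its kernel row, so
its score reflects how well side-effect similarity alone identifies the
right target family.

The same pipeline is scriptable from the shell:

```
pharmlink simulate --seed 42 --out fixtures/
pharmlink cv --method AERS-freq --gold fixtures/gold_standard.tsv \
    --drug-files fixtures/DRUG10Q1.TXT --reac-files fixtures/REAC10Q1.TXT \
    ... --sequences fixtures/targets.fasta --max-freq 0.05 --out run/
```

Seven method selectors mirror the kernel configurations: `AERS-freq`,
`AERS-bit`, `SIDER`, `JAPIC`, `CHEM`, `INTEG-P` (sum of the
pharmacological kernels) and `INTEG-PC` (additionally the chemical
kernel).

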