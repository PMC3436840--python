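"""Cross-validation designs and ranking metrics for bipartite link prediction.

Two CV schemes mirror the two practical drug-target identification
settings:

* pair-wise CV splits individual drug-target pairs into folds -- it
  simulates finding *additional* targets of drugs that already have some
  known targets (held-out positives' labels are masked to 0 at training
  time, but the drug's other interactions remain visible);
* block-wise CV splits *drugs* into folds -- the test set is every pair of
  a held-out drug with every target, so the model sees nothing about the
  test drugs.  This is the harder, more realistic setting for drugs with
  no known targets, and AUCs here are systematically lower.

Scores are summarized by the area under the ROC curve (Mann-Whitney
rank form, ties counted half) and the area under the precision-recall
curve (non-interpolated descending-score sweep).  Pairs absent from the
gold standard are treated as negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from pharmlink.pkr import PairwiseKernelRegression, build_label_matrix
from pharmlink.similarity import SimilarityMatrix, condition_kernel

Pair = tuple[str, str]


@dataclass
class CVPlan:
    scheme: str = "pairwise"
    n_folds: int = 3
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("pairwise", "blockwise"):
            raise ValueError("scheme must be 'pairwise' or 'blockwise'")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CVResult:
    """Per-fold/per-repeat AUC and AUPR with summary statistics."""

    plan: CVPlan
    fold_auc: list[list[float]]  # [repeat][fold]
    fold_aupr: list[list[float]]
    repeat_auc: list[float] = field(default_factory=list)
    repeat_aupr: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.repeat_auc:
            self.repeat_auc = [float(np.mean(r)) for r in self.fold_auc]
        if not self.repeat_aupr:
            self.repeat_aupr = [float(np.mean(r)) for r in self.fold_aupr]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.repeat_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.repeat_auc, ddof=0))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.repeat_aupr))

    @property
    def sd_aupr(self) -> float:
        return float(np.std(self.repeat_aupr, ddof=0))

    def to_dict(self) -> dict:
        return {
            "scheme": self.plan.scheme,
            "n_folds": self.plan.n_folds,
            "n_repeats": self.plan.n_repeats,
            "seed": self.plan.seed,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_aupr": self.mean_aupr,
            "sd_aupr": self.sd_aupr,
            "repeat_auc": self.repeat_auc,
            "repeat_aupr": self.repeat_aupr,
        }


def auc(scores, labels) -> float:
    """Rank-based ROC AUC (Mann-Whitney U / (n+ n-)), ties counted 0.5.

    1 means every positive outranks every negative; 0.5 is chance level.
    Raises on single-class input, where the AUC is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve (non-interpolated).

    Sweeps thresholds down the score ranking and accumulates
    precision * delta-recall; equals average precision.  Ties in score are
    processed as one block so the result is permutation-invariant.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPR undefined: no positive labels")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    area = 0.0
    tp = 0
    seen = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        block_pos = int(y[i:j].sum())
        tp += block_pos
        seen += j - i
        if block_pos:
            area += (tp / seen) * (block_pos / n_pos)
        i = j
    return float(area)


def split_pairwise(
    pairs: list[Pair], n_folds: int, rng: np.random.Generator
) -> list[list[Pair]]:
    """Randomly partition pairs into folds of sizes differing by <= 1."""
    if len(pairs) < n_folds:
        raise ValueError(f"need at least {n_folds} pairs, got {len(pairs)}")
    pairs = sorted(pairs)  # order-independence before shuffling
    perm = rng.permutation(len(pairs))
    folds: list[list[Pair]] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(perm):
        folds[pos % n_folds].append(pairs[idx])
    return folds


def split_blockwise(
    drugs: list[str], n_folds: int, rng: np.random.Generator
) -> list[list[str]]:
    """Randomly partition drugs into folds of sizes differing by <= 1."""
    if len(drugs) < n_folds:
        raise ValueError(f"need at least {n_folds} drugs, got {len(drugs)}")
    drugs = sorted(drugs)
    perm = rng.permutation(len(drugs))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(perm):
        folds[pos % n_folds].append(drugs[idx])
    return folds


def _tune_q_pairwise(
    Kx, Ky, gold_set, drug_ids, target_ids, test_pairs, q_grid, rng
) -> int:
    """Pick q by AUC on an inner validation split of the training pairs."""
    test_set = set(test_pairs)
    train_pairs = [
        (d, t) for d in drug_ids for t in target_ids if (d, t) not in test_set
    ]
    perm = rng.permutation(len(train_pairs))
    inner = [train_pairs[i] for i in perm[: len(train_pairs) // 3]]
    labels = build_label_matrix(
        gold_set, drug_ids, target_ids, test_mask=list(test_set) + inner
    )
    model = PairwiseKernelRegression(Kx, Ky, labels)
    di = {d: i for i, d in enumerate(drug_ids)}
    ti = {t: j for j, t in enumerate(target_ids)}
    y = np.array([1 if p in gold_set else 0 for p in inner])
    if y.sum() == 0 or y.sum() == y.size:
        return q_grid[-1]
    best_q, best_auc = q_grid[0], -np.inf
    for q in q_grid:
        F = model.fit(q=q).fittedvalues
        s = np.array([F[di[d], ti[t]] for d, t in inner])
        a = auc(s, y)
        if a > best_auc:
            best_q, best_auc = q, a
    return best_q


def _tune_q_blockwise(
    Kx, Ky, gold_set, train_drugs, target_ids, q_grid, rng
) -> int:
    """Pick q by AUC on an inner held-out drug subset of the training fold."""
    perm = rng.permutation(len(train_drugs))
    inner_drugs = [train_drugs[i] for i in perm[: max(1, len(train_drugs) // 3)]]
    core_drugs = [d for d in train_drugs if d not in set(inner_drugs)]
    if not core_drugs:
        return q_grid[-1]
    Kx_core = Kx.submatrix(core_drugs)
    core_gold = {p for p in gold_set if p[0] in set(core_drugs)}
    labels = build_label_matrix(core_gold, core_drugs, target_ids)
    model = PairwiseKernelRegression(Kx_core, Ky, labels)
    pos = {d: i for i, d in enumerate(Kx.entity_ids)}
    kx_new = Kx.values[np.ix_([pos[d] for d in inner_drugs], [pos[d] for d in core_drugs])]
    y = np.array(
        [1 if (d, t) in gold_set else 0 for d in inner_drugs for t in target_ids]
    )
    if y.sum() == 0 or y.sum() == y.size:
        return q_grid[-1]
    full = min(len(core_drugs), len(target_ids))
    best_q, best_auc = q_grid[0], -np.inf
    for q in q_grid:
        q = min(q, full)
        s = model.fit(q=q).predict(kx_new=kx_new, ky_new=Ky.values).ravel()
        a = auc(s, y)
        if a > best_auc:
            best_q, best_auc = q, a
    return best_q


def default_q_grid(n_x: int, n_y: int) -> list[int]:
    """Roughly logarithmic rank grid up to the full rank."""
    full = min(n_x, n_y)
    grid = sorted({1, 2, 3, 4, 6, 8, 12, 16, 24, 32, full})
    return [q for q in grid if q <= full]


def run_cv(
    K_x: SimilarityMatrix,
    K_y: SimilarityMatrix,
    gold: list[Pair],
    plan: CVPlan,
    q: int | None = None,
    q_grid: list[int] | None = None,
    jitter: float = 1e-6,
    pool_folds: bool = False,
) -> CVResult:
    """Run repeated k-fold CV of the PKR model and report AUC/AUPR.

    Pair-wise scheme: the full drug x target grid is split by pair; test
    positives are masked to 0 in the training label matrix, the model is
    fitted on the full kernels, and the test-fold pairs are scored and
    labelled by gold-standard membership.

    Block-wise scheme: drugs are split; the model is trained on the
    training drugs' kernel submatrix (full target kernel) and test drugs
    are scored via their kernel rows against the training drugs.

    The SVD rank may be fixed (``q``) or tuned per fold over ``q_grid`` by
    AUC on a nested validation split of the training data (the objective
    the method's parameters are meant to be optimized with); ``q`` and
    ``q_grid`` are mutually exclusive.

    By default per-fold AUCs are averaged within a repeat; with
    ``pool_folds=True`` scores from all folds of a repeat are pooled into
    one ranking first.
    """
    if q is not None and q_grid is not None:
        raise ValueError("pass either q or q_grid, not both")
    drug_ids = list(K_x.entity_ids)
    target_ids = list(K_y.entity_ids)
    gold_set = set(gold)
    missing = [p for p in gold_set if p[0] not in set(drug_ids) or p[1] not in set(target_ids)]
    if missing:
        raise KeyError(f"gold pairs reference unknown entities: {missing[:3]}")
    Kx = condition_kernel(K_x, jitter)
    Ky = condition_kernel(K_y, jitter)

    master = np.random.default_rng(plan.seed)
    fold_auc: list[list[float]] = []
    fold_aupr: list[list[float]] = []
    for _ in range(plan.n_repeats):
        rng = np.random.default_rng(master.integers(2**31))
        if plan.scheme == "pairwise":
            all_pairs = [(d, t) for d in drug_ids for t in target_ids]
            folds = split_pairwise(all_pairs, plan.n_folds, rng)
            aucs, auprs, pooled_s, pooled_y = [], [], [], []
            for test_pairs in folds:
                q_fold = q
                if q_grid is not None:
                    q_fold = _tune_q_pairwise(
                        Kx, Ky, gold_set, drug_ids, target_ids,
                        test_pairs, q_grid, rng,
                    )
                labels = build_label_matrix(
                    gold_set, drug_ids, target_ids, test_mask=test_pairs
                )
                res = PairwiseKernelRegression(Kx, Ky, labels).fit(q=q_fold)
                F = res.fittedvalues
                di = {d: i for i, d in enumerate(drug_ids)}
                ti = {t: j for j, t in enumerate(target_ids)}
                s = np.array([F[di[d], ti[t]] for d, t in test_pairs])
                y = np.array([1 if p in gold_set else 0 for p in test_pairs])
                if pool_folds:
                    pooled_s.append(s)
                    pooled_y.append(y)
                else:
                    aucs.append(auc(s, y))
                    auprs.append(aupr(s, y))
            if pool_folds:
                s = np.concatenate(pooled_s)
                y = np.concatenate(pooled_y)
                aucs = [auc(s, y)]
                auprs = [aupr(s, y)]
        else:
            folds = split_blockwise(drug_ids, plan.n_folds, rng)
            aucs, auprs, pooled_s, pooled_y = [], [], [], []
            for test_drugs in folds:
                train_drugs = [d for d in drug_ids if d not in set(test_drugs)]
                q_fold = q
                if q_grid is not None:
                    q_fold = _tune_q_blockwise(
                        Kx, Ky, gold_set, train_drugs, target_ids, q_grid, rng
                    )
                Kx_tr = Kx.submatrix(train_drugs)
                train_gold = {p for p in gold_set if p[0] in set(train_drugs)}
                labels = build_label_matrix(train_gold, train_drugs, target_ids)
                if q_fold is not None:
                    q_fold = min(q_fold, len(train_drugs), len(target_ids))
                res = PairwiseKernelRegression(Kx_tr, Ky, labels).fit(q=q_fold)
                pos = {d: i for i, d in enumerate(Kx.entity_ids)}
                tr_idx = [pos[d] for d in train_drugs]
                te_idx = [pos[d] for d in test_drugs]
                kx_new = Kx.values[np.ix_(te_idx, tr_idx)]
                F = res.predict(kx_new=kx_new, ky_new=Ky.values)
                s = F.ravel()
                y = np.array(
                    [
                        1 if (d, t) in gold_set else 0
                        for d in test_drugs
                        for t in target_ids
                    ]
                )
                if y.sum() == 0 or y.sum() == y.size:
                    continue  # fold has a single class; AUC undefined
                if pool_folds:
                    pooled_s.append(s)
                    pooled_y.append(y)
                else:
                    aucs.append(auc(s, y))
                    auprs.append(aupr(s, y))
            if pool_folds:
                s = np.concatenate(pooled_s)
                y = np.concatenate(pooled_y)
                aucs = [auc(s, y)]
                auprs = [aupr(s, y)]
        fold_auc.append(aucs)
        fold_aupr.append(auprs)
    return CVResult(plan, fold_auc, fold_aupr)
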