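"""Pairwise kernel regression (PKR) for bipartite drug-target link prediction.

The model scores a drug-target pair (x, y) as

    f(x, y) = sum_ij beta_ij k_x(x, x_i) k_y(y, y_j),

i.e. a regression on the tensor-product kernel k((x,y),(x',y')) =
k_x(x,x') * k_y(y,y').  Because the pairwise kernel factorizes, the
n_x*n_y weight vector folds into an n_x x n_y matrix B and the
least-squares solution has the closed form

    B = K_x^{-1} Z K_y^{-1},

with Z the 0/1 interaction label matrix (known pairs 1, everything else --
including pairs held out for prediction -- 0).  This avoids ever building
the (n_x*n_y) x (n_x*n_y) pairwise kernel.  A low-rank variant replaces Z
by its rank-q SVD truncation U_q D_q V_q^T, which regularizes the fit.

The module follows the Model/Results convention: build a
:class:`PairwiseKernelRegression` from two kernels and a label matrix,
call ``fit()`` (or ``fit_regularized(q)``), and use the returned
:class:`PKRResults` to predict scores for new drugs/targets via their
kernel rows against the training entities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import linalg

from pharmlink.similarity import SimilarityMatrix

Pair = tuple[str, str]


@dataclass
class InteractionLabels:
    """Label matrix Z over the drug x target grid.

    z_ij = 1 for known interacting pairs in the training region and 0
    everywhere else; pairs listed in ``test_mask`` are forced to 0 even if
    they are known interactions (this is how held-out pairs enter the
    learning stage).
    """

    drug_ids: list[str]
    target_ids: list[str]
    Z: np.ndarray
    known_pairs: set[Pair] = field(default_factory=set)
    test_mask: set[Pair] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError("Z shape does not match id lists")


def build_label_matrix(
    E_plus: Iterable[Pair],
    drug_ids: Sequence[str],
    target_ids: Sequence[str],
    test_mask: Iterable[Pair] = (),
    label_scale: float = 1.0,
) -> InteractionLabels:
    """Build Z with z_ij = label_scale for training positives, 0 elsewhere."""
    di = {d: i for i, d in enumerate(drug_ids)}
    ti = {t: j for j, t in enumerate(target_ids)}
    E_plus = set(E_plus)
    mask = set(test_mask)
    Z = np.zeros((len(drug_ids), len(target_ids)))
    for d, t in E_plus:
        if d not in di or t not in ti:
            raise KeyError(f"unknown entity in pair ({d!r}, {t!r})")
        Z[di[d], ti[t]] = label_scale
    for d, t in mask:
        if d not in di or t not in ti:
            raise KeyError(f"unknown entity in test_mask pair ({d!r}, {t!r})")
        Z[di[d], ti[t]] = 0.0
    return InteractionLabels(list(drug_ids), list(target_ids), Z, E_plus, mask)


def _as_kernel(K, ids=None):
    if isinstance(K, SimilarityMatrix):
        return K.values, list(K.entity_ids)
    K = np.asarray(K, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(K.shape[0])]
    return K, list(ids)


class PairwiseKernelRegression:
    """PKR model over a drug kernel, a target kernel and interaction labels.

    Parameters
    ----------
    K_x : SimilarityMatrix or (n_x, n_x) array
        Drug-side kernel; must be positive definite (apply
        :func:`pharmlink.similarity.condition_kernel` upstream if needed).
    K_y : SimilarityMatrix or (n_y, n_y) array
        Target-side kernel, same requirement.
    labels : InteractionLabels
        The 0/1 (or scaled) interaction matrix with its entity orders.
    """

    def __init__(self, K_x, K_y, labels: InteractionLabels):
        Kx, dx = _as_kernel(K_x, labels.drug_ids)
        Ky, dy = _as_kernel(K_y, labels.target_ids)
        if dx != labels.drug_ids or dy != labels.target_ids:
            raise ValueError("kernel entity order does not match labels")
        if Kx.shape[0] != len(labels.drug_ids):
            raise ValueError("K_x size does not match drug count")
        if Ky.shape[0] != len(labels.target_ids):
            raise ValueError("K_y size does not match target count")
        self.K_x = Kx
        self.K_y = Ky
        self.labels = labels
        self.drug_ids = list(labels.drug_ids)
        self.target_ids = list(labels.target_ids)
        self.n_x = len(self.drug_ids)
        self.n_y = len(self.target_ids)

    def _factorize(self):
        try:
            cx = linalg.cho_factor(self.K_x)
            cy = linalg.cho_factor(self.K_y)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "kernel matrix is not positive definite; condition it with "
                "a larger jitter (see condition_kernel)"
            ) from exc
        return cx, cy

    def fit(self, q: int | None = None) -> "PKRResults":
        """Solve B = K_x^{-1} Z K_y^{-1} (rank-q truncated Z when q given).

        Uses two symmetric positive-definite solves, never explicit
        inversion.  ``q = min(n_x, n_y)`` (or None) is the unregularized
        fit.
        """
        full = min(self.n_x, self.n_y)
        if q is None:
            q = full
        if not 1 <= q <= full:
            raise ValueError(f"q must be in [1, {full}], got {q}")
        Z = self.labels.Z
        if q < full:
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            Z = (U[:, :q] * s[:q]) @ Vt[:q]
        cx, cy = self._factorize()
        # B = K_x^{-1} Z K_y^{-1}: solve K_x A = Z, then K_y B^T = A^T
        A = linalg.cho_solve(cx, Z)
        B = linalg.cho_solve(cy, A.T).T
        return PKRResults(self, B, q)

    def fit_regularized(self, q: int) -> "PKRResults":
        """SVD-regularized fit; alias for ``fit(q=q)``."""
        return self.fit(q=q)


class PKRResults:
    """Fitted PKR weights with prediction and reporting helpers."""

    def __init__(self, model: PairwiseKernelRegression, B: np.ndarray, q: int):
        self.model = model
        self.B = B
        self.q = q

    @property
    def fittedvalues(self) -> np.ndarray:
        """In-sample score matrix K_x B K_y."""
        return self.model.K_x @ self.B @ self.model.K_y

    @property
    def resid(self) -> np.ndarray:
        return self.model.labels.Z - self.fittedvalues

    def predict(
        self,
        kx_new: np.ndarray | None = None,
        ky_new: np.ndarray | None = None,
    ) -> np.ndarray:
        """Score query pairs: f = kx_new B ky_new^T.

        ``kx_new`` holds, per query drug, its kernel values against the
        n_x training drugs in training order (``ky_new`` likewise for
        targets).  Defaults to the training kernels, i.e. in-sample scores.
        A query entity with an all-zero kernel row (no source data) scores
        0 against everything.
        """
        kx_new = self.model.K_x if kx_new is None else np.atleast_2d(kx_new)
        ky_new = self.model.K_y if ky_new is None else np.atleast_2d(ky_new)
        if kx_new.shape[1] != self.model.n_x:
            raise ValueError(
                f"kx_new must have {self.model.n_x} columns aligned to the "
                "training drug order"
            )
        if ky_new.shape[1] != self.model.n_y:
            raise ValueError(
                f"ky_new must have {self.model.n_y} columns aligned to the "
                "training target order"
            )
        return kx_new @ self.B @ ky_new.T

    def rank_predictions(
        self,
        threshold: float,
        scores: np.ndarray | None = None,
        drug_ids: Sequence[str] | None = None,
        target_ids: Sequence[str] | None = None,
        known: set[Pair] | None = None,
    ) -> list[tuple[str, str, float]]:
        """Novel pairs scoring at or above ``threshold``, best first."""
        if scores is None:
            scores = self.fittedvalues
        drug_ids = self.model.drug_ids if drug_ids is None else list(drug_ids)
        target_ids = self.model.target_ids if target_ids is None else list(target_ids)
        known = self.model.labels.known_pairs if known is None else known
        return rank_predictions(scores, drug_ids, target_ids, known, threshold)

    def summary(self) -> str:
        Z = self.model.labels.Z
        recon = np.abs(Z - self.fittedvalues).max() if Z.size else 0.0
        lines = [
            "Pairwise Kernel Regression Results",
            "=" * 44,
            f"n drugs (n_x):        {self.model.n_x}",
            f"n targets (n_y):      {self.model.n_y}",
            f"known interactions:   {len(self.model.labels.known_pairs)}",
            f"rank q:               {self.q}"
            + ("  (unregularized)" if self.q == min(self.model.n_x, self.model.n_y) else ""),
            f"max |Z - KxBKy|:      {recon:.3e}",
            f"|B|_F:                {np.linalg.norm(self.B):.6g}",
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Serialize the fitted model: B as TSV plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "B.tsv", "w") as fh:
            fh.write("drug_id\t" + "\t".join(self.model.target_ids) + "\n")
            for did, row in zip(self.model.drug_ids, self.B):
                fh.write(did + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")
        np.savetxt(out / "K_x.tsv", self.model.K_x, delimiter="\t")
        np.savetxt(out / "K_y.tsv", self.model.K_y, delimiter="\t")
        manifest = {
            "q": self.q,
            "drug_ids": self.model.drug_ids,
            "target_ids": self.model.target_ids,
            "known_pairs": sorted(map(list, self.model.labels.known_pairs)),
        }
        with open(out / "model.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, out_dir: str | Path) -> "PKRResults":
        out = Path(out_dir)
        with open(out / "model.json") as fh:
            manifest = json.load(fh)
        drug_ids = manifest["drug_ids"]
        target_ids = manifest["target_ids"]
        B = []
        with open(out / "B.tsv") as fh:
            fh.readline()
            for line in fh:
                B.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
        B = np.array(B)
        K_x = np.loadtxt(out / "K_x.tsv", delimiter="\t", ndmin=2)
        K_y = np.loadtxt(out / "K_y.tsv", delimiter="\t", ndmin=2)
        known = {tuple(p) for p in manifest["known_pairs"]}
        labels = build_label_matrix(known, drug_ids, target_ids)
        model = PairwiseKernelRegression(K_x, K_y, labels)
        return cls(model, B, manifest["q"])


def rank_predictions(
    scores: np.ndarray,
    drug_ids: Sequence[str],
    target_ids: Sequence[str],
    known: set[Pair],
    threshold: float,
) -> list[tuple[str, str, float]]:
    """Non-known pairs with score >= threshold, sorted descending by score.

    Ties are broken lexicographically by (drug_id, target_id) so output is
    deterministic.
    """
    scores = np.asarray(scores)
    out = []
    for i, d in enumerate(drug_ids):
        for j, t in enumerate(target_ids):
            s = float(scores[i, j])
            if (d, t) not in known and s >= threshold:
                out.append((d, t, s))
    out.sort(key=lambda r: (-r[2], r[0], r[1]))
    return out
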