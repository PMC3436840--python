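"""Similarity kernels over drugs and proteins.

The pharmacological similarity between two drugs is the weighted cosine
correlation of their side-effect profiles,

    s(x, x') = sum_k w_k x_k x'_k /
               (sqrt(sum_k w_k x_k^2) * sqrt(sum_k w_k x'_k^2)),

where the keyword weight w_k = exp(-d_k^2 / (h * sigma)^2) down-weights
common keywords (nausea, dizziness, ...) in favour of rare, more
informative ones; d_k is the keyword's reporting frequency, sigma the mean
frequency over retained keywords and h a bandwidth parameter (default 1).

Chemical similarity is the Tanimoto coefficient over binary fingerprints
and genomic sequence similarity a normalized Smith-Waterman score
SW(a,b) / sqrt(SW(a,a) * SW(b,b)); both are pluggable surrogates behind a
common matrix type, so precomputed kernels from external tools can be
loaded from TSV instead.  Integrated kernels are entrywise sums after
aligning each component to the entity union, with zero rows/columns for
entities a source knows nothing about (the standard missing-data
convention: an unknown drug is similar to nothing, including itself).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from pharmlink.aers import KeywordVocabulary, PharmProfileMatrix

logger = logging.getLogger(__name__)

KINDS = (
    "aersfreq",
    "aersbit",
    "sider",
    "japic",
    "chem",
    "geno",
    "integrated",
)


@dataclass
class SimilarityMatrix:
    """Symmetric entity-indexed similarity matrix usable as a kernel."""

    entity_ids: list[str]
    values: np.ndarray
    kind: str = "integrated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over entity_ids")
        if len(set(self.entity_ids)) != n:
            raise ValueError("duplicate entity IDs")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def submatrix(self, ids: Sequence[str]) -> "SimilarityMatrix":
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return SimilarityMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.kind, dict(self.meta)
        )

    def to_tsv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.entity_ids) + "\n")
            for eid, row in zip(self.entity_ids, self.values):
                fh.write(eid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump({"kind": self.kind, **self.meta}, fh, indent=2)

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "integrated") -> "SimilarityMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            ids = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        if ids != header:
            raise ValueError(f"row/column ID mismatch in {path}")
        return cls(ids, np.array(rows, dtype=float), kind)


def gaussian_weight(d: np.ndarray, sigma: float, h: float) -> np.ndarray:
    """Default weight functional form: exp(-d_k^2 / (h*sigma)^2)."""
    return np.exp(-(d**2) / (h * sigma) ** 2)


def keyword_weights(
    vocab: KeywordVocabulary,
    form: Callable[[np.ndarray, float, float], np.ndarray] = gaussian_weight,
) -> np.ndarray:
    """Per-keyword weights, strictly decreasing in the keyword frequency."""
    if vocab.K == 0:
        raise ValueError("empty vocabulary")
    if vocab.sigma <= 0:
        raise ValueError("degenerate vocabulary: sigma must be positive")
    w = np.asarray(form(vocab.d, vocab.sigma, vocab.h), dtype=float)
    if np.any(w <= 0):
        raise ValueError("weight function produced non-positive weights")
    return w


def weighted_cosine(x: np.ndarray, x2: np.ndarray, w: np.ndarray) -> float:
    """Weighted cosine correlation between two profiles.

    Returns 0 when either profile has zero weighted norm (the missing-data
    convention used throughout this package).
    """
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == x2.shape == w.shape):
        raise ValueError("profile/weight length mismatch")
    nx = np.sqrt(np.sum(w * x * x))
    ny = np.sqrt(np.sum(w * x2 * x2))
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.sum(w * x * x2) / (nx * ny))


def pharm_similarity_matrix(
    profiles: PharmProfileMatrix,
    vocab: KeywordVocabulary,
    form: Callable[[np.ndarray, float, float], np.ndarray] = gaussian_weight,
) -> SimilarityMatrix:
    """All-pairs weighted cosine similarity over drug profiles.

    Zero-norm profiles (drugs with no retained keywords) get similarity 0
    to everything, including themselves.
    """
    if profiles.keywords != vocab.keywords:
        raise ValueError("profile keyword order does not match vocabulary")
    w = keyword_weights(vocab, form)
    X = profiles.values * np.sqrt(w)  # similarity = cosine in sqrt(w)-space
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Xn = X / safe[:, None]
    S = Xn @ Xn.T
    S[norms == 0, :] = 0.0
    S[:, norms == 0] = 0.0
    np.fill_diagonal(S, np.where(norms > 0, 1.0, 0.0))
    S = (S + S.T) / 2.0
    kind = "aersfreq" if profiles.mode == "freq" else "aersbit"
    return SimilarityMatrix(
        list(profiles.drug_ids), S, kind, {"h": vocab.h, "sigma": vocab.sigma}
    )


def chem_similarity_matrix(
    drug_ids: Sequence[str], fingerprints: np.ndarray
) -> SimilarityMatrix:
    """Tanimoto similarity |a & b| / |a | b| over binary fingerprints."""
    F = np.asarray(fingerprints)
    if not np.isin(F, (0, 1)).all():
        raise ValueError("fingerprints must be binary")
    F = F.astype(float)
    inter = F @ F.T
    counts = F.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    empty = counts == 0
    if empty.any():
        logger.info("%d empty fingerprints; zero similarity rows", empty.sum())
    S[empty, :] = 0.0
    S[:, empty] = 0.0
    S = (S + S.T) / 2.0
    return SimilarityMatrix(list(drug_ids), S, "chem")


@dataclass(frozen=True)
class SWScoring:
    """Smith-Waterman scoring scheme, recorded in output metadata."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


def _sw_aligner(scoring: SWScoring):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -abs(scoring.gap_open)
    aligner.extend_gap_score = -abs(scoring.gap_extend)
    return aligner


def seq_similarity_matrix(
    records: Iterable, scoring: SWScoring = SWScoring()
) -> SimilarityMatrix:
    """Normalized Smith-Waterman similarity over protein sequences.

    ``records`` is an iterable of Bio.SeqIO records (or (id, sequence)
    tuples).  Each pairwise score is normalized by the geometric mean of
    the two self-alignment scores, giving a symmetric matrix in [0, 1]
    with unit diagonal.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in records:
        if isinstance(rec, tuple):
            rid, seq = rec
        else:
            rid, seq = rec.id, str(rec.seq)
        ids.append(rid)
        seqs.append(seq.upper())
    aligner = _sw_aligner(scoring)
    alphabet = set(aligner.substitution_matrix.alphabet)
    for rid, seq in zip(ids, seqs):
        if len(seq) == 0:
            raise ValueError(f"empty sequence for record {rid}")
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(
                f"invalid residue(s) {sorted(bad)} in record {rid}"
            )
    n = len(ids)
    self_scores = np.array([aligner.score(s, s) for s in seqs])
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sw = aligner.score(seqs[i], seqs[j])
            S[i, j] = S[j, i] = sw / np.sqrt(self_scores[i] * self_scores[j])
    return SimilarityMatrix(
        ids,
        S,
        "geno",
        {
            "matrix": scoring.matrix,
            "gap_open": scoring.gap_open,
            "gap_extend": scoring.gap_extend,
        },
    )


def align_to(
    S: SimilarityMatrix, entity_union: Sequence[str]
) -> SimilarityMatrix:
    """Embed a similarity matrix into a larger entity universe.

    Entities absent from ``S`` get all-zero rows and columns (an entity
    with no source data is similar to nothing).
    """
    if len(set(entity_union)) != len(entity_union):
        raise ValueError("duplicate entity IDs in union")
    pos = {e: i for i, e in enumerate(S.entity_ids)}
    n = len(entity_union)
    out = np.zeros((n, n))
    present = [i for i, e in enumerate(entity_union) if e in pos]
    src = np.array([pos[entity_union[i]] for i in present], dtype=int)
    out[np.ix_(present, present)] = S.values[np.ix_(src, src)]
    return SimilarityMatrix(list(entity_union), out, S.kind, dict(S.meta))


def integrate(
    similarities: Sequence[SimilarityMatrix],
    entity_union: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Entrywise sum of similarity matrices aligned on an entity union.

    This is how the integrated pharmacological (INTEG-P) and
    pharmaco-chemical (INTEG-PC) kernels are assembled: missing entities
    contribute zero.
    """
    if not similarities:
        raise ValueError("need at least one similarity matrix")
    if entity_union is None:
        seen: dict[str, None] = {}
        for S in similarities:
            for e in S.entity_ids:
                seen.setdefault(e)
        entity_union = list(seen)
    total = np.zeros((len(entity_union), len(entity_union)))
    for S in similarities:
        total += align_to(S, entity_union).values
    return SimilarityMatrix(
        list(entity_union),
        total,
        "integrated",
        {"components": [S.kind for S in similarities]},
    )


def condition_kernel(
    S: SimilarityMatrix, jitter: float = 1e-6, shift: bool = False
) -> SimilarityMatrix:
    """Make a symmetric similarity matrix safely positive definite.

    Adds ``jitter`` to the diagonal; with ``shift=True`` the spectrum is
    first shifted by |lambda_min| when the smallest eigenvalue is negative,
    so the result's smallest eigenvalue is at least ``jitter``.
    """
    V = S.values.copy()
    if shift:
        lam_min = float(np.linalg.eigvalsh(V)[0])
        if lam_min < 0:
            V += abs(lam_min) * np.eye(S.n)
    V += jitter * np.eye(S.n)
    meta = dict(S.meta)
    meta["jitter"] = jitter
    return SimilarityMatrix(list(S.entity_ids), V, S.kind, meta)


def read_fingerprints_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read (drug_id, bitstring) fingerprint TSV."""
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            did, bits = line.rstrip("\n").split("\t")[:2]
            ids.append(did)
            rows.append([int(b) for b in bits])
    return ids, np.array(rows, dtype=int)
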