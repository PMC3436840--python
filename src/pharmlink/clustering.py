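"""Single-linkage clustering of drugs and representative selection.

Benchmark gold standards are full of near-duplicate drugs optimized from
the same lead; splitting such twins across CV folds makes target
prediction trivially easy and inflates accuracy.  The standard control is
to cut the single-linkage dendrogram of chemical similarity at a
threshold, keep one randomly chosen representative per cluster, and sweep
the threshold (0.1 to 1.0 in steps of 0.1) to chart the difficulty /
dataset-size trade-off.

Cutting a single-linkage tree at similarity t is exactly the connected
components of the graph with an edge wherever similarity > t (strict:
ties at the threshold do not merge), which is how it is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from pharmlink.similarity import SimilarityMatrix


@dataclass
class RepresentativeSet:
    threshold: float
    clusters: list[list[str]]
    representatives: list[str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.representatives) != len(self.clusters):
            raise ValueError("exactly one representative per cluster required")
        for rep, members in zip(self.representatives, self.clusters):
            assert rep in members, "representative must belong to its cluster"


def single_linkage_clusters(
    S: SimilarityMatrix, threshold: float
) -> list[list[str]]:
    """Partition entities at a single-linkage similarity cut.

    Two drugs end up in the same cluster iff they are connected by a chain
    of pairwise similarities strictly greater than ``threshold``.  Clusters
    are returned sorted (by first member) with sorted members, so output is
    independent of input order up to relabeling.
    """
    A = S.values > threshold
    np.fill_diagonal(A, False)
    n_comp, labels = connected_components(
        csr_matrix(A), directed=False, return_labels=True
    )
    clusters: dict[int, list[str]] = {}
    for eid, lab in zip(S.entity_ids, labels):
        clusters.setdefault(int(lab), []).append(eid)
    out = [sorted(members) for members in clusters.values()]
    out.sort(key=lambda c: c[0])
    return out


def select_representatives(
    clusters: list[list[str]], threshold: float, seed: int = 0
) -> RepresentativeSet:
    """Pick one uniformly random member per cluster, deterministic by seed.

    The draw depends only on the sorted cluster membership, so the result
    is invariant to the order drugs were supplied in.
    """
    rng = np.random.default_rng(seed)
    ordered = sorted((sorted(c) for c in clusters), key=lambda c: c[0])
    reps = []
    for members in ordered:
        assert members, "empty cluster"
        reps.append(members[int(rng.integers(len(members)))])
    return RepresentativeSet(threshold, ordered, reps, seed)


def threshold_sweep(
    S: SimilarityMatrix,
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10)),
    seed: int = 0,
) -> list[RepresentativeSet]:
    """Representative sets across a grid of clustering thresholds.

    Higher thresholds split clusters, so representative counts are
    non-decreasing along an increasing threshold grid.
    """
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError(f"thresholds must lie in (0, 1], got {t}")
    out = []
    for t in thresholds:
        clusters = single_linkage_clusters(S, t)
        out.append(select_representatives(clusters, t, seed))
    return out


def write_clusters_tsv(reps: RepresentativeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tcluster_id\tis_representative\tthreshold\n")
        for cid, members in enumerate(reps.clusters):
            for m in members:
                is_rep = int(m == reps.representatives[cid])
                fh.write(f"{m}\t{cid}\t{is_rep}\t{reps.threshold:g}\n")
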