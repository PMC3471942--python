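"""Identity clustering and leakage-free fold assignment.

Cross-validation folds are assigned at the protein-cluster level so that no
pair of proteins sharing more than the identity threshold (default 30%)
straddles a train/test split, and every hypothetical reverse record lands in
the same fold as its forward partner.

Pairwise identity is computed from a global alignment (match=1, mismatch=0,
gap open=-1, extend=-0.5) as identities / alignment columns; clusters are
single-linkage components of the "identity > threshold" graph. Clusters are
then dealt to folds greedily — largest mutation count first, each into the
currently lightest fold — which balances the number of mutations per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .records import MutationDataset, MutationRecord, ProteinRecord, ValidationError

IDENTITY_THRESHOLD = 0.30


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, aligner=None) -> float:
    """Global-alignment identity: matched identical columns / alignment length."""
    aligner = aligner or _aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    return alignment.counts().identities / alignment.length


def identity_clusters(proteins: dict[str, ProteinRecord],
                      threshold: float = IDENTITY_THRESHOLD) -> list[list[str]]:
    """Single-linkage clusters of proteins sharing > threshold identity."""
    ids = sorted(proteins)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    aligner = _aligner()
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if pairwise_identity(proteins[a].sequence, proteins[b].sequence,
                                 aligner) > threshold:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for pid in ids:
        groups.setdefault(find(pid), []).append(pid)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


@dataclass
class FoldAssignment:
    """protein_id -> fold (1..k), plus the clusters it was derived from."""

    fold_of: dict[str, int]
    clusters: list[list[str]]
    k: int
    identity_threshold: float = IDENTITY_THRESHOLD
    base_of: dict[str, str] = field(default_factory=dict)  # mutant id -> base id

    def fold_of_record(self, rec: MutationRecord) -> int:
        pid = rec.protein_id
        if pid in self.fold_of:
            return self.fold_of[pid]
        base = self.base_of.get(pid)
        if base is not None and base in self.fold_of:
            return self.fold_of[base]
        raise ValidationError(f"no fold for protein {pid!r}")


def cluster_and_fold(proteins: dict[str, ProteinRecord], dataset: MutationDataset,
                     k: int = 5, threshold: float = IDENTITY_THRESHOLD,
                     seed: int = 0) -> FoldAssignment:
    """Assign identity clusters to k folds with balanced mutation counts.

    Deterministic for a given seed: the seed only shuffles the order in which
    clusters with equal mutation counts are dealt.
    """
    clusters = identity_clusters(proteins, threshold)
    if len(clusters) < k:
        raise ValidationError(
            f"only {len(clusters)} identity clusters but {k} folds requested; "
            f"use a smaller k"
        )
    counts = []
    for cluster in clusters:
        n = sum(1 for rec in dataset.records
                if rec.direction == "forward" and rec.protein_id in cluster)
        counts.append(n)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(clusters)))
    order.sort(key=lambda i: -counts[i])  # stable: ties stay in shuffled order

    load = [0] * k
    fold_of: dict[str, int] = {}
    for i in order:
        fold = int(np.argmin(load))
        load[fold] += counts[i]
        for pid in clusters[i]:
            fold_of[pid] = fold + 1
    return FoldAssignment(fold_of=fold_of, clusters=clusters, k=k,
                          identity_threshold=threshold)
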