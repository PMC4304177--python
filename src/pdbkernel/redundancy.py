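"""Redundancy reduction: pairwise similarity, greedy clustering at seven
identity levels, and representative selection.

Similarity between two chains is the identity count of the best local
alignment divided by the average of the two sequence lengths, so it lives
in [0, 1] and penalizes length mismatch.  Clustering is greedy: chains are
visited in decreasing priority (length, then resolution, then deposit
date) and each joins the first cluster whose representative is at least as
similar as the identity level, otherwise it founds a new cluster.
"""

from __future__ import annotations

import datetime as _dt
import functools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from Bio import Align

IDENTITY_LEVELS = (0.90, 0.80, 0.70, 0.60, 0.50, 0.40, 0.30)

#: length difference below which resolution outranks length
LENGTH_WINDOW = 10

Aligner = Callable[[str, str], int]


@dataclass(frozen=True)
class SimilarityScore:
    identities: int
    avg_len: float

    @property
    def value(self) -> float:
        return self.identities / self.avg_len


@dataclass(frozen=True)
class PriorityKey:
    """Attributes driving representative priority.

    Structures that are not X-ray (or X-ray entries lacking a stated
    resolution) are ranked as if their resolution were worst possible.
    """

    chain_id: str
    length: int
    is_xray: bool = False
    resolution: float | None = None
    deposit_date: _dt.date | None = None

    def _resolution_rank(self) -> tuple[float, int]:
        if self.is_xray and self.resolution is not None:
            return (self.resolution, 0)
        return (float("inf"), 0 if self.is_xray else 1)

    def _date_rank(self) -> int:
        # later date = higher priority; missing date ranks last
        return -(self.deposit_date.toordinal() if self.deposit_date else 0)


@dataclass
class ClusterSet:
    """Partition of chain ids at one identity level."""

    level: float
    clusters: list[tuple[str, list[str]]] = field(default_factory=list)

    def members(self) -> list[str]:
        return [m for _, ms in self.clusters for m in ms]

    def representative_of(self, chain_id: str) -> str:
        for rep, ms in self.clusters:
            if chain_id in ms:
                return rep
        raise KeyError(chain_id)


def _builtin_identities(a: str, b: str) -> int:
    """Identity count of the single best local alignment (identity matrix:
    match +2, mismatch -1, gap open -2, extend -1).

    The pair is canonicalized before aligning so the score is symmetric
    even when co-optimal alignments differ in identity count.
    """
    if a > b:
        a, b = b, a
    aligner = Align.PairwiseAligner(
        mode="local", match_score=2, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-1,
    )
    if aligner.score(a, b) <= 0:
        return 0
    best = aligner.align(a, b)[0]
    return int(best.counts().identities)


def pairwise_similarity(a: str, b: str, aligner: Aligner | None = None
                        ) -> SimilarityScore:
    """Local-alignment identities over average sequence length."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    identities = (aligner or _builtin_identities)(a, b)
    return SimilarityScore(identities=identities, avg_len=(len(a) + len(b)) / 2)


def rank_priority(a: PriorityKey, b: PriorityKey) -> PriorityKey:
    """Pairwise priority: a length edge of >= 10 residues wins outright;
    otherwise better (numerically smaller) resolution, X-ray beating
    NMR/unknown; then later deposit date; then smaller chain id."""
    if abs(a.length - b.length) >= LENGTH_WINDOW:
        return a if a.length > b.length else b
    ka = (a._resolution_rank(), a._date_rank(), a.chain_id)
    kb = (b._resolution_rank(), b._date_rank(), b.chain_id)
    return a if ka <= kb else b


def _priority_cmp(a: PriorityKey, b: PriorityKey) -> int:
    if a == b:
        return 0
    return -1 if rank_priority(a, b) is a else 1


def priority_sorted(keys: Sequence[PriorityKey]) -> list[PriorityKey]:
    """Keys in decreasing priority under the pairwise comparator.

    The comparator is not transitive across length windows, so the result
    is the deterministic outcome of a stable sort for the given input
    order, which is what the greedy pass consumes.
    """
    return sorted(keys, key=functools.cmp_to_key(_priority_cmp))


def select_representative(members: Sequence[PriorityKey]) -> str:
    """Windowed total rule: among members within 10 residues of the maximum
    length, pick best resolution, then latest deposit date, then smallest
    id.  Coincides with the pairwise rule on any two-member cluster."""
    if not members:
        raise ValueError("empty cluster")
    longest = max(k.length for k in members)
    window = [k for k in members if k.length > longest - LENGTH_WINDOW]
    best = min(window,
               key=lambda k: (k._resolution_rank(), k._date_rank(), k.chain_id))
    return best.chain_id


def greedy_cluster(
    seqs: Mapping[str, str],
    level: float,
    keys: Mapping[str, PriorityKey] | None = None,
    aligner: Aligner | None = None,
) -> ClusterSet:
    """Greedy incremental clustering at one identity level.

    Chains are visited in decreasing priority; each joins the first
    existing cluster whose representative's similarity reaches the level,
    else founds a new cluster with itself as representative.
    """
    if not any(abs(level - lv) < 1e-9 for lv in IDENTITY_LEVELS):
        raise ValueError(
            f"level must be one of {IDENTITY_LEVELS}, got {level}")
    if keys is None:
        keys = {cid: PriorityKey(chain_id=cid, length=len(s))
                for cid, s in seqs.items()}
    order = priority_sorted([keys[cid] for cid in seqs])
    result = ClusterSet(level=level)
    for key in order:
        cid = key.chain_id
        placed = False
        for rep, members in result.clusters:
            sim = pairwise_similarity(seqs[rep], seqs[cid], aligner)
            if sim.value >= level:
                members.append(cid)
                placed = True
                break
        if not placed:
            result.clusters.append((cid, [cid]))
    return result


class UnknownChainError(KeyError):
    def __init__(self, ids: list[str]):
        super().__init__(f"unknown chain ids: {', '.join(sorted(ids))}")
        self.ids = ids


def cluster_id_list(
    ids: Sequence[str],
    level: float,
    store: Mapping[str, str],
    keys: Mapping[str, PriorityKey] | None = None,
    aligner: Aligner | None = None,
) -> ClusterSet:
    """Cluster only the listed chains; representatives are re-selected
    among the listed members with the windowed priority rule."""
    missing = [i for i in ids if i not in store]
    if missing:
        raise UnknownChainError(missing)
    subset = {i: store[i] for i in ids}
    if keys is not None:
        keys = {i: keys[i] for i in ids}
    else:
        keys = {i: PriorityKey(chain_id=i, length=len(s))
                for i, s in subset.items()}
    clustered = greedy_cluster(subset, level, keys, aligner)
    reselected = [
        (select_representative([keys[m] for m in members]), members)
        for _, members in clustered.clusters
    ]
    return ClusterSet(level=level, clusters=reselected)


def clusters_to_tsv(cs: ClusterSet) -> str:
    lines = ["level\trepresentative\tmember"]
    for rep, members in cs.clusters:
        for m in members:
            lines.append(f"{cs.level:.2f}\t{rep}\t{m}")
    return "\n".join(lines) + "\n"
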