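"""Greedy fixed-identity OTU clustering with dereplication.

Identity between two sequences is defined as 1 − (Levenshtein distance) /
max(len): symmetric, in [0, 1], and exactly checkable against a textbook
dynamic-programming oracle. Clustering is greedy-incremental in the spirit of
CD-HIT-EST: unique sequences are sorted (abundance desc, length desc,
lexicographic) and each either joins the first centroid it matches at >= θ_c
or founds a new OTU.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import edlib

from .merging import MergedRead


@dataclass
class OTU:
    otu_id: str
    centroid: str
    member_count: int
    sample_id: str | None = None
    marker: str | None = None
    #: (sequence, multiplicity) of every member, populated when requested
    members: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.member_count < 1:
            raise ValueError("member_count must be >= 1")


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global identity = 1 − edit distance / max(len); symmetric, in [0, 1]."""
    if not seq_a or not seq_b:
        raise ValueError("percent_identity of an empty sequence")
    dist = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(seq_a), len(seq_b))


def _max_edits(len_a: int, len_b: int, theta: float) -> int:
    """Largest edit distance compatible with identity >= theta (integer form,
    with a small epsilon so exact boundaries like 1/50 at θ=0.98 land inside)."""
    return math.floor((1.0 - theta) * max(len_a, len_b) + 1e-9)


def meets_identity(seq_a: str, seq_b: str, theta: float) -> bool:
    """identity(seq_a, seq_b) >= theta, decided on integer edit distance."""
    k = _max_edits(len(seq_a), len(seq_b), theta)
    res = edlib.align(seq_a, seq_b, mode="NW", task="distance", k=k)
    return res["editDistance"] != -1


ReadsLike = Union[Sequence[MergedRead], Sequence[str]]


def greedy_cluster(
    reads: ReadsLike,
    cluster_identity: float = 0.97,
    sample_id: str | None = None,
    marker: str | None = None,
    keep_members: bool = False,
    best_centroid: bool = False,
) -> list[OTU]:
    """Cluster merged reads into OTUs at identity θ_c.

    By default a sequence joins the FIRST centroid meeting the threshold
    (classic greedy-incremental clustering); ``best_centroid=True`` joins the
    best-matching centroid instead. member_count accumulates read
    multiplicities. Deterministic for any input order.
    """
    if not (0 < cluster_identity <= 1):
        raise ValueError("cluster_identity must be in (0, 1]")
    seqs = [r.sequence if isinstance(r, MergedRead) else str(r) for r in reads]
    if not seqs:
        return []
    counts = Counter(seqs)
    uniq = sorted(counts, key=lambda s: (-counts[s], -len(s), s))

    centroids: list[str] = []
    otu_members: list[list[tuple[str, int]]] = []
    if cluster_identity == 1.0:
        # pure dereplication: distinct sequences can never join a centroid
        centroids = list(uniq)
        otu_members = [[(s, counts[s])] for s in uniq]
        uniq = []
    for seq in uniq:
        target = None
        if best_centroid:
            best = None
            for i, cen in enumerate(centroids):
                if meets_identity(seq, cen, cluster_identity):
                    ident = percent_identity(seq, cen)
                    if best is None or ident > best[0]:
                        best = (ident, i)
            if best is not None:
                target = best[1]
        else:
            for i, cen in enumerate(centroids):
                if meets_identity(seq, cen, cluster_identity):
                    target = i
                    break
        if target is None:
            centroids.append(seq)
            otu_members.append([(seq, counts[seq])])
        else:
            otu_members[target].append((seq, counts[seq]))

    otus = []
    for i, (cen, members) in enumerate(zip(centroids, otu_members)):
        otus.append(
            OTU(
                otu_id=f"OTU{i + 1:04d}",
                centroid=cen,
                member_count=sum(m for _, m in members),
                sample_id=sample_id,
                marker=marker,
                members=tuple(members) if keep_members else None,
            )
        )
    return otus


def filter_low_abundance(otus: Iterable[OTU], min_otu_size: int = 5) -> list[OTU]:
    """Keep OTUs with member_count >= min_otu_size, preserving order."""
    if min_otu_size < 1:
        raise ValueError("min_otu_size must be >= 1")
    return [o for o in otus if o.member_count >= min_otu_size]


def omitted_read_fraction(otus: Sequence[OTU], kept: Sequence[OTU]) -> float:
    """Fraction of reads lost to the low-abundance filter (for run logs)."""
    total = sum(o.member_count for o in otus)
    if total == 0:
        return 0.0
    return 1.0 - sum(o.member_count for o in kept) / total
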