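"""Exhaustive reference search, tie detection, host flagging, and error/threshold
estimation.

Reference sets at this scale are small enough that every OTU centroid is
compared against every same-marker reference by global alignment, taking the
better of the forward and reverse-complement orientations. The per-base
sequencing error — and hence the identification threshold θ_id = 1 − e — is
calibrated from OTU centroids identified as the host, whose reference sequence
is known.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._seq import revcomp
from .clustering import OTU, greedy_cluster, percent_identity
from .taxonomy import Lineage, ReferenceRecord, normalize_name

#: identities are rounded to this many decimals before tie comparison
TIE_DECIMALS = 4


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class SearchHit:
    otu_id: str
    record_id: str
    species: str | None
    identity: float
    alignment_length: int
    lineage: Lineage


@dataclass(frozen=True)
class ErrorEstimate:
    """Per-base error e and the identification threshold derived from it."""

    error: float
    n_centroids: int

    @property
    def id_threshold(self) -> float:
        return 1.0 - self.error


def search_all(
    otus: Sequence[OTU],
    db: Sequence[ReferenceRecord],
    marker: str,
) -> dict[str, list[SearchHit]]:
    """Identity of every OTU against every same-marker reference.

    Returns hits per OTU, sorted by identity descending with record_id as the
    deterministic tie-break. Identity is the better of the two strand
    orientations of the centroid.
    """
    refs = [r for r in db if r.marker == marker]
    if not refs:
        raise SearchError(f"no references for marker {marker!r}")
    out: dict[str, list[SearchHit]] = {}
    for otu in otus:
        rc = revcomp(otu.centroid)
        hits = []
        for ref in refs:
            ident = max(
                percent_identity(otu.centroid, ref.sequence),
                percent_identity(rc, ref.sequence),
            )
            hits.append(
                SearchHit(
                    otu_id=otu.otu_id,
                    record_id=ref.record_id,
                    species=ref.lineage.species,
                    identity=ident,
                    alignment_length=max(len(otu.centroid), len(ref.sequence)),
                    lineage=ref.lineage,
                )
            )
        hits.sort(key=lambda h: (-round(h.identity, TIE_DECIMALS), h.record_id))
        out[otu.otu_id] = hits
    return out


def tied_top_hits(hits: Sequence[SearchHit], tie_tol: float = 0.0) -> list[SearchHit]:
    """All hits within tie_tol of the top identity (rounded to 4 decimals)."""
    if not hits:
        return []
    top = round(hits[0].identity, TIE_DECIMALS)
    return [
        h
        for h in hits
        if round(h.identity, TIE_DECIMALS) >= top - tie_tol - 1e-12
    ]


def flag_host_otus(
    otus: Sequence[OTU],
    hits: Mapping[str, Sequence[SearchHit]],
    host_species: str,
) -> tuple[list[OTU], list[OTU]]:
    """Partition OTUs into (host, non-host).

    An OTU is host when the host species appears among its tied top hits
    (ties involving the host are conservatively treated as host).
    """
    host_key = normalize_name(host_species)
    host, prey = [], []
    for otu in otus:
        tied = tied_top_hits(hits.get(otu.otu_id, []))
        tied_species = {
            normalize_name(h.species) for h in tied if h.species is not None
        }
        (host if host_key in tied_species else prey).append(otu)
    return host, prey


def estimate_error(
    host_otus: Sequence[OTU], host_reference: str | ReferenceRecord
) -> ErrorEstimate:
    """e = 1 − member-count-weighted mean identity of host centroids vs the
    host reference; θ_id = 1 − e.

    Raises SearchError when no host OTUs are available — fall back to the
    configured default threshold in that case.
    """
    if not host_otus:
        raise SearchError(
            "no host OTUs: cannot calibrate error; use the configured id_threshold"
        )
    ref_seq = (
        host_reference.sequence
        if isinstance(host_reference, ReferenceRecord)
        else host_reference
    )
    rc_cache: dict[str, float] = {}
    num = den = 0.0
    for otu in host_otus:
        if otu.centroid not in rc_cache:
            rc_cache[otu.centroid] = max(
                percent_identity(otu.centroid, ref_seq),
                percent_identity(revcomp(otu.centroid), ref_seq),
            )
        num += otu.member_count * rc_cache[otu.centroid]
        den += otu.member_count
    return ErrorEstimate(error=1.0 - num / den, n_centroids=len(host_otus))


def estimate_error_from_reads(
    sequences: Iterable[str], host_reference: str | ReferenceRecord
) -> ErrorEstimate:
    """Calibrate e from raw host amplicons.

    Dereplicates the sequences (every distinct sequence its own centroid,
    weighted by multiplicity) before applying :func:`estimate_error`; clustering
    at a coarse identity first would hide typical errors inside the dominant
    centroid and bias e toward zero.
    """
    otus = greedy_cluster(list(sequences), cluster_identity=1.0)
    return estimate_error(otus, host_reference)
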