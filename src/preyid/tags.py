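"""Species-diagnostic signature tags: short (~40 bp) windows of a reference
that occur in no other species' same-marker reference on either strand.

Tags rescue OTUs the similarity stage cannot resolve (ties, or hits just below
the identity threshold): an exact substring match of a verified tag in the OTU
centroid is accepted as a species identification.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import encode, revcomp
from .clustering import OTU
from .taxonomy import ReferenceRecord, normalize_name


@dataclass(frozen=True)
class SignatureTag:
    species: str
    marker: str
    record_id: str
    start: int  # 0-based offset in the source reference
    length: int
    sequence: str


@dataclass
class SpecificityReport:
    valid: list[SignatureTag]
    flagged: list[tuple[SignatureTag, str]]  # (tag, reason)


@dataclass(frozen=True)
class TagMatch:
    """Outcome of matching verified tags against one centroid."""

    species: str | None
    matched_species: tuple[str, ...]

    @property
    def conflict(self) -> bool:
        return len(self.matched_species) > 1


def _windows(seq: str, length: int) -> np.ndarray:
    codes = encode(seq)
    if len(codes) < length:
        return np.empty((0, length), dtype=np.uint8)
    return np.lib.stride_tricks.sliding_window_view(codes, length)


def _sweep_lengths(L: int, length_sweep: Sequence[int] | None) -> list[int]:
    if length_sweep is None:
        return [L]
    # L first, then alternating outward by distance for a deterministic order
    rest = sorted((l for l in length_sweep if l != L), key=lambda l: (abs(l - L), l))
    return [L, *rest]


def derive_tags(
    db: Sequence[ReferenceRecord],
    marker: str,
    length: int = 40,
    length_sweep: Sequence[int] | None = range(36, 45),
) -> tuple[list[SignatureTag], list[str]]:
    """Derive one diagnostic tag per species for a marker.

    A window is diagnostic iff neither it nor its reverse complement occurs as
    an exact substring of any other species' same-marker reference. Among
    diagnostic windows the one maximizing the minimum Hamming distance to the
    best-matching same-length window in any other species is chosen (most
    robust to sequencing error); ties go to the leftmost window of the first
    reference. Species with no diagnostic window at the target length are
    retried over ``length_sweep`` and reported tagless if none works.
    """
    if length < 8:
        raise ValueError("tag length must be >= 8")
    refs = [r for r in db if r.marker == marker and r.lineage.species]
    by_species: dict[str, list[ReferenceRecord]] = {}
    for r in refs:
        by_species.setdefault(normalize_name(r.lineage.species), []).append(r)

    tags: list[SignatureTag] = []
    tagless: list[str] = []
    for key in sorted(by_species):
        own = sorted(by_species[key], key=lambda r: r.record_id)
        others = [r for r in refs if normalize_name(r.lineage.species) != key]
        tag = None
        for L in _sweep_lengths(length, length_sweep):
            tag = _best_tag_for_species(own, others, marker, L)
            if tag is not None:
                break
        if tag is None:
            tagless.append(own[0].lineage.species)
        else:
            tags.append(tag)
    return tags, tagless


def _best_tag_for_species(
    own: Sequence[ReferenceRecord],
    others: Sequence[ReferenceRecord],
    marker: str,
    L: int,
) -> SignatureTag | None:
    other_windows = [
        w
        for r in others
        for w in (_windows(r.sequence, L), _windows(revcomp(r.sequence), L))
        if w.shape[0]
    ]
    B = np.concatenate(other_windows, axis=0) if other_windows else None

    best: tuple[int, int, int] | None = None  # (min_dist, ref_index, start)
    for ri, ref in enumerate(own):
        A = _windows(ref.sequence, L)
        if not A.shape[0]:
            continue
        if B is None:
            # single-species database: every window is diagnostic; take leftmost
            if best is None:
                best = (np.iinfo(np.int64).max, ri, 0)
            continue
        # min Hamming distance of each own window to any other-species window
        dists = (A[:, None, :] != B[None, :, :]).sum(axis=2).min(axis=1)
        start = int(np.argmax(dists))  # first (leftmost) maximizer
        d = int(dists[start])
        if d >= 1 and (best is None or d > best[0]):
            best = (d, ri, start)
    if best is None:
        return None
    _, ri, start = best
    ref = own[ri]
    return SignatureTag(
        species=ref.lineage.species,
        marker=marker,
        record_id=ref.record_id,
        start=start,
        length=L,
        sequence=ref.sequence[start : start + L],
    )


def verify_specificity(
    tags: Iterable[SignatureTag], db: Sequence[ReferenceRecord]
) -> SpecificityReport:
    """Re-scan every tag against all same-marker references on both strands."""
    report = SpecificityReport(valid=[], flagged=[])
    for tag in tags:
        reason = None
        rc = revcomp(tag.sequence)
        for ref in db:
            if ref.marker != tag.marker or ref.lineage.species is None:
                continue
            if normalize_name(ref.lineage.species) == normalize_name(tag.species):
                continue
            if tag.sequence in ref.sequence or rc in ref.sequence:
                reason = f"occurs in {ref.lineage.species} ({ref.record_id})"
                break
        if reason is None:
            source = next(
                (
                    r
                    for r in db
                    if r.record_id == tag.record_id and r.marker == tag.marker
                ),
                None,
            )
            if source is not None and (
                source.sequence[tag.start : tag.start + tag.length] != tag.sequence
            ):
                reason = "tag does not match its stated source window"
        if reason is None:
            report.valid.append(tag)
        else:
            report.flagged.append((tag, reason))
    return report


def match_tags(otu: OTU | str, tags: Sequence[SignatureTag]) -> TagMatch:
    """Exact-substring tag matching against an OTU centroid, both strands.

    A single matching species is an identification; multiple distinct species
    is a conflict (no identification); none is a miss.
    """
    centroid = otu.centroid if isinstance(otu, OTU) else str(otu)
    rc = revcomp(centroid)
    matched: list[str] = []
    seen: set[str] = set()
    for tag in tags:
        if tag.sequence in centroid or tag.sequence in rc:
            key = normalize_name(tag.species)
            if key not in seen:
                seen.add(key)
                matched.append(tag.species)
    if len(matched) == 1:
        return TagMatch(species=matched[0], matched_species=tuple(matched))
    return TagMatch(species=None, matched_species=tuple(matched))
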