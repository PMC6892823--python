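"""Overlap-based merging of paired-end amplicon reads.

A maximum-score overlap merger: the reverse mate is reverse-complemented, every
candidate overlap of at least ``min_overlap`` bases is scored as
(matches − mismatches), and the best-scoring overlap is accepted when its
mismatch fraction is small enough. Within the overlap the base with the higher
quality wins (tie → forward base). This reproduces the outcome of standard
paired-end mergers on amplicon data without their statistical machinery.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._seq import N_CODE, encode, revcomp


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    forward_seq: str
    forward_qual: str
    reverse_seq: str
    reverse_qual: str

    def __post_init__(self) -> None:
        if len(self.forward_seq) != len(self.forward_qual):
            raise ValueError(f"{self.read_id}: forward seq/qual length mismatch")
        if len(self.reverse_seq) != len(self.reverse_qual):
            raise ValueError(f"{self.read_id}: reverse seq/qual length mismatch")


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    sequence: str
    sample_id: str | None = None
    marker: str | None = None


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | None:
    """Merge one pair, or return None on failure.

    Candidate overlaps align the forward 3' end against the 5' end of the
    reverse-complemented mate. N never counts as a match. Ties in score prefer
    the longer overlap (equivalently the smaller start offset).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    fwd, rev = pair.forward_seq.upper(), pair.reverse_seq.upper()
    if not fwd or not rev or set(fwd) == {"N"} or set(rev) == {"N"}:
        return None
    rc = revcomp(rev)
    rc_qual = pair.reverse_qual[::-1]
    f_codes, r_codes = encode(fwd), encode(rc)
    lf, lr = len(fwd), len(rc)

    best_score, best_o, best_matches = None, None, 0
    for o in range(min_overlap, min(lf, lr) + 1):
        a = f_codes[lf - o :]
        b = r_codes[:o]
        matches = int(np.count_nonzero((a == b) & (a != N_CODE)))
        score = 2 * matches - o
        # strict > keeps the longest overlap among ties because o ascends
        if best_score is None or score > best_score or (score == best_score and o > best_o):
            best_score, best_o, best_matches = score, o, matches
    if best_o is None:
        return None
    if (best_o - best_matches) / best_o > max_mismatch_frac:
        return None

    overlap = []
    for i in range(best_o):
        fi = lf - best_o + i
        if fwd[fi] == rc[i]:
            overlap.append(fwd[fi])
        elif rc_qual[i] > pair.forward_qual[fi]:
            overlap.append(rc[i])
        else:
            overlap.append(fwd[fi])
    merged = fwd[: lf - best_o] + "".join(overlap) + rc[best_o:]
    return MergedRead(read_id=pair.read_id, sequence=merged)


def merge_sample(
    pairs: Iterable[ReadPair],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    sample_id: str | None = None,
    marker: str | None = None,
) -> tuple[list[MergedRead], float | None]:
    """Merge all pairs; returns (merged reads in input order, merge rate).

    merge_rate is None for empty input.
    """
    merged: list[MergedRead] = []
    total = 0
    for pair in pairs:
        total += 1
        m = merge_pair(pair, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac)
        if m is not None:
            merged.append(
                MergedRead(m.read_id, m.sequence, sample_id=sample_id, marker=marker)
            )
    if total == 0:
        return [], None
    return merged, len(merged) / total


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    """Load mate pairs from two FASTQ files (paired by position)."""
    from Bio import SeqIO

    fwd = list(SeqIO.parse(str(r1_path), "fastq"))
    rev = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(fwd) != len(rev):
        raise ValueError("R1 and R2 have different read counts")
    pairs = []
    for f, r in zip(fwd, rev):
        pairs.append(
            ReadPair(
                read_id=f.id,
                forward_seq=str(f.seq).upper(),
                forward_qual="".join(
                    chr(q + 33) for q in f.letter_annotations["phred_quality"]
                ),
                reverse_seq=str(r.seq).upper(),
                reverse_qual="".join(
                    chr(q + 33) for q in r.letter_annotations["phred_quality"]
                ),
            )
        )
    return pairs
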