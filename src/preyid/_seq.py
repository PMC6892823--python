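"""Low-level nucleotide helpers shared across modules."""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_BASE_TO_CODE["N"] = 4
_CODE_TO_BASE = np.array(list("ACGTN"))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

N_CODE = 4


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N to uint8 codes 0..4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, N_CODE, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[codes])


def random_seq(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def mutate_exact(seq: str, n_sites: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``n_sites`` distinct positions to a different base.

    Drawing an exact site count (rather than per-base Bernoulli) keeps realized
    divergences close to their targets on short marker sequences.
    """
    codes = encode(seq)
    if n_sites == 0:
        return seq
    sites = rng.choice(len(codes), size=n_sites, replace=False)
    shifts = rng.integers(1, 4, size=n_sites).astype(np.uint8)
    codes[sites] = (codes[sites] + shifts) % 4
    return decode(codes)


def mutate_at_sites(seq: str, sites: np.ndarray, rng: np.random.Generator) -> str:
    """Substitute the given positions to a different base."""
    codes = encode(seq)
    if len(sites):
        shifts = rng.integers(1, 4, size=len(sites)).astype(np.uint8)
        codes[sites] = (codes[sites] + shifts) % 4
    return decode(codes)


def substitute_iid(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. per-base substitutions at ``rate``; returns a new array."""
    out = codes.copy()
    if rate <= 0:
        return out
    mask = rng.random(len(codes)) < rate
    k = int(mask.sum())
    if k:
        shifts = rng.integers(1, 4, size=k).astype(np.uint8)
        out[mask] = (out[mask] + shifts) % 4
    return out


def hamming_fraction(a: str, b: str) -> float:
    """Substitution fraction between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming_fraction requires equal lengths")
    return float(np.count_nonzero(encode(a) != encode(b)) / len(a))
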