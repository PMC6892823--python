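"""Synthetic reference databases and fecal amplicon samples with known truth.

The generator emulates the statistical structure the analysis assumes: a
predator (host) whose reads dominate fecal samples, a pool of prey fishes with
controlled pairwise divergence (within-genus < within-family < within-order),
per-base substitution sequencing error, and paired reads overlapping by a fixed
length. Reference sequences ARE the marker amplicon region (12S-like 250 bp,
16S-like 280 bp, 18S-like 400 bp), so a merged read spans its full reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._seq import (
    decode,
    encode,
    hamming_fraction,
    mutate_at_sites,
    mutate_exact,
    random_seq,
    revcomp,
    substitute_iid,
)
from .merging import ReadPair
from .taxonomy import Lineage, ReferenceRecord, normalize_name

AMPLICON_LENGTHS = {"12S": 250, "16S": 280, "18S": 400}

#: Default host: an elasmobranch predator in its own order/family, clearly
#: divergent from every teleost prey species. Synthetic stand-in lineage.
HOST_SPECIES = "Pristis synthetica"
HOST_LINEAGE = Lineage(
    kingdom="Animalia",
    class_="Elasmobranchii",
    order="Rhinopristiformes",
    family="Pristidae",
    genus="Pristis",
    species=HOST_SPECIES,
)

#: Default out-of-class contaminant (scavenged-bait pathway): a penaeid-like
#: shrimp, out of the fish classes entirely. Synthetic stand-in lineage.
OUTGROUP_SPECIES = "Penaeus syntheticus"
OUTGROUP_LINEAGE = Lineage(
    kingdom="Animalia",
    class_="Malacostraca",
    order="Decapoda",
    family="Penaeidae",
    genus="Penaeus",
    species=OUTGROUP_SPECIES,
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class DivergenceSpec:
    """Target pairwise substitution fractions by shared rank."""

    within_genus: float = 0.05
    within_family: float = 0.12
    within_order: float = 0.20
    #: relative tolerance on realized pairwise divergence
    rel_tol: float = 0.30

    def __post_init__(self) -> None:
        if not (0 < self.within_genus < self.within_family < self.within_order):
            raise SimulationError(
                "divergence targets must satisfy within_genus < within_family < within_order"
            )


def simulate_reference_db(
    n_orders: int = 2,
    genera_per_order: int = 2,
    species_per_genus: int = 2,
    markers: Sequence[str] = ("12S", "16S"),
    divergence: DivergenceSpec | None = None,
    seed: int = 0,
    include_host: bool = True,
    include_outgroup: bool = False,
    id_threshold: float = 0.98,
    seq_lengths: Mapping[str, int] | None = None,
) -> list[ReferenceRecord]:
    """Generate a taxonomy-structured marker reference database.

    Sequences are produced by mutating a per-marker root sequence along the
    taxonomy tree with exact per-branch substitution counts, so realized
    pairwise divergences track the targets (within ±rel_tol relative).
    Raises SimulationError when the spec is infeasible: species within a genus
    must stay more than 2·(1−id_threshold) apart, or they could not be told
    apart at the identification threshold.

    Deterministic given ``seed``.
    """
    div = divergence or DivergenceSpec()
    if div.within_genus <= 2 * (1 - id_threshold) and species_per_genus > 1:
        raise SimulationError(
            f"within-genus divergence {div.within_genus} <= 2*(1-id_threshold)"
            f"={2 * (1 - id_threshold):.3f}: species would be unidentifiable"
        )
    lengths = dict(AMPLICON_LENGTHS)
    if seq_lengths:
        lengths.update(seq_lengths)

    # additive branch substitution fractions (pairwise divergence ~ 2 * path)
    m_species = div.within_genus / 2
    m_genus = (div.within_family - div.within_genus) / 2
    m_family = (div.within_order - div.within_family) / 2
    m_order = 0.15

    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []
    counter = 0
    for marker in markers:
        L = lengths[marker]
        root = random_seq(L, rng)

        def k(frac: float) -> int:
            return max(1, round(frac * L))

        species_seqs: dict[str, str] = {}
        lineage_of: dict[str, Lineage] = {}
        for oi in range(1, n_orders + 1):
            order_name = f"Ordosim{oi}"
            order_seq = mutate_exact(root, k(m_order), rng)
            # genera are grouped pairwise into families so that within-family
            # (cross-genus) and within-order (cross-family) pairs both exist
            family_seqs: dict[int, str] = {}
            for gi in range(1, genera_per_order + 1):
                fi = (gi + 1) // 2
                if fi not in family_seqs:
                    family_seqs[fi] = mutate_exact(order_seq, k(m_family), rng)
                family_name = f"Famsim{oi}x{fi}"
                genus_name = f"Genosim{oi}x{gi}"
                genus_seq = mutate_exact(family_seqs[fi], k(m_genus), rng)
                # sibling species mutate disjoint site sets so their pairwise
                # divergence is exactly 2*m_species, never eroded by collisions
                ks = k(m_species)
                sites = rng.choice(L, size=ks * species_per_genus, replace=False)
                for si in range(1, species_per_genus + 1):
                    sp_name = f"{genus_name} simspec{si}"
                    own = sites[(si - 1) * ks : si * ks]
                    species_seqs[sp_name] = mutate_at_sites(genus_seq, own, rng)
                    lineage_of[sp_name] = Lineage(
                        kingdom="Animalia",
                        class_="Actinopterygii",
                        order=order_name,
                        family=family_name,
                        genus=genus_name,
                        species=sp_name,
                    )

        _check_divergences(species_seqs, lineage_of, div, id_threshold)

        if include_host:
            host_seq = mutate_exact(root, k(0.30), rng)
            species_seqs[HOST_SPECIES] = host_seq
            lineage_of[HOST_SPECIES] = HOST_LINEAGE
        if include_outgroup:
            out_seq = mutate_exact(root, k(0.45), rng)
            species_seqs[OUTGROUP_SPECIES] = out_seq
            lineage_of[OUTGROUP_SPECIES] = OUTGROUP_LINEAGE

        for sp_name, seq in species_seqs.items():
            counter += 1
            records.append(
                ReferenceRecord(
                    record_id=f"SIM{counter:05d}",
                    marker=marker,
                    lineage=lineage_of[sp_name],
                    sequence=seq,
                )
            )
    return records


def _check_divergences(
    species_seqs: Mapping[str, str],
    lineage_of: Mapping[str, Lineage],
    div: DivergenceSpec,
    id_threshold: float,
) -> None:
    names = list(species_seqs)
    floor = 2 * (1 - id_threshold)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = hamming_fraction(species_seqs[a], species_seqs[b])
            la, lb = lineage_of[a], lineage_of[b]
            if la.genus == lb.genus:
                target = div.within_genus
            elif la.family == lb.family:
                target = div.within_family
            elif la.order == lb.order:
                target = div.within_order
            else:
                target = None
            if target is not None and abs(d - target) > div.rel_tol * target:
                raise SimulationError(
                    f"realized divergence {d:.3f} between {a} and {b} misses "
                    f"target {target} by more than {div.rel_tol:.0%}"
                )
            if d <= floor:
                raise SimulationError(
                    f"{a} and {b} are only {d:.3f} apart; identification at "
                    f"threshold {id_threshold} needs > {floor:.3f}"
                )


@dataclass(frozen=True)
class SimulatedCommunity:
    """Ground-truth composition for one fecal sample."""

    host_species: str = HOST_SPECIES
    prey_fractions: Mapping[str, float] = field(default_factory=dict)
    host_fraction: float = 0.5
    n_reads: int = 5000
    error_rate: float = 0.01
    overlap: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.host_fraction <= 1):
            raise SimulationError("host_fraction must be in [0, 1]")
        if not (0 <= self.error_rate < 0.25):
            raise SimulationError("error_rate must be in [0, 0.25)")
        if self.n_reads < 1:
            raise SimulationError("n_reads must be >= 1")
        if self.prey_fractions:
            total = sum(self.prey_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(f"prey fractions sum to {total}, not 1")
        elif self.host_fraction < 1:
            raise SimulationError("prey_fractions required when host_fraction < 1")


@dataclass
class SampleTruth:
    """True per-species read counts for one simulated sample."""

    host_species: str
    host_count: int
    prey_counts: dict[str, int]
    n_reads: int

    @property
    def prey_species(self) -> set[str]:
        return {s for s, c in self.prey_counts.items() if c > 0}

    def as_dict(self) -> dict:
        return {
            "host_species": self.host_species,
            "host_count": self.host_count,
            "prey_counts": dict(self.prey_counts),
            "n_reads": self.n_reads,
        }


@dataclass
class SimulatedSample:
    sample_id: str
    marker: str
    pairs: list[ReadPair]
    truth: SampleTruth
    #: source species of each read pair, aligned with ``pairs``
    read_species: list[str]
    community: SimulatedCommunity


def simulate_sample(
    community: SimulatedCommunity,
    db: Sequence[ReferenceRecord],
    marker: str,
    sample_id: str = "S1",
) -> SimulatedSample:
    """Draw one sample: multinomial species counts, per-molecule errors,
    overlapping read pairs.

    Substitutions at rate ε are applied once per molecule; both mates are then
    cut from the mutated fragment, overlapping by exactly ``community.overlap``
    bases. Truth counts match emitted reads exactly. Deterministic given
    ``community.seed``.
    """
    by_species = {
        normalize_name(r.lineage.species): r
        for r in db
        if r.marker == marker and r.lineage.species
    }
    species = [community.host_species] + sorted(community.prey_fractions)
    probs = [community.host_fraction] + [
        (1 - community.host_fraction) * community.prey_fractions[s]
        for s in sorted(community.prey_fractions)
    ]
    for s, p in zip(species, probs):
        if p > 0 and normalize_name(s) not in by_species:
            raise SimulationError(f"species {s!r} has no {marker} reference")

    rng = np.random.default_rng(community.seed)
    probs = np.asarray(probs, dtype=float)
    counts = rng.multinomial(community.n_reads, probs / probs.sum())

    pairs: list[ReadPair] = []
    read_species: list[str] = []
    for sp, count in zip(species, counts):
        if count == 0:
            continue
        ref = by_species[normalize_name(sp)]
        frag_codes = encode(ref.sequence)
        for i in range(count):
            mutated = substitute_iid(frag_codes, community.error_rate, rng)
            pairs.append(_pair_from_fragment(mutated, community.overlap, ""))
            read_species.append(sp)
    # shuffle so read order carries no truth signal
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    read_species = [read_species[i] for i in order]
    pairs = [
        replace(p, read_id=f"{sample_id}:read{i + 1}") for i, p in enumerate(pairs)
    ]

    prey_counts = {
        s: int(c) for s, c in zip(species[1:], counts[1:])
    }
    truth = SampleTruth(
        host_species=community.host_species,
        host_count=int(counts[0]),
        prey_counts=prey_counts,
        n_reads=community.n_reads,
    )
    return SimulatedSample(sample_id, marker, pairs, truth, read_species, community)


def _pair_from_fragment(frag_codes: np.ndarray, overlap: int, read_id: str) -> ReadPair:
    A = len(frag_codes)
    if overlap >= A:
        raise SimulationError("overlap must be shorter than the fragment")
    fwd_len = (A + overlap + 1) // 2
    rev_len = A + overlap - fwd_len  # mates overlap by exactly ``overlap``
    fwd = decode(frag_codes[:fwd_len])
    rev = revcomp(decode(frag_codes[A - rev_len :]))
    return ReadPair(read_id, fwd, "I" * fwd_len, rev, "I" * rev_len)


def simulate_bait_contamination(
    sample: SimulatedSample,
    contaminant_fraction: float,
    db: Sequence[ReferenceRecord],
    contaminant_species: str = OUTGROUP_SPECIES,
    seed: int = 0,
) -> SimulatedSample:
    """Replace a fraction of prey reads with reads from an out-of-class taxon.

    Each prey read is independently replaced with probability
    ``contaminant_fraction`` by a read simulated (same error model) from the
    contaminant's reference, emulating scavenged-bait signal in a sample.
    """
    if not (0 <= contaminant_fraction <= 1):
        raise SimulationError("contaminant_fraction must be in [0, 1]")
    if contaminant_fraction == 0:
        return sample
    by_species = {
        normalize_name(r.lineage.species): r
        for r in db
        if r.marker == sample.marker and r.lineage.species
    }
    key = normalize_name(contaminant_species)
    if key not in by_species:
        raise SimulationError(
            f"no {sample.marker} reference for contaminant {contaminant_species!r}"
        )
    frag_codes = encode(by_species[key].sequence)
    rng = np.random.default_rng(seed)
    community = sample.community

    new_pairs: list[ReadPair] = []
    new_species: list[str] = []
    prey_counts = dict(sample.truth.prey_counts)
    contaminant_count = 0
    host_key = normalize_name(sample.truth.host_species)
    for pair, sp in zip(sample.pairs, sample.read_species):
        if normalize_name(sp) != host_key and rng.random() < contaminant_fraction:
            mutated = substitute_iid(frag_codes, community.error_rate, rng)
            new_pairs.append(
                replace(
                    _pair_from_fragment(mutated, community.overlap, ""),
                    read_id=pair.read_id,
                )
            )
            new_species.append(contaminant_species)
            prey_counts[sp] -= 1
            contaminant_count += 1
        else:
            new_pairs.append(pair)
            new_species.append(sp)
    prey_counts[contaminant_species] = (
        prey_counts.get(contaminant_species, 0) + contaminant_count
    )
    truth = SampleTruth(
        host_species=sample.truth.host_species,
        host_count=sample.truth.host_count,
        prey_counts=prey_counts,
        n_reads=sample.truth.n_reads,
    )
    return SimulatedSample(
        sample.sample_id, sample.marker, new_pairs, truth, new_species, community
    )


def write_sample_fastq(sample: SimulatedSample, out_dir: str | Path) -> tuple[Path, Path]:
    """Write `<sample>_R1.fastq` / `<sample>_R2.fastq` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    r1 = out_dir / f"{sample.sample_id}_R1.fastq"
    r2 = out_dir / f"{sample.sample_id}_R2.fastq"
    with open(r1, "w") as f1, open(r2, "w") as f2:
        for p in sample.pairs:
            f1.write(f"@{p.read_id}\n{p.forward_seq}\n+\n{p.forward_qual}\n")
            f2.write(f"@{p.read_id}\n{p.reverse_seq}\n+\n{p.reverse_qual}\n")
    return r1, r2
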