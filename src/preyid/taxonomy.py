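"""Taxonomic lineages, marker reference databases, and occurrence records.

The reference database is the search/tag universe for prey identification: a
FASTA of marker sequences (mitochondrial 12S/16S, nuclear 18S rRNA) paired with
a TSV taxonomy table giving each record a ranked lineage. Occurrence tables map
sampling locations to the species known to occur there (fisheries records) and
drive the plausibility check used to relegate dubious species-level calls.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Rank vocabulary, highest to lowest. Phylum is accepted but optional; fish
#: identifications in this workflow run kingdom > class > order > family >
#: genus > species.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Ranks that must be contiguous from the top (phylum may be absent anywhere).
_REQUIRED_CHAIN = ("kingdom", "class", "order", "family", "genus", "species")

MARKERS = ("12S", "16S", "18S")


class TaxonomyError(ValueError):
    """Raised for malformed lineages, databases, or occurrence lookups."""


def normalize_name(name: str) -> str:
    """Case-insensitive, whitespace-normalized form used for all comparisons."""
    return " ".join(name.split()).lower()


@dataclass(frozen=True)
class Lineage:
    """Ranked names for one taxon; lower ranks may be absent (None)."""

    kingdom: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        seen_absent = False
        for rank in _REQUIRED_CHAIN:
            value = self.get(rank)
            if value is None:
                seen_absent = True
            elif seen_absent:
                raise TaxonomyError(
                    f"rank {rank!r} present but a higher rank is absent: {self}"
                )
        if self.species and self.genus:
            if normalize_name(self.species).split()[0] != normalize_name(self.genus):
                raise TaxonomyError(
                    f"species {self.species!r} does not start with genus {self.genus!r}"
                )

    def get(self, rank: str) -> str | None:
        return getattr(self, "class_" if rank == "class" else rank)

    def deepest_rank(self) -> str:
        deepest = "kingdom"
        for rank in _REQUIRED_CHAIN:
            if self.get(rank) is not None:
                deepest = rank
        return deepest

    @classmethod
    def from_mapping(cls, row: Mapping[str, str | None]) -> "Lineage":
        def clean(v):
            if v is None or (not isinstance(v, str) and pd.isna(v)):
                return None
            v = str(v).strip()
            return v or None

        return cls(
            kingdom=clean(row.get("kingdom")),
            phylum=clean(row.get("phylum")),
            class_=clean(row.get("class")),
            order=clean(row.get("order")),
            family=clean(row.get("family")),
            genus=clean(row.get("genus")),
            species=clean(row.get("species")),
        )

    def as_dict(self) -> dict[str, str | None]:
        return {
            "kingdom": self.kingdom,
            "phylum": self.phylum,
            "class": self.class_,
            "order": self.order,
            "family": self.family,
            "genus": self.genus,
            "species": self.species,
        }


@dataclass(frozen=True)
class ReferenceRecord:
    """One marker sequence with its full lineage."""

    record_id: str
    marker: str
    lineage: Lineage
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise TaxonomyError(f"empty sequence for record {self.record_id!r}")
        if self.marker not in MARKERS:
            raise TaxonomyError(
                f"unknown marker {self.marker!r} (expected one of {MARKERS})"
            )
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise TaxonomyError(
                f"record {self.record_id!r} has non-ACGTN characters: {sorted(bad)}"
            )


def lowest_common_taxon(lineages: Sequence[Lineage]) -> tuple[str, str]:
    """Deepest rank (and its name) shared by every lineage.

    Used to resolve tied reference hits: two tied seatrout references collapse
    to their genus. Phylum is skipped whenever any lineage lacks it.
    """
    if not lineages:
        raise TaxonomyError("lowest_common_taxon of an empty lineage list")
    result: tuple[str, str] | None = None
    for rank in RANKS:
        names = [lin.get(rank) for lin in lineages]
        if any(n is None for n in names):
            if rank == "phylum":
                continue
            break
        normalized = {normalize_name(n) for n in names}
        if len(normalized) == 1:
            result = (rank, names[0])
        else:
            break
    if result is None:
        raise TaxonomyError("lineages share no taxonomic rank")
    return result


@dataclass
class OccurrenceTable:
    """Map location_id -> set of species known to occur there."""

    occurrences: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[str, set[str]] = {}
        for loc, species in self.occurrences.items():
            if not str(loc).strip():
                raise TaxonomyError("empty location_id in occurrence table")
            normalized[loc] = {normalize_name(s) for s in species}
        self.occurrences = normalized

    def species_at(self, location: str) -> set[str]:
        if location not in self.occurrences:
            raise TaxonomyError(f"unknown location {location!r}")
        return self.occurrences[location]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OccurrenceTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"location_id", "species"} <= set(df.columns):
            raise TaxonomyError(
                "occurrence TSV needs columns (location_id, species)"
            )
        occ: dict[str, set[str]] = {}
        for loc, sub in df.groupby("location_id"):
            occ[str(loc)] = set(sub["species"].dropna())
        return cls(occ)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"location_id": loc, "species": sp}
            for loc, spp in sorted(self.occurrences.items())
            for sp in sorted(spp)
        ]
        pd.DataFrame(rows, columns=["location_id", "species"]).to_csv(
            path, sep="\t", index=False
        )


def is_plausible(species: str, location: str, occ: OccurrenceTable) -> bool:
    """True iff ``species`` is on the occurrence list for ``location``."""
    return normalize_name(species) in occ.species_at(location)


@dataclass
class PipelineParams:
    """All numeric knobs of the identification workflow.

    cluster_identity
        OTU clustering identity threshold θ_c (fraction of identical columns).
    min_otu_size
        OTUs with fewer member reads are treated as inconsequential noise.
    id_threshold
        Minimum identity θ_id for accepting a reference hit; by construction
        θ_id = 1 − estimated per-base sequencing error.
    tag_length
        Target signature-tag length L in bp.
    normalization_total
        Per-sample read depth T that profiles are rescaled to.
    min_overlap
        Smallest mate overlap considered during read merging.
    """

    cluster_identity: float = 0.97
    min_otu_size: int = 5
    id_threshold: float = 0.98
    tag_length: int = 40
    normalization_total: int = 10_000
    min_overlap: int = 10
    max_mismatch_frac: float = 0.1
    host_species: str | None = None
    derive_threshold: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cluster_identity <= 1):
            raise ValueError("cluster_identity must be in (0, 1]")
        if not (0 < self.id_threshold <= 1):
            raise ValueError("id_threshold must be in (0, 1]")
        if self.min_otu_size < 1:
            raise ValueError("min_otu_size must be >= 1")
        if self.tag_length < 8:
            raise ValueError("tag_length must be >= 8")
        if self.normalization_total < 1:
            raise ValueError("normalization_total must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


# ---------------------------------------------------------------------------
# Reference database I/O


def load_reference_db(
    fasta_path: str | Path, taxonomy_path: str | Path
) -> list[ReferenceRecord]:
    """Load a reference database from a FASTA + taxonomy TSV pair.

    The TSV must carry ``record_id`` plus rank columns (empty cell = rank
    absent). The record's marker comes from a ``marker`` TSV column if present,
    else from a ``marker=XX`` token in the FASTA description.
    """
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
    if "record_id" not in tax.columns:
        raise TaxonomyError("taxonomy TSV must have a 'record_id' column")
    if tax["record_id"].duplicated().any():
        dup = tax["record_id"][tax["record_id"].duplicated()].iloc[0]
        raise TaxonomyError(f"duplicate record_id {dup!r} in taxonomy table")
    tax_rows = {row["record_id"]: row for _, row in tax.iterrows()}

    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise TaxonomyError(f"duplicate record_id {rid!r} in FASTA")
        seen.add(rid)
        if rid not in tax_rows:
            raise TaxonomyError(f"FASTA record {rid!r} missing from taxonomy table")
        row = tax_rows[rid]
        marker = None
        if "marker" in tax.columns and isinstance(row.get("marker"), str):
            marker = row["marker"].strip()
        if not marker:
            for token in rec.description.split():
                if token.startswith("marker="):
                    marker = token.split("=", 1)[1]
        if not marker:
            raise TaxonomyError(f"no marker given for record {rid!r}")
        records.append(
            ReferenceRecord(
                record_id=rid,
                marker=marker,
                lineage=Lineage.from_mapping(row),
                sequence=str(rec.seq).upper(),
            )
        )
    if not records:
        raise TaxonomyError("empty reference database")
    return records


def write_reference_db(
    records: Iterable[ReferenceRecord],
    fasta_path: str | Path,
    taxonomy_path: str | Path,
) -> None:
    """Write records back to a FASTA + taxonomy TSV pair (round-trip safe)."""
    records = list(records)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description=f"marker={r.marker}")
        for r in records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    rows = []
    for r in records:
        row = {"record_id": r.record_id, "marker": r.marker}
        row.update({k: (v or "") for k, v in r.lineage.as_dict().items()})
        rows.append(row)
    cols = ["record_id", "marker", *RANKS]
    pd.DataFrame(rows, columns=cols).to_csv(taxonomy_path, sep="\t", index=False)


def species_lineages(db: Iterable[ReferenceRecord]) -> dict[str, Lineage]:
    """Map normalized species name -> lineage, across all markers."""
    out: dict[str, Lineage] = {}
    for rec in db:
        if rec.lineage.species:
            out.setdefault(normalize_name(rec.lineage.species), rec.lineage)
    return out
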