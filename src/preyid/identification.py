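"""The taxonomic identification cascade and the end-to-end sample pipeline.

Cascade for mitochondrial markers, per OTU:

1. a unique top reference hit at identity >= θ_id is accepted at species level;
2. tied top hits (distinct species) are sent to signature-tag rescue — an exact
   tag match identifies the species;
3. unresolved ties fall back to the lowest shared taxon of the tied lineages;
4. OTUs below θ_id can still be rescued by a tag match, else are unidentified;
5. any species-level call implausible at the sampling location (per the
   occurrence table) is relegated upward to the lowest rank that contains a
   locally plausible species.

The 18S mode instead takes the class of the single best hit (ascending to the
next present rank when class is absent), reflecting that marker's lower
taxonomic resolution.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .clustering import OTU, filter_low_abundance, greedy_cluster, omitted_read_fraction
from .merging import MergedRead, ReadPair, merge_sample
from .search import (
    ErrorEstimate,
    SearchError,
    SearchHit,
    estimate_error,
    flag_host_otus,
    search_all,
    tied_top_hits,
)
from .tags import SignatureTag, match_tags
from .taxonomy import (
    Lineage,
    OccurrenceTable,
    PipelineParams,
    ReferenceRecord,
    is_plausible,
    lowest_common_taxon,
    normalize_name,
    species_lineages,
)


class Method(str, enum.Enum):
    SIMILARITY = "similarity"
    TAG = "tag"
    LCA = "lca"
    OCCURRENCE_RELEGATED = "occurrence_relegated"
    HOST = "host"
    CLASS_LEVEL = "class_level"
    UNIDENTIFIED = "unidentified"


@dataclass(frozen=True)
class Identification:
    otu_id: str
    rank: str | None
    name: str | None
    method: Method
    hits: tuple[SearchHit, ...] = ()
    member_count: int = 0

    @property
    def identified(self) -> bool:
        return self.method not in (Method.UNIDENTIFIED, Method.HOST)


@dataclass
class SampleProfile:
    """Normalized taxon composition of one sample for one marker."""

    sample_id: str
    marker: str
    counts: dict[str, int] = field(default_factory=dict)
    host_fraction: float = 0.0
    unidentified_fraction: float = 0.0

    @property
    def taxa(self) -> set[str]:
        return {t for t, c in self.counts.items() if c > 0}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


def _taxon_label(rank: str, name: str) -> str:
    """Display label: species binomial, 'Genus sp.', or 'Name (rank)'."""
    if rank == "species":
        return name
    if rank == "genus":
        return f"{name} sp."
    return f"{name} ({rank})"


def identify_otu(
    otu: OTU,
    hits: Sequence[SearchHit],
    tags: Sequence[SignatureTag],
    id_threshold: float,
    occ: OccurrenceTable | None = None,
    location: str | None = None,
    taxonomy: Mapping[str, Lineage] | None = None,
    tie_tol: float = 0.0,
) -> Identification:
    """Run the full mitochondrial cascade for one OTU (host flagging is done
    separately). Every OTU receives exactly one Identification."""
    base = dict(otu_id=otu.otu_id, member_count=otu.member_count)
    if not hits:
        return Identification(rank=None, name=None, method=Method.UNIDENTIFIED, **base)
    tied = tied_top_hits(hits, tie_tol=tie_tol)
    top_identity = round(hits[0].identity, 4)
    tied_species = []
    for h in tied:
        if h.species and normalize_name(h.species) not in {
            normalize_name(s) for s in tied_species
        }:
            tied_species.append(h.species)

    if top_identity >= id_threshold - 1e-12:
        if len(tied_species) == 1:
            ident = Identification(
                rank="species",
                name=tied_species[0],
                method=Method.SIMILARITY,
                hits=tuple(tied),
                **base,
            )
        else:
            tag_match = match_tags(otu, tags)
            if tag_match.species is not None:
                ident = Identification(
                    rank="species",
                    name=tag_match.species,
                    method=Method.TAG,
                    hits=tuple(tied),
                    **base,
                )
            else:
                rank, name = lowest_common_taxon([h.lineage for h in tied])
                ident = Identification(
                    rank=rank, name=name, method=Method.LCA, hits=tuple(tied), **base
                )
    else:
        # below threshold: signature tags are the only remaining evidence
        tag_match = match_tags(otu, tags)
        if tag_match.species is not None:
            ident = Identification(
                rank="species",
                name=tag_match.species,
                method=Method.TAG,
                hits=tuple(tied),
                **base,
            )
        else:
            return Identification(
                rank=None, name=None, method=Method.UNIDENTIFIED, hits=tuple(tied), **base
            )

    return _relegate_if_implausible(ident, occ, location, taxonomy)


def _relegate_if_implausible(
    ident: Identification,
    occ: OccurrenceTable | None,
    location: str | None,
    taxonomy: Mapping[str, Lineage] | None,
) -> Identification:
    """Walk a species-level call up the ranks until a locally plausible
    species falls under the assigned taxon (genus first)."""
    if (
        ident.rank != "species"
        or occ is None
        or location is None
        or taxonomy is None
        or ident.name is None
    ):
        return ident
    if is_plausible(ident.name, location, occ):
        return ident
    lineage = taxonomy.get(normalize_name(ident.name))
    if lineage is None:
        return ident
    local = [
        taxonomy[sp] for sp in occ.species_at(location) if sp in taxonomy
    ]
    for rank in ("genus", "family", "order", "class", "kingdom"):
        taxon = lineage.get(rank)
        if taxon is None:
            continue
        key = normalize_name(taxon)
        if any(
            lin.get(rank) and normalize_name(lin.get(rank)) == key for lin in local
        ):
            return Identification(
                otu_id=ident.otu_id,
                rank=rank,
                name=taxon,
                method=Method.OCCURRENCE_RELEGATED,
                hits=ident.hits,
                member_count=ident.member_count,
            )
    return Identification(
        otu_id=ident.otu_id,
        rank=None,
        name=None,
        method=Method.UNIDENTIFIED,
        hits=ident.hits,
        member_count=ident.member_count,
    )


def identify_class_level(otu: OTU, hits: Sequence[SearchHit]) -> Identification:
    """18S mode: class of the single top hit, ascending when class is absent."""
    base = dict(otu_id=otu.otu_id, member_count=otu.member_count)
    if not hits:
        return Identification(rank=None, name=None, method=Method.UNIDENTIFIED, **base)
    top = hits[0]
    for rank in ("class", "phylum", "kingdom"):
        name = top.lineage.get(rank)
        if name is not None:
            return Identification(
                rank=rank, name=name, method=Method.CLASS_LEVEL, hits=(top,), **base
            )
    return Identification(
        rank=None, name=None, method=Method.UNIDENTIFIED, hits=(top,), **base
    )


def normalize_counts(counts: Mapping[str, float], total: int = 10_000) -> dict[str, int]:
    """Rescale counts to sum exactly to ``total`` (largest-remainder rounding).

    Zero counts stay zero; all-zero input is an error.
    """
    raw_total = sum(counts.values())
    if raw_total <= 0:
        raise ValueError("normalize_counts needs at least one positive count")
    quotas = {k: v * total / raw_total for k, v in counts.items()}
    floors = {k: int(q) for k, q in quotas.items()}
    leftover = total - sum(floors.values())
    # hand out remaining units by descending fractional remainder, name-stable
    order = sorted(quotas, key=lambda k: (-(quotas[k] - floors[k]), k))
    for k in order[:leftover]:
        floors[k] += 1
    return floors


def remove_host(
    counts: Mapping[str, float], host_taxa: str | set[str]
) -> tuple[dict[str, float], float]:
    """Drop host entries; returns (prey-only counts, host read fraction)."""
    if isinstance(host_taxa, str):
        host_taxa = {host_taxa}
    host_keys = {normalize_name(t) for t in host_taxa}
    total = sum(counts.values())
    host = sum(v for k, v in counts.items() if normalize_name(k) in host_keys)
    prey = {k: v for k, v in counts.items() if normalize_name(k) not in host_keys}
    return prey, (host / total if total > 0 else 0.0)


@dataclass
class PipelineResult:
    profile: SampleProfile
    identifications: list[Identification]
    host_otus: list[OTU]
    error_estimate: ErrorEstimate | None
    log: dict


def run_pipeline(
    reads: Sequence[ReadPair] | Sequence[MergedRead] | Sequence[str],
    db: Sequence[ReferenceRecord],
    params: PipelineParams,
    marker: str,
    tags: Sequence[SignatureTag] = (),
    occ: OccurrenceTable | None = None,
    location: str | None = None,
    sample_id: str = "sample",
) -> PipelineResult:
    """merge → cluster → filter → search → calibrate → identify → profile.

    ``reads`` may be raw pairs (merged here) or pre-merged sequences. The 18S
    marker runs the class-level mode and normalizes before host removal; the
    mitochondrial markers remove host reads first and normalize the prey
    counts, matching how fecal metabarcoding tables report "after removal of
    host sequences".
    """
    log: dict = {"sample_id": sample_id, "marker": marker}
    reads = list(reads)
    if not reads:
        raise PipelineError("merge", "empty sample")

    if isinstance(reads[0], ReadPair):
        merged, merge_rate = merge_sample(
            reads,
            min_overlap=params.min_overlap,
            max_mismatch_frac=params.max_mismatch_frac,
            sample_id=sample_id,
            marker=marker,
        )
        log["n_pairs"] = len(reads)
        log["merge_rate"] = merge_rate
    else:
        merged = [
            r if isinstance(r, MergedRead) else MergedRead(f"read{i}", str(r))
            for i, r in enumerate(reads)
        ]
        log["n_pairs"] = None
        log["merge_rate"] = None
    log["n_merged"] = len(merged)
    if not merged:
        raise PipelineError("merge", "no read pairs could be merged")

    otus = greedy_cluster(
        merged,
        cluster_identity=params.cluster_identity,
        sample_id=sample_id,
        marker=marker,
        keep_members=params.derive_threshold,
    )
    log["n_otus"] = len(otus)
    kept = filter_low_abundance(otus, params.min_otu_size)
    log["n_otus_kept"] = len(kept)
    log["omitted_read_fraction"] = omitted_read_fraction(otus, kept)
    if not kept:
        raise PipelineError("filter", "no OTU passed the abundance filter")

    hits = search_all(kept, db, marker)

    host_otus: list[OTU] = []
    prey_otus = list(kept)
    error_estimate = None
    id_threshold = params.id_threshold
    if params.host_species:
        host_otus, prey_otus = flag_host_otus(kept, hits, params.host_species)
        host_ref = next(
            (
                r
                for r in db
                if r.marker == marker
                and r.lineage.species
                and normalize_name(r.lineage.species)
                == normalize_name(params.host_species)
            ),
            None,
        )
        if host_otus and host_ref is not None:
            if params.derive_threshold:
                host_seqs = [
                    seq
                    for otu in host_otus
                    for seq, mult in (otu.members or ((otu.centroid, otu.member_count),))
                    for _ in range(mult)
                ]
                error_estimate = estimate_error(
                    greedy_cluster(host_seqs, cluster_identity=1.0), host_ref
                )
                id_threshold = error_estimate.id_threshold
            else:
                try:
                    error_estimate = estimate_error(host_otus, host_ref)
                except SearchError:
                    error_estimate = None
    log["n_host_otus"] = len(host_otus)
    log["error_estimate"] = error_estimate.error if error_estimate else None
    log["id_threshold"] = id_threshold

    taxonomy = species_lineages(db)
    identifications: list[Identification] = []
    for otu in host_otus:
        identifications.append(
            Identification(
                otu_id=otu.otu_id,
                rank="species",
                name=params.host_species,
                method=Method.HOST,
                hits=tuple(tied_top_hits(hits[otu.otu_id])),
                member_count=otu.member_count,
            )
        )
    for otu in prey_otus:
        if marker == "18S":
            identifications.append(identify_class_level(otu, hits[otu.otu_id]))
        else:
            identifications.append(
                identify_otu(
                    otu,
                    hits[otu.otu_id],
                    tags,
                    id_threshold=id_threshold,
                    occ=occ,
                    location=location,
                    taxonomy=taxonomy,
                )
            )
    method_counts: dict[str, int] = {}
    for ident in identifications:
        method_counts[ident.method.value] = method_counts.get(ident.method.value, 0) + 1
    log["method_counts"] = method_counts

    total_reads = sum(o.member_count for o in kept)
    host_reads = sum(o.member_count for o in host_otus)
    unident_reads = sum(
        i.member_count for i in identifications if i.method is Method.UNIDENTIFIED
    )
    host_fraction = host_reads / total_reads if total_reads else 0.0
    unidentified_fraction = unident_reads / total_reads if total_reads else 0.0

    host_label = params.host_species or ""
    taxon_counts: dict[str, int] = {}
    for ident in identifications:
        if ident.method is Method.UNIDENTIFIED:
            continue
        if ident.method is Method.HOST:
            label = host_label
        else:
            label = _taxon_label(ident.rank, ident.name)
        taxon_counts[label] = taxon_counts.get(label, 0) + ident.member_count

    if marker == "18S":
        # normalize everything (host included), then drop host entries
        if taxon_counts:
            normalized = normalize_counts(taxon_counts, params.normalization_total)
            prey_counts, _ = remove_host(normalized, host_label) if host_label else (
                normalized,
                0.0,
            )
        else:
            prey_counts = {}
    else:
        prey_raw, _ = remove_host(taxon_counts, host_label) if host_label else (
            dict(taxon_counts),
            0.0,
        )
        prey_counts = (
            normalize_counts(prey_raw, params.normalization_total)
            if sum(prey_raw.values()) > 0
            else {}
        )

    profile = SampleProfile(
        sample_id=sample_id,
        marker=marker,
        counts={k: int(v) for k, v in prey_counts.items()},
        host_fraction=host_fraction,
        unidentified_fraction=unidentified_fraction,
    )
    log["host_fraction"] = host_fraction
    log["unidentified_fraction"] = unidentified_fraction
    log["n_prey_taxa"] = len(profile.taxa)
    return PipelineResult(
        profile=profile,
        identifications=identifications,
        host_otus=host_otus,
        error_estimate=error_estimate,
        log=log,
    )
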