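"""The identification cascade, normalization, host removal, and the pipeline."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preyid import (
    OTU,
    Method,
    OccurrenceTable,
    PipelineParams,
    SimulatedCommunity,
    identify_class_level,
    identify_otu,
    normalize_counts,
    remove_host,
    run_pipeline,
    simulate_sample,
)
from preyid.identification import PipelineError
from preyid.search import SearchHit
from preyid.simulate import HOST_SPECIES, OUTGROUP_SPECIES
from preyid.tags import SignatureTag

from conftest import make_lineage


def _lin(genus, species, family="Sciaenidae", order="Perciformes"):
    return make_lineage(order=order, family=family, genus=genus, species=species)


def _hit(identity, record_id, species, genus=None, **kw):
    genus = genus or species.split()[0]
    return SearchHit(
        otu_id="O1",
        record_id=record_id,
        species=species,
        identity=identity,
        alignment_length=250,
        lineage=_lin(genus, species, **kw),
    )


OTU1 = OTU("O1", "ACGT" * 40, 100)

TAXONOMY = {
    "cynoscion arenarius": _lin("Cynoscion", "Cynoscion arenarius"),
    "cynoscion nebulosus": _lin("Cynoscion", "Cynoscion nebulosus"),
    "menticirrhus littoralis": _lin("Menticirrhus", "Menticirrhus littoralis"),
    "menticirrhus americanus": _lin("Menticirrhus", "Menticirrhus americanus"),
}

OCC = OccurrenceTable(
    {"CharlotteHarbor": {"Cynoscion arenarius", "Cynoscion nebulosus",
                         "Menticirrhus americanus"}}
)


class TestCascade:
    def test_unique_hit_above_threshold_accepted_at_species(self):
        hits = [_hit(0.99, "R1", "Cynoscion arenarius"), _hit(0.93, "R2", "Cynoscion nebulosus")]
        ident = identify_otu(OTU1, hits, [], 0.98, OCC, "CharlotteHarbor", TAXONOMY)
        assert (ident.rank, ident.name, ident.method) == (
            "species", "Cynoscion arenarius", Method.SIMILARITY,
        )

    def test_tie_without_tag_collapses_to_genus_lca(self):
        hits = [_hit(0.99, "R1", "Cynoscion arenarius"), _hit(0.99, "R2", "Cynoscion nebulosus")]
        ident = identify_otu(OTU1, hits, [], 0.98, OCC, "CharlotteHarbor", TAXONOMY)
        assert (ident.rank, ident.name, ident.method) == ("genus", "Cynoscion", Method.LCA)

    def test_tie_rescued_by_signature_tag(self):
        tag = SignatureTag("Cynoscion nebulosus", "12S", "R2", 0, 8, OTU1.centroid[:8])
        hits = [_hit(0.99, "R1", "Cynoscion arenarius"), _hit(0.99, "R2", "Cynoscion nebulosus")]
        ident = identify_otu(OTU1, hits, [tag], 0.98, OCC, "CharlotteHarbor", TAXONOMY)
        assert (ident.rank, ident.name, ident.method) == (
            "species", "Cynoscion nebulosus", Method.TAG,
        )

    def test_implausible_species_relegated_to_genus(self):
        # unique best hit to a species absent from the local occurrence list
        hits = [_hit(0.99, "R1", "Menticirrhus littoralis")]
        ident = identify_otu(OTU1, hits, [], 0.98, OCC, "CharlotteHarbor", TAXONOMY)
        assert (ident.rank, ident.name, ident.method) == (
            "genus", "Menticirrhus", Method.OCCURRENCE_RELEGATED,
        )

    def test_below_threshold_without_tag_unidentified(self):
        hits = [_hit(0.95, "R1", "Cynoscion arenarius")]
        ident = identify_otu(OTU1, hits, [], 0.98, OCC, "CharlotteHarbor", TAXONOMY)
        assert ident.method is Method.UNIDENTIFIED and ident.rank is None

    def test_below_threshold_with_tag_rescued(self):
        tag = SignatureTag("Cynoscion nebulosus", "12S", "R2", 0, 8, OTU1.centroid[:8])
        hits = [_hit(0.95, "R1", "Cynoscion arenarius")]
        ident = identify_otu(OTU1, hits, [tag], 0.98, OCC, "CharlotteHarbor", TAXONOMY)
        assert (ident.rank, ident.name, ident.method) == (
            "species", "Cynoscion nebulosus", Method.TAG,
        )

    def test_same_species_double_hit_is_not_a_tie(self):
        hits = [_hit(0.99, "R1", "Cynoscion arenarius"), _hit(0.99, "R9", "Cynoscion arenarius")]
        ident = identify_otu(OTU1, hits, [], 0.98, OCC, "CharlotteHarbor", TAXONOMY)
        assert ident.method is Method.SIMILARITY

    def test_every_otu_gets_exactly_one_method(self):
        cases = [
            [],
            [_hit(0.99, "R1", "Cynoscion arenarius")],
            [_hit(0.99, "R1", "Cynoscion arenarius"), _hit(0.99, "R2", "Cynoscion nebulosus")],
            [_hit(0.90, "R1", "Cynoscion arenarius")],
        ]
        for hits in cases:
            ident = identify_otu(OTU1, hits, [], 0.98, OCC, "CharlotteHarbor", TAXONOMY)
            assert isinstance(ident.method, Method)


class TestClassLevel:
    def test_class_of_top_hit(self):
        ident = identify_class_level(OTU1, [_hit(0.9, "R1", "Cynoscion arenarius")])
        assert (ident.rank, ident.name, ident.method) == (
            "class", "Actinopterygii", Method.CLASS_LEVEL,
        )

    def test_rank_ascends_when_class_absent(self):
        hit = SearchHit(
            otu_id="O1", record_id="R1", species=None, identity=0.9,
            alignment_length=100,
            lineage=make_lineage(kingdom="Chromalveolata", class_=None),
        )
        ident = identify_class_level(OTU1, [hit])
        assert (ident.rank, ident.name) == ("kingdom", "Chromalveolata")

    def test_empty_hits_unidentified(self):
        assert identify_class_level(OTU1, []).method is Method.UNIDENTIFIED


class TestNormalization:
    def test_symmetric_split(self):
        assert normalize_counts({"a": 1, "b": 1}, 10_000) == {"a": 5000, "b": 5000}

    def test_largest_remainder_by_hand(self):
        assert normalize_counts({"a": 1, "b": 2}, 10_000) == {"a": 3333, "b": 6667}

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            normalize_counts({"a": 0}, 10_000)

    @given(
        st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=4),
            st.integers(min_value=0, max_value=10_000),
            min_size=1,
            max_size=12,
        ).filter(lambda d: sum(d.values()) > 0)
    )
    @settings(deadline=None, max_examples=200)
    def test_sums_exactly_to_total_and_preserves_zeros(self, counts):
        out = normalize_counts(counts, 10_000)
        assert sum(out.values()) == 10_000
        assert all(out[k] == 0 for k, v in counts.items() if v == 0)


class TestRemoveHost:
    def test_known_host_fraction(self):
        prey, frac = remove_host({"host": 70, "a": 20, "b": 10}, "host")
        assert frac == pytest.approx(0.70)
        assert prey == {"a": 20, "b": 10}

    def test_all_host_and_no_host(self):
        prey, frac = remove_host({"host": 5}, "host")
        assert prey == {} and frac == 1.0
        prey2, frac2 = remove_host({"a": 5}, "host")
        assert prey2 == {"a": 5} and frac2 == 0.0


class TestRunPipeline:
    def test_recovers_truth_with_host(self, small_db, prey_species, params):
        chosen = prey_species[:3]
        comm = SimulatedCommunity(
            prey_fractions={s: 1 / 3 for s in chosen},
            host_fraction=0.5, n_reads=1500, error_rate=0.0, seed=21,
        )
        sample = simulate_sample(comm, small_db, "12S")
        result = run_pipeline(sample.pairs, small_db, params, "12S", sample_id="SF9")
        assert result.profile.taxa == sample.truth.prey_species
        assert sum(result.profile.counts.values()) == params.normalization_total
        assert result.profile.host_fraction == pytest.approx(
            sample.truth.host_count / 1500, abs=0.01
        )

    def test_empty_sample_errors_at_merge(self, small_db, params):
        with pytest.raises(PipelineError, match="merge"):
            run_pipeline([], small_db, params, "12S")

    def test_deterministic(self, small_db, prey_species, params):
        comm = SimulatedCommunity(
            prey_fractions={prey_species[0]: 1.0}, host_fraction=0.4,
            n_reads=400, error_rate=0.01, seed=22,
        )
        sample = simulate_sample(comm, small_db, "12S")
        r1 = run_pipeline(sample.pairs, small_db, params, "12S")
        r2 = run_pipeline(sample.pairs, small_db, params, "12S")
        assert r1.profile.counts == r2.profile.counts
        assert [i.method for i in r1.identifications] == [
            i.method for i in r2.identifications
        ]

    def test_premerged_input_accepted(self, small_db, prey_species, params):
        ref = next(
            r
            for r in small_db
            if r.marker == "12S" and r.lineage.species == prey_species[0]
        )
        result = run_pipeline([ref.sequence] * 20, small_db, params, "12S")
        assert result.profile.taxa == {prey_species[0]}

    def test_18s_mode_assigns_classes(self, params):
        from preyid import simulate_reference_db

        db18 = simulate_reference_db(seed=11, include_outgroup=True, markers=("18S",))
        prey = sorted(
            r.lineage.species
            for r in db18
            if r.lineage.species not in (HOST_SPECIES, OUTGROUP_SPECIES)
        )
        comm = SimulatedCommunity(
            prey_fractions={prey[0]: 0.5, OUTGROUP_SPECIES: 0.5},
            host_fraction=0.5, n_reads=600, error_rate=0.0, seed=23,
        )
        sample = simulate_sample(comm, db18, "18S")
        result = run_pipeline(sample.pairs, db18, params, "18S", sample_id="SF4")
        # fish prey -> Actinopterygii, bait shrimp -> Malacostraca
        assert "Actinopterygii (class)" in result.profile.counts
        assert "Malacostraca (class)" in result.profile.counts
        methods = {i.method for i in result.identifications}
        assert methods <= {Method.HOST, Method.CLASS_LEVEL}

    def test_method_counts_partition_otus(self, small_db, prey_species, params):
        comm = SimulatedCommunity(
            prey_fractions={s: 1 / len(prey_species) for s in prey_species},
            host_fraction=0.3, n_reads=1200, error_rate=0.01, seed=24,
        )
        sample = simulate_sample(comm, small_db, "12S")
        result = run_pipeline(sample.pairs, small_db, params, "12S")
        assert sum(result.log["method_counts"].values()) == len(result.identifications)
        assert result.log["n_otus_kept"] == len(result.identifications)
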