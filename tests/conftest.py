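"""Shared fixtures: small simulated databases and hand-built lineages."""
from __future__ import annotations

import pytest

from preyid import Lineage, PipelineParams, simulate_reference_db
from preyid.simulate import HOST_SPECIES


def make_lineage(
    kingdom="Animalia",
    class_="Actinopterygii",
    order=None,
    family=None,
    genus=None,
    species=None,
    phylum=None,
):
    return Lineage(
        kingdom=kingdom,
        phylum=phylum,
        class_=class_,
        order=order,
        family=family,
        genus=genus,
        species=species,
    )


@pytest.fixture(scope="session")
def small_db():
    """2 orders x 2 genera x 2 species + host, 12S and 16S."""
    return simulate_reference_db(
        n_orders=2, genera_per_order=2, species_per_genus=2, seed=11
    )


@pytest.fixture(scope="session")
def prey_species(small_db):
    return sorted(
        {
            r.lineage.species
            for r in small_db
            if r.marker == "12S" and r.lineage.species != HOST_SPECIES
        }
    )


@pytest.fixture
def params():
    return PipelineParams(host_species=HOST_SPECIES)
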