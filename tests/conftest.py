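import numpy as np
import pandas as pd
import pytest

from ssrcore.genotype_io import GenotypeDataset
from ssrcore.synthetic_data import SimConfig, simulate_dataset


def make_ds(cells, species=None, pops=None, coords=None):
    """Build a small GenotypeDataset from {accession: {locus: set-of-sizes}}.

    Unspecified metadata defaults to one population/species; ``species`` and
    ``pops`` map accession -> label; ``coords`` maps accession -> (lon, lat).
    """
    accs = list(cells)
    loci = sorted({l for bands in cells.values() for l in bands})
    calls = pd.DataFrame(
        {l: [frozenset(cells[a].get(l, ())) for a in accs] for l in loci},
        index=accs,
    )
    species = species or {}
    pops = pops or {}
    coords = coords or {}
    meta = pd.DataFrame(
        {
            "species_group": [species.get(a, "SP1") for a in accs],
            "population_id": [pops.get(a, "P1") for a in accs],
            "province": "test",
            "longitude": [coords.get(a, (0.0, 0.0))[0] for a in accs],
            "latitude": [coords.get(a, (0.0, 0.0))[1] for a in accs],
        },
        index=pd.Index(accs, name="accession_id"),
    )
    return GenotypeDataset(calls, meta)


@pytest.fixture(scope="session")
def small_sim():
    """A small structured dataset with complete data (fast, deterministic)."""
    cfg = SimConfig(
        n_species=2,
        pops_per_species=3,
        accessions_per_pop=6,
        n_loci=8,
        alleles_per_locus=(4, 8),
        fst_species=0.3,
        fst_pop=0.15,
        inbreeding_f=1.0,
        missing_rate=0.0,
        ibd_scale=None,
        seed=42,
    )
    ds, truth = simulate_dataset(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def messy_sim():
    """A dataset with missing cells and partial heterozygosity."""
    cfg = SimConfig(
        n_species=2,
        pops_per_species=3,
        accessions_per_pop=8,
        n_loci=10,
        alleles_per_locus=(4, 10),
        fst_species=0.3,
        fst_pop=0.15,
        inbreeding_f=0.8,
        missing_rate=0.25,
        ibd_scale=400.0,
        seed=7,
    )
    ds, truth = simulate_dataset(cfg)
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
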