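import pytest

from genefam.curation import (CurationParams, DomainModel, assign_names,
                              curate_family, scan_domains)
from genefam.simulate import SimulationConfig, simulate_family_genomes


@pytest.fixture(scope="session")
def sim_cfg() -> SimulationConfig:
    return SimulationConfig(rng_seed=1)


@pytest.fixture(scope="session")
def genomes(sim_cfg):
    """Default synthetic two-genome dataset with ground truth."""
    return simulate_family_genomes(sim_cfg)


@pytest.fixture(scope="session")
def curated(sim_cfg, genomes):
    """Curated, named family members of both genomes."""
    bundle_a, bundle_b, truth = genomes
    model = DomainModel("DOM00001", sim_cfg.domain_consensus)
    params = CurationParams()
    out = []
    for bundle, prefix in ((bundle_a, "Gaa"), (bundle_b, "Gbb")):
        hits = scan_domains(list(bundle.proteins.values()), model, params)
        members, report = curate_family(bundle.genes, bundle.proteins,
                                        bundle.cds, hits, params)
        assign_names(members, prefix, "FAM")
        out.append((members, report))
    return out[0], out[1]
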