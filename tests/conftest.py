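import pytest

from txpolish import synthio


@pytest.fixture(scope="session")
def cleanup_fixture():
    """500 contigs with planted adapters (10%), bacterial (20%) and no-hit (10%)
    truth labels, plus the consistent hit tables and taxonomy map."""
    contigs, manifest = synthio.make_contigs(500, seed=11)
    contigs, ref_hits, nt_hits, taxonomy, manifest = synthio.plant_contaminants(
        contigs,
        bacterial_fraction=0.2,
        no_hit_fraction=0.1,
        seed=12,
        manifest=manifest,
    )
    contigs, manifest = synthio.plant_adapters(
        contigs, rate=0.1, seed=13, manifest=manifest
    )
    return contigs, ref_hits, nt_hits, taxonomy, manifest


@pytest.fixture(scope="session")
def planted_orf_fixture():
    """200 contigs each carrying one verified maximal Met-initiated CDS."""
    return synthio.plant_orfs(200, seed=21)
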