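import pytest

from velvet_grn import RunConfig, SimConfig, run_pipeline, simulate


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small simulated study (120 genes) shared across tests."""
    cfg = SimConfig(n_genes=120, rng_seed=7)
    out = tmp_path_factory.mktemp("bundle")
    paths, truth = simulate(cfg, out)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    """Full pipeline result on the small bundle."""
    cfg, paths, truth = small_bundle
    rc = RunConfig(
        genome_fasta=str(paths["genome"]),
        gene_models=str(paths["genes_tsv"]),
        peaks_a=str(paths["peaks_a"]),
        peaks_b=str(paths["peaks_b"]),
        de_a=str(paths["de_a"]),
        de_b=str(paths["de_b"]),
        string_links=str(paths["links"]),
        aliases=str(paths["aliases"]),
        gmt=str(paths["gmt"]),
        regulator_a=cfg.regulator_a,
        regulator_b=cfg.regulator_b,
        rng_seed=1,
        outdir=str(tmp_path_factory.mktemp("run")),
    )
    return rc, run_pipeline(rc)
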