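import pytest
import yaml

from netgba.pipeline import RunConfig, run_pipeline
from netgba.synthdata import SyntheticConfig, write_fixture_bundle


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """Synthetic fixture bundle at the default benchmark conditions."""
    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(SyntheticConfig(rng_seed=1), out)
    return out


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    """Full pipeline run on the synthetic bundle; returns the report dir.

    The seed-degree filter is scaled to the synthetic interactome's density
    (mean degree ~7 vs the orders-of-magnitude denser curated databases the
    default of 25 is calibrated for).
    """
    out = tmp_path_factory.mktemp("run")
    run = {
        "interactome": "interactome.tsv",
        "known_genes": "known_genes.txt",
        "tf_list": "tf_list.txt",
        "gmt": "genesets.gmt",
        "datasets": {
            "synth": {
                "matrices": {f"T{i}": f"expression_T{i}.tsv" for i in (1, 2, 3)},
                "metadata": "metadata.tsv",
            }
        },
        "out_dir": str(out),
        "min_global_degree": 5,
    }
    cfg_path = bundle_dir / "run.yaml"
    cfg_path.write_text(yaml.safe_dump(run))
    run_pipeline(RunConfig.from_yaml(cfg_path))
    return out
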