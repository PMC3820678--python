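import pytest

from combichip.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A modest bundle with decoys, reused across read-only tests."""
    cfg = SyntheticConfig(
        seed=42,
        n_promoters=400,
        sex_decoy_frac=0.02,
        nrun_decoy_frac=0.01,
        dup_decoy_count=12,
    )
    bundle, truth = generate_dataset(cfg)
    return bundle, truth


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    from combichip.synthetic_data import write_bundle

    bundle, truth = small_bundle
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(bundle, truth, outdir)
    return outdir, paths
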