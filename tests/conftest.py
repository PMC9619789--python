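import pytest

from biobank_omop.pipeline import run_pipeline
from biobank_omop.synthetic import GeneratorConfig, generate_bundle
from biobank_omop.vocabulary import load_vocabulary


@pytest.fixture(scope="session")
def small_config():
    # small bundle exercising every pathology: rejected participants,
    # unmappable-only COVID cases, a planted unit-domain defect
    return GeneratorConfig(n_participants=60, seed=11,
                           covid_prevalence=0.2, unmappable_case_rate=0.15,
                           missing_yob_rate=0.02, n_withdrawn=1,
                           unit_domain_mismatch_count=1)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("bundle_small")
    gt = generate_bundle(small_config, out)
    return out, gt


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_bundle):
    bundle_dir, _ = small_bundle
    out = tmp_path_factory.mktemp("run_small")
    manifest = run_pipeline(bundle_dir, out)
    return out, manifest


@pytest.fixture(scope="session")
def vocab_store(small_bundle):
    bundle_dir, _ = small_bundle
    v = bundle_dir / "vocabulary"
    return load_vocabulary(v / "concepts.csv", [v / "crossmaps.csv"],
                           [v / "custom_maps.csv"])
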