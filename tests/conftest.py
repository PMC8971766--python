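import pytest

from mutanome2vax import pipeline, synthetic_data


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the default study conditions, shared by all
    recovery tests: (report, out_dir, truth manifest)."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = synthetic_data.SimulationConfig(seed=11)
    report = pipeline.run_pipeline(cfg, out)
    truth = synthetic_data.read_manifest(out / "truth_manifest.json")
    return report, out, truth


@pytest.fixture(scope="session")
def default_repertoires():
    """Repertoire set plus planted truth at the default study conditions."""
    cfg = synthetic_data.SimulationConfig(seed=11)
    antigens = [f"G{i}" for i in range(1, 6)]
    return synthetic_data.generate_repertoires(cfg, antigens)
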