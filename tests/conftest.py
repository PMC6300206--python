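import pytest

from fishsurvey.dwc import SpecimenRecord
from fishsurvey.pipeline import PipelineConfig, run_pipeline
from fishsurvey.simulate import GeneratorConfig, GroundTruthManifest, write_bundle


def make_record(record_id="r1", recordset_id="rs1", **kwargs) -> SpecimenRecord:
    return SpecimenRecord(record_id=record_id, recordset_id=recordset_id, **kwargs)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Synthetic recordset bundle at the generator's stated defaults
    (10 collections, ~20k fish lots, contaminants and decoys present)."""
    config = GeneratorConfig(seed=7)
    out = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(config, out)
    manifest = GroundTruthManifest.from_json(paths["manifest"].read_text(encoding="utf-8"))
    return config, paths, manifest


@pytest.fixture(scope="session")
def pipeline_run(default_bundle, tmp_path_factory):
    """Full pipeline run over the default synthetic bundle."""
    _config, paths, manifest = default_bundle
    out = tmp_path_factory.mktemp("run")
    pc = PipelineConfig(
        occurrences=paths["occurrences"],
        catalog=paths["catalog"],
        registry=paths["registry"],
        merge_rules=paths["merge_rules"],
        baseline=paths["baseline"],
        out_dir=out,
    )
    result = run_pipeline(pc)
    return pc, result, manifest
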