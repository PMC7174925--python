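import pytest
from hypothesis import settings

from msgddi import ExperimentConfig, GenParams, Report, ReportCorpus, TrainParams, run_pipeline

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def tiny_corpus() -> ReportCorpus:
    """Six reports over two planted drug/reaction groups."""
    reps = [
        Report(("D1", "D2"), ("R1", "R2")),
        Report(("D1",), ("R1", "R3")),
        Report(("D2",), ("R2",)),
        Report(("D3", "D4"), ("R4", "R5")),
        Report(("D3",), ("R4",)),
        Report(("D4",), ("R5", "R4")),
    ]
    return ReportCorpus(tuple(reps))


def planted_experiment_config(seed: int) -> ExperimentConfig:
    """The strong-signal synthetic study conditions used for recovery checks."""
    return ExperimentConfig(
        gen=GenParams(
            n_classes=5,
            drugs_per_class=40,
            n_reports=2000,
            signal=0.9,
            noise_rate=0.1,
        ),
        train=TrainParams(dim=50, epochs=5, min_count=5),
        pca_dim=50,
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted_runs(tmp_path_factory):
    """Two identical full-pipeline runs at the planted-signal conditions.

    Shared across the recovery and determinism checks so the pipeline
    executes exactly twice for the whole suite.
    """
    cfg = planted_experiment_config(seed=1)
    d1 = tmp_path_factory.mktemp("planted_run1")
    d2 = tmp_path_factory.mktemp("planted_run2")
    res1 = run_pipeline(cfg, str(d1))
    res2 = run_pipeline(cfg, str(d2))
    return res1, res2
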