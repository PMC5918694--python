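"""Shared fixtures: a small simulated cohort and a classifier trained on it.

Session-scoped so the expensive pipeline run is paid once; tests must not
mutate these objects.
"""

import pandas as pd
import pytest

import pathscore as ps

SMALL_GRID = ps.TrainingConfig(alpha_grid=(0.1,), l1_ratio_grid=(0.15,), seed=7)


@pytest.fixture(scope="session")
def small_cohort() -> ps.SimulatedCohort:
    config = ps.SimulationConfig(
        n_samples=400,
        n_genes=300,
        n_signal_genes=40,
        effect_size=1.0,
        seed=123,
    )
    return ps.simulate_cohort(config)


@pytest.fixture(scope="session")
def small_result(small_cohort) -> ps.PipelineResult:
    return ps.train_pipeline(
        small_cohort.expression,
        small_cohort.mutations,
        small_cohort.copy_number,
        small_cohort.covariates,
        small_cohort.spec,
        SMALL_GRID,
    )


@pytest.fixture()
def cohort_dir(tmp_path, small_cohort):
    """The small cohort written out as the four TSV files."""
    small_cohort.expression.to_tsv(tmp_path / "expression.tsv")
    small_cohort.mutations.to_tsv(tmp_path / "mutations.tsv")
    small_cohort.copy_number.to_tsv(tmp_path / "copy_number.tsv")
    small_cohort.covariates.to_tsv(tmp_path / "covariates.tsv")
    return tmp_path


@pytest.fixture()
def tiny_model() -> ps.ClassifierModel:
    return ps.ClassifierModel(
        gene_weights={"GA": 0.5, "GB": -0.25, "GC": 0.0},
        covariate_weights={"LUAD": 0.1, "log10_mut": 0.2},
        intercept=-1.0,
        alpha=0.1,
        l1_ratio=0.15,
        feature_means={"GA": 1.0, "GB": -2.0, "GC": 0.0, "log10_mut": 1.5},
        feature_sds={"GA": 2.0, "GB": 0.5, "GC": 1.0, "log10_mut": 0.4},
        target_spec=ps.GeneTargetSpec(oncogenes=("KRAS",)),
        metadata={"seed": "7"},
    )
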