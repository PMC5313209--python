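"""Shared fixtures: one session-scoped simulated run + pipeline report."""

from __future__ import annotations

import pytest

from srnagradient.pipeline import PipelineConfig, run_all
from srnagradient.simulate import SimulationConfig, simulate_run

SIM_SEED = 20230701


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("simdata")
    return simulate_run(SimulationConfig(seed=SIM_SEED), out)


@pytest.fixture(scope="session")
def pipeline_report(sim_run, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig(
        fastq={lib: str(p) for lib, p in sim_run.fastq.items()},
        mature=str(sim_run.mature),
        genome=str(sim_run.genome),
        transcripts=str(sim_run.transcripts),
        references={k: str(v) for k, v in sim_run.references.items()},
        ct_table=str(sim_run.ct_table),
        out_dir=str(out),
    )
    return run_all(cfg)
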