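"""Shared fixtures; the expensive sampling runs are session-scoped."""

import numpy as np
import pytest

from pathmetad.fixtures import DoubleWellSpec, double_well_system
from pathmetad.metad_engine import IdentityCV, WTMetaDParams, run_wtmetad
from pathmetad.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def double_well_run():
    """One long WT-MetaD run on the 1-D double well, reused by several tests."""
    spec = DoubleWellSpec()
    system = double_well_system(spec)
    params = WTMetaDParams(initial_height=0.2, bias_factor=15.0,
                           sigma=(0.1,), pace=250, wall_position=None)
    hills, colvar = run_wtmetad(system, IdentityCV((0,)), params,
                                n_steps=800_000, seed=11, dt=0.005,
                                x0=np.array([-spec.half_separation]),
                                stride=100)
    return spec, params, hills, colvar


@pytest.fixture(scope="session")
def funnel_runs(tmp_path_factory):
    """Full pipeline runs on the built-in funnel toy, three seeds."""
    runs = {}
    for seed in (1, 2, 3):
        outdir = tmp_path_factory.mktemp(f"funnel_seed{seed}")
        result = run_pipeline(PipelineConfig(seed=seed, outdir=str(outdir)))
        runs[seed] = (result, outdir)
    return runs
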