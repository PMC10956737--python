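"""Standard synthetic benchmark runs shared by the test suite and the
acceptance script.

Each benchmark fixes its synthetic study conditions (scenario preset, data
seed, durations) and derives the training and held-out evaluation seeds
from a single user seed, then runs the full desk-profile pipeline and
returns the held-out probe-error summary.
"""

from __future__ import annotations

import numpy as np

from .pipeline import EvaluationReport, RunConfig, run_pipeline

__all__ = ["benchmark_config", "run_benchmark", "BENCHMARKS"]

# (scenario preset, fixed data seed) per benchmark condition
BENCHMARKS = {
    "in_vivo": ("in_vivo", 42),
    "phantom": ("phantom", 7),
    "in_vitro": ("in_vitro", 11),
}


def derived_seeds(seed: int, n: int = 2):
    """Deterministic child seeds (< 2**31) from one user seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def benchmark_config(name: str, seed: int, out_dir: str | None = None) -> RunConfig:
    scenario_name, data_seed = BENCHMARKS[name]
    train_seed, eval_offset = derived_seeds(seed)
    cfg = RunConfig.preset(scenario_name)
    cfg.profile = "desk"
    cfg.epochs = 20
    cfg.data_seed = data_seed
    cfg.eval_seed = data_seed + 1 + eval_offset % 10_000   # held-out run, distinct noise
    cfg.train_seed = train_seed
    if out_dir is not None:
        cfg.out_dir = out_dir
    else:
        cfg.out_dir = f"scratch/benchmarks/{name}_seed{seed}"
    return cfg


def run_benchmark(name: str, seed: int, out_dir: str | None = None) -> EvaluationReport:
    """Full desk-profile pipeline for one benchmark condition."""
    return run_pipeline(benchmark_config(name, seed, out_dir))
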