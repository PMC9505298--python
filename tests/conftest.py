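"""Shared fixtures: a small synthetic dataset and a finished pipeline run.

Everything is generated programmatically at test time from seeded
configurations; no stored data files are used.
"""

from __future__ import annotations

import warnings

import pytest
from hypothesis import HealthCheck, settings

from pasite.pipeline import RunConfig, run_all
from pasite.simulate import SimConfig, simulate_all

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


SMALL_SIM = dict(seed=42, n_chromosomes=1, chrom_length=250_000, n_genes=50,
                 reads_per_site=10)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small but fully featured synthetic dataset (jitter and decoys on)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_all(SimConfig(**SMALL_SIM),
                            tmp_path_factory.mktemp("small_sim"))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A full pipeline run over the small synthetic dataset."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = RunConfig(out_dir=str(out), sim=SimConfig(**SMALL_SIM))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(cfg)


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Jitter-free, error-free run: every cleavage coordinate is exactly
    recoverable and every cluster has a single member position."""
    out = tmp_path_factory.mktemp("noiseless_run")
    cfg = RunConfig(out_dir=str(out),
                    sim=SimConfig(seed=7, n_chromosomes=1, chrom_length=250_000,
                                  n_genes=50, reads_per_site=6,
                                  cs_jitter_sd=0.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(cfg)
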