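"""Shared fixtures: scaled-down synthetic studies for fast unit tests.

The scaled study keeps every distributional parameter at its default value
and only reduces the per-condition ROI count, so all structural properties
of full-size studies hold.
"""

from dataclasses import replace

import pytest

from glycopap import PipelineConfig, default_config, generate_study, run_full_analysis


def scaled_config(n_rois: int = 40):
    return {c: replace(p, n_rois=n_rois) for c, p in default_config().items()}


@pytest.fixture(scope="session")
def small_config():
    return scaled_config(40)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config, seed=42)


@pytest.fixture(scope="session")
def small_report(small_study):
    return run_full_analysis(small_study, PipelineConfig())
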