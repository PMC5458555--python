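import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mxfret import (
    get_preset,
    simulate_dataset,
    qc_select,
    correct_bleedthrough,
    compute_fret,
)


def process_dataset(dataset, bleedthrough=0.075, params=None):
    """QC + bleed correction + FRET for every passing trace of a dataset.

    Returns a list of dicts with the raw trace, corrected trace, FRET trace,
    ground truth and QC result — the common front half of most round-trip
    tests.
    """
    out = []
    for trace, truth in zip(dataset.traces, dataset.ground_truths):
        result = qc_select(trace, params)
        if not result.passed:
            continue
        corrected = correct_bleedthrough(trace, bleedthrough)
        fret = compute_fret(
            corrected, result.analysis_end, result.bg_sd_donor, result.bg_sd_acceptor
        )
        out.append(
            {
                "trace": trace,
                "corrected": corrected,
                "fret": fret,
                "truth": truth,
                "qc": result,
            }
        )
    return out


@pytest.fixture(scope="session")
def gmppcp_dataset():
    """Mid-size dynamic two-state dataset shared across unit tests."""
    return simulate_dataset(get_preset("AS_GMPPCP"), 80, seed=11)


@pytest.fixture(scope="session")
def gmppcp_items(gmppcp_dataset):
    return process_dataset(gmppcp_dataset)


@pytest.fixture(scope="session")
def apo_dataset():
    return simulate_dataset(get_preset("AS_apo"), 80, seed=12)


@pytest.fixture(scope="session")
def apo_items(apo_dataset):
    return process_dataset(apo_dataset)
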