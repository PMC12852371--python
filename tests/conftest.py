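"""Shared phantom fixtures.

Heavy phantom analyses are session-scoped: each scenario is generated and
measured once and reused by unit and acceptance tests alike.
"""

from __future__ import annotations

import numpy as np
import pytest

from atriometry import compute_all_metrics, generate_phantom
from atriometry.grading import grade_case
from atriometry.labelmap import postprocess_labels, resample_isotropic
from atriometry.phantom import PhantomSpec, phantom_catalog


@pytest.fixture(scope="session")
def default_phantom():
    """(LabelMap, GroundTruth) of the default scenario at 0.5 mm isotropic."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_iso_map(default_phantom):
    """Default phantom after the pipeline's resample + label cleanup."""
    lm, _ = default_phantom
    return postprocess_labels(resample_isotropic(lm, 0.5))


@pytest.fixture(scope="session")
def default_report(default_phantom):
    lm, _ = default_phantom
    return compute_all_metrics(lm)


@pytest.fixture(scope="session")
def catalog_results():
    """name -> (spec, GroundTruth, MetricReport, UsabilityGrade) for all scenarios."""
    out = {}
    for name, spec in phantom_catalog().items():
        lm, gt = generate_phantom(spec)
        report = compute_all_metrics(lm)
        out[name] = (spec, gt, report, grade_case(report))
    return out


def relerr(measured: float, truth: float) -> float:
    return abs(measured - truth) / abs(truth)
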