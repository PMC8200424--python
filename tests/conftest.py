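"""Shared fixtures.

The scaled study (3 synthetic patients, full error grid, both detectors,
four criteria, native + 1 mm resolutions) takes a couple of minutes and is
shared session-wide by the acceptance and study-property tests.  Its seed is
fixed so every derived assertion is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import qasense as q
from qasense.study import StudyConfig, run_study

SCALED_SEED = 20260917  # fixed once; all study assertions are deterministic


@pytest.fixture(scope="session")
def plan1():
    return q.generate_patient_plan(1, target_diameter=35.0, n_control_points=24)


@pytest.fixture(scope="session")
def rendered1(plan1):
    """Composite dose of plan 1 on a grid covering both detector footprints."""
    return q.render_composite_dose(plan1, extent=(664.0, 212.0))


@pytest.fixture(scope="session")
def array_spec():
    return q.build_arccheck_lattice()


@pytest.fixture(scope="session")
def panel_spec():
    return q.build_epid_panel()


@pytest.fixture(scope="session")
def scaled_config():
    return StudyConfig(n_patients=3, master_seed=SCALED_SEED)


@pytest.fixture(scope="session")
def scaled_study(scaled_config):
    """The 3-patient scaled study result (records + manifest)."""
    return run_study(scaled_config)


@pytest.fixture(scope="session")
def scaled_records(scaled_study):
    rec = scaled_study.records
    assert (rec["failure"] == "").all(), "scaled study produced failure rows"
    return rec


def smooth_random_dose(rng: np.random.Generator, n: int = 16, spacing: float = 2.0):
    """A smooth positive test field: Gaussian blob + seeded low-freq ripple."""
    ax = spacing * (np.arange(n) - (n - 1) / 2.0)
    xx, yy = np.meshgrid(ax, ax)
    blob = np.exp(-(xx**2 + yy**2) / (2 * (0.3 * n * spacing) ** 2))
    ripple = 0.1 * np.sin(xx / 7.0 + rng.uniform(0, 6)) * np.cos(yy / 9.0 + rng.uniform(0, 6))
    vals = np.clip(blob * (1 + ripple), 0, None)
    return q.DoseMatrix(vals, spacing, (float(ax[0]), float(ax[0])))
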