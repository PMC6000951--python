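"""Shared fixtures: recalibration curve, medium runs, dose-matched runs."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from ionrad.clusters import RecalibrationCurve
from ionrad.config import ArtifactConfig, BeamSpec, RunConfig
from ionrad.imaging import fluence_for_dose
from ionrad.simulate import energy_response, simulate_run


def make_recal_curve() -> RecalibrationCurve:
    """Analysis-side inverse of the 10 V partial-depletion response."""
    true = np.linspace(0.05, 18.0, 256)
    measured = np.array([energy_response(t, 10.0) for t in true])
    return RecalibrationCurve(measured, true)


@pytest.fixture(scope="session")
def recal_curve() -> RecalibrationCurve:
    return make_recal_curve()


def imaging_config(half_y_mm: float = 3.0, species: str = "helium",
                   energy: float = 168.3) -> RunConfig:
    """Uniform-field step-phantom run restricted in y to keep runtimes sane."""
    cfg = RunConfig(beam=BeamSpec(species=species, energy_per_nucleon=energy,
                                  profile="uniform", half_width_x_mm=6.0,
                                  half_width_y_mm=half_y_mm))
    if species == "proton":
        cfg.artifacts.fragmentation_probability = 0.0
    return cfg


def ions_for_dose(cfg: RunConfig, dose_ugy: float) -> int:
    phi = fluence_for_dose(cfg.beam, cfg.phantom, dose_ugy)
    area_cm2 = (2 * cfg.beam.half_width_x_mm / 10.0) \
        * (2 * cfg.beam.half_width_y_mm / 10.0)
    return int(round(phi * area_cm2))


@pytest.fixture(scope="session")
def medium_run():
    """6k-primary default run shared by event/imaging tests."""
    cfg = RunConfig()
    return cfg, simulate_run(cfg, seed=42, n_ions_total=6000)


@pytest.fixture(scope="session")
def diagnostic_dose_run(recal_curve):
    """Step-phantom acquisition at the 450 uGy diagnostic dose level.

    The primary count is fixed by the fluence that deposits 450 uGy in the
    phantom over the simulated field; the stage-wise quality table is
    computed once and shared by the acceptance tests.
    """
    from ionrad.quality import stage_comparison

    cfg = imaging_config()
    n = ions_for_dose(cfg, 450.0)
    res = simulate_run(cfg, seed=450, n_ions_total=n)
    stages = stage_comparison(res.frames, cfg, recalibration=recal_curve,
                              dose_ugy=450.0)
    return cfg, res, stages
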