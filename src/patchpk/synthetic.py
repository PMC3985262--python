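"""Synthetic clinical sampling of the model trajectories.

Real validation data for the patch are sparse serum samples with assay
error roughly proportional to the measured level.  This module emulates
that: model concentrations at chosen sampling times, perturbed by
multiplicative lognormal noise with unit mean and a chosen coefficient
of variation.  Every estimation and metrics routine in the package is
exercisable on this output alone, so parameter-recovery behaviour can be
tested without any external data.

The default schedule samples every 12 h during the three wear weeks and
every 6 h during the post-removal decay, mirroring the resolution of
published weekly-cycle concentration profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model import ConcentrationSeries, analytic_concentrations
from .params import DrugParams
from .regimen import Regimen

__all__ = ["SamplingDesign", "generate_observations", "default_sample_times"]

DEFAULT_NOISE_CV = 0.05


def default_sample_times(removal_h: float = 504.0, horizon_h: float = 600.0,
                         wear_step_h: float = 12.0,
                         decay_step_h: float = 6.0) -> np.ndarray:
    """Sparse clinical schedule: 12 h steps while worn, 6 h in the decay tail."""
    wear = np.arange(0.0, removal_h, wear_step_h)
    decay = np.arange(removal_h, horizon_h + 1e-9, decay_step_h)
    return np.concatenate([wear, decay])


@dataclass(frozen=True)
class SamplingDesign:
    """A reproducible synthetic sampling plan.

    Identical designs (same seed included) produce bit-identical series.
    """

    params: DrugParams
    regimen: Regimen
    sample_times: np.ndarray
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int = 0
    c0: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.sample_times, dtype=float)
        object.__setattr__(self, "sample_times", times)
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if times.size == 0:
            raise ValueError("sample_times must be non-empty")
        if np.any(times < 0) or np.any(times > self.regimen.horizon):
            raise ValueError("sample_times must lie within the regimen horizon")

    def sidecar(self) -> dict:
        """Provenance record (JSON-serialisable) describing this design."""
        return {
            "hormone": self.params.name,
            "noise_cv": self.noise_cv,
            "seed": self.seed,
            "c0": self.c0,
            "n_samples": int(self.sample_times.size),
            "t_first": float(self.sample_times.min()),
            "t_last": float(self.sample_times.max()),
        }


def generate_observations(design: SamplingDesign) -> ConcentrationSeries:
    """Noisy observations C_obs(t_i) = C_model(t_i) * eps_i.

    eps_i is lognormal with mean 1 and coefficient of variation
    ``noise_cv``: sigma^2 = ln(1 + cv^2), mu = -sigma^2 / 2.  With
    ``noise_cv = 0`` the output equals the closed-form model exactly.
    """
    times = np.sort(design.sample_times, kind="stable")
    clean = analytic_concentrations(design.params, design.regimen, times,
                                    design.c0)
    if design.noise_cv == 0.0:
        values = clean
    else:
        sigma2 = np.log1p(design.noise_cv ** 2)
        sigma = np.sqrt(sigma2)
        rng = np.random.default_rng(design.seed)
        eps = rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=times.size)
        values = clean * eps
    return ConcentrationSeries(times, values, design.params.conc_unit,
                               design.params.name)


def write_sidecar(design: SamplingDesign, path) -> None:
    """Echo the design into a JSON provenance sidecar next to the CSV."""
    with open(path, "w") as fh:
        json.dump(design.sidecar(), fh, indent=2)
        fh.write("\n")
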