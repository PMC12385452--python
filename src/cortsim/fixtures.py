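"""Seeded synthetic fixtures for testing the analysis machinery.

These generators emulate the two kinds of data the analysis stack
consumes, without running the simulator: labeled ensembles of scalar
firing-rate samples (for the information metrics) and bimodal
membrane-potential samples (for Up-state mode extraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .info import LabeledSamples

__all__ = ["FixtureSpec", "BimodalSpec", "gaussian_class_samples",
           "bimodal_potential_samples"]


@dataclass(frozen=True)
class FixtureSpec:
    """Gaussian class ensemble: one (mean, sd) pair per class."""

    means: tuple
    sds: tuple
    n_per_class: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.means) != len(self.sds):
            raise ValueError("means and sds must align")
        if any(s < 0 for s in self.sds):
            raise ValueError("standard deviations must be non-negative")
        if self.n_per_class < 1:
            raise ValueError("need at least one sample per class")


def gaussian_class_samples(spec: FixtureSpec) -> LabeledSamples:
    """Draw exactly ``n_per_class`` seeded samples per class."""
    rng = np.random.default_rng(spec.seed)
    groups = [rng.normal(m, s, spec.n_per_class) for m, s in zip(spec.means, spec.sds)]
    return LabeledSamples.from_arrays(*groups)


@dataclass(frozen=True)
class BimodalSpec:
    """Two-component Gaussian mixture of membrane potentials (mV)."""

    means: tuple = (-70.0, -58.0)
    sds: tuple = (1.0, 1.0)
    weights: tuple = (0.5, 0.5)
    n_samples: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to one")


def bimodal_potential_samples(spec: BimodalSpec = BimodalSpec()) -> np.ndarray:
    """Seeded draw from a two-component Gaussian mixture."""
    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.n_samples, spec.weights)
    parts = [rng.normal(m, s, n) for (m, s, n) in zip(spec.means, spec.sds, counts)]
    out = np.concatenate(parts)
    rng.shuffle(out)
    return out
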