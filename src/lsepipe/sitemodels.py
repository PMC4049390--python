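"""Site-class mixture specifications: M1a, M2a, M8a, M8.

Each model resolves to a discrete set of (weight, omega) site classes:

* M1a  - purifying class (omega0 < 1) + neutral class (omega = 1)
* M2a  - M1a + a positive-selection class (omega2 > 1)
* M8   - K-category discretised Beta(p, q) on (0, 1) + one class omega_s > 1
* M8a  - M8 with the extra class pinned at omega_s = 1
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

MODELS = ("M1a", "M2a", "M8a", "M8")

#: nested null -> alternative pairs with LRT degrees of freedom
NESTED_PAIRS = {("M1a", "M2a"): 2, ("M8a", "M8"): 1}

DEFAULT_BETA_CATEGORIES = 10


def discretize_beta(p: float, q: float, k: int = DEFAULT_BETA_CATEGORIES) -> np.ndarray:
    """k equal-probability category omegas for Beta(p, q), via quantile medians."""
    quantiles = (np.arange(k) + 0.5) / k
    omegas = beta_dist.ppf(quantiles, p, q)
    return np.clip(omegas, 1e-6, 1.0 - 1e-6)


@dataclass
class SiteModelSpec:
    """Resolved mixture: parallel arrays of class weights and omegas."""

    model: str
    weights: np.ndarray
    omegas: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.omegas = np.asarray(self.omegas, dtype=float)
        if self.weights.shape != self.omegas.shape:
            raise ValueError("weights and omegas differ in shape")
        if np.any(self.weights < -1e-12) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("class weights must be a probability vector")

    @property
    def positive_mask(self) -> np.ndarray:
        """Classes with omega strictly above 1."""
        return self.omegas > 1.0


def m1a(p0: float, omega0: float) -> SiteModelSpec:
    return SiteModelSpec(
        model="M1a",
        weights=[p0, 1.0 - p0],
        omegas=[omega0, 1.0],
        params={"p0": p0, "omega0": omega0},
    )


def m2a(p0: float, p1: float, omega0: float, omega2: float) -> SiteModelSpec:
    p2 = 1.0 - p0 - p1
    if p2 < -1e-12:
        raise ValueError("p0 + p1 must not exceed 1")
    return SiteModelSpec(
        model="M2a",
        weights=[p0, p1, max(p2, 0.0)],
        omegas=[omega0, 1.0, omega2],
        params={"p0": p0, "p1": p1, "p2": max(p2, 0.0),
                "omega0": omega0, "omega2": omega2},
    )


def m8(
    p0: float, p: float, q: float, omega_s: float,
    k: int = DEFAULT_BETA_CATEGORIES,
) -> SiteModelSpec:
    omegas = np.append(discretize_beta(p, q, k), omega_s)
    weights = np.append(np.full(k, p0 / k), 1.0 - p0)
    return SiteModelSpec(
        model="M8",
        weights=weights,
        omegas=omegas,
        params={"p0": p0, "p": p, "q": q, "omega_s": omega_s, "k": k},
    )


def m8a(p0: float, p: float, q: float, k: int = DEFAULT_BETA_CATEGORIES) -> SiteModelSpec:
    spec = m8(p0, p, q, 1.0, k)
    spec.model = "M8a"
    spec.params.pop("omega_s")
    return spec
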