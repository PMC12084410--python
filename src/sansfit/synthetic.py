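"""Seeded synthetic SANS curves with the statistical structure the
analysis assumes: a smooth form-factor signal on a log-spaced Q grid,
fractional Gaussian noise with an absolute floor, a flat background, and an
optional low-Q clustering upturn.

The module also ships the four reference scenarios used throughout the
package: dumbbell curves for the KaiC and ancestral anKaiC hexamers (the
published fitted geometries) and polymer excluded-volume curves for KaiA
and anKaiA (published radii of gyration, Porod exponent 3).  These stand in
for raw reduced measurements, which are deposited in an external archive
rather than printed; the noise convention (3% fractional, floor 1e-4 of
the forward intensity) is a declared choice plausible for hour-scale SANS
sessions, not a measured one.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .curves import ScatteringCurve
from .models import (DumbbellParams, PolymerEVParams, dumbbell_intensity,
                     polymer_ev_intensity)

__all__ = ["NoiseModel", "make_q_grid", "simulate_curve", "fixture_suite",
           "KAIC_DUMBBELL", "ANKAIC_DUMBBELL", "KAIA_POLYMER",
           "ANKAIA_POLYMER", "DEFAULT_BACKGROUND"]

# Published fitted geometries (lengths in A).  The hexamer double ring is
# two coaxial ellipsoid lobes with an axial channel.
KAIC_DUMBBELL = DumbbellParams(
    center_distance=50.0, polar_semiaxis=32.4, equatorial_semiaxis=44.5,
    hole_radius=16.8, scale=1.0, background=1e-3)
ANKAIC_DUMBBELL = DumbbellParams(
    center_distance=53.0, polar_semiaxis=35.4, equatorial_semiaxis=45.5,
    hole_radius=17.4, scale=1.0, background=1e-3)
# Published radii of gyration (nm); exponent 3 = loosely packed chain.
KAIA_POLYMER = PolymerEVParams(rg=3.4, porod_exponent=3.0,
                               scale=1.0, background=1e-3)
ANKAIA_POLYMER = PolymerEVParams(rg=8.6, porod_exponent=3.0,
                                 scale=1.0, background=1e-3)

DEFAULT_BACKGROUND = 1e-3


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise sigma_I = fractional * I + floor, seeded."""

    fractional: float = 0.03
    floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fractional < 0 or self.floor < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def noise_free(self) -> bool:
        return self.fractional == 0 and self.floor == 0


def make_q_grid(qmin: float = 0.005, qmax: float = 0.5, n: int = 100,
                spacing: str = "log") -> np.ndarray:
    """Strictly increasing Q grid (1/A); log-spaced by default."""
    if not 0 < qmin < qmax:
        raise ValueError("need 0 < qmin < qmax")
    if n < 2:
        raise ValueError("need n >= 2")
    if spacing == "log":
        return np.geomspace(qmin, qmax, n)
    if spacing == "linear":
        return np.linspace(qmin, qmax, n)
    raise ValueError(f"unknown spacing {spacing!r}")


def simulate_curve(model_id: str, params, q_grid, noise: NoiseModel,
                   label: str = "", n_alpha: int = 76,
                   n_z: int = 64) -> ScatteringCurve:
    """Model curve plus seeded Gaussian noise N(0, sigma_I).

    The sigma_I column records exactly the noise model's own sigma
    (fractional * I_model + floor).  With a noise-free model
    (fractional = floor = 0) the returned intensities are exactly the
    model values with sigma_I = 0.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if model_id == "dumbbell":
        clean = dumbbell_intensity(q_grid, params, n_alpha=n_alpha, n_z=n_z)
    elif model_id == "polymer_ev":
        clean = polymer_ev_intensity(q_grid, params)
    else:
        raise ValueError(f"unknown model {model_id!r}")
    sigma = noise.fractional * clean.I + noise.floor
    rng = np.random.default_rng(noise.seed)
    I = clean.I + rng.normal(0.0, 1.0, q_grid.size) * sigma
    meta = {"model": model_id, "seed": noise.seed,
            "noise_fractional": noise.fractional, "noise_floor": noise.floor}
    meta.update({k: float(v) for k, v in asdict(params).items()})
    return ScatteringCurve(q_grid, I, sigma, label=label, metadata=meta)


def fixture_suite(seed: int = 0, q_grid=None) -> dict[str, ScatteringCurve]:
    """The four reference scenarios, each as a noisy curve plus a
    noise-free twin.

    Returns a dict keyed ``kaic``, ``ankaic``, ``kaia``, ``ankaia`` and the
    same with ``_clean`` appended.  Noisy curves carry 3% fractional noise
    with the default floor; the clean twins have the model intensities but
    keep the same sigma_I column, so a fit at the generating parameters
    has chi2 = 0.
    """
    if q_grid is None:
        q_grid = make_q_grid()
    scenarios = {
        "kaic": ("dumbbell", KAIC_DUMBBELL),
        "ankaic": ("dumbbell", ANKAIC_DUMBBELL),
        "kaia": ("polymer_ev", KAIA_POLYMER),
        "ankaia": ("polymer_ev", ANKAIA_POLYMER),
    }
    out = {}
    for k, (name, (model_id, params)) in enumerate(scenarios.items()):
        noise = NoiseModel(seed=seed + k)
        noisy = simulate_curve(model_id, params, q_grid, noise, label=name)
        clean = simulate_curve(model_id, params, q_grid,
                               NoiseModel(0.0, 0.0, seed + k),
                               label=name + "_clean")
        clean = ScatteringCurve(clean.Q, clean.I, noisy.sigma_I,
                                label=clean.label, metadata=clean.metadata)
        out[name] = noisy
        out[name + "_clean"] = clean
    return out
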