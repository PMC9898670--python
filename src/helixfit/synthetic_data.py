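"""Synthetic experiments: noisy scattering curves and two-state melts.

Every stage of the analysis can be exercised without instrument data.  A
"synthetic experiment" starts from a known conformer (the truth), computes
its noise-free sphere-model curves per contrast -- hydrated for X-rays, dry
for neutrons in heavy water -- over the instrument-like window
Q = 0.04-4 nm^-1, and then applies multiplicative Gaussian noise whose
relative width grows linearly with Q, sigma(Q) = sigma_rel * I(Q) * (1 + c Q),
emulating the worsening counting statistics of real detectors at wide angle.
An optional Gaussian Q-resolution kernel is available for neutron-like
smearing.  Melting curves are two-state sigmoids between linear folded and
unfolded baselines.  All randomness flows from one seeded generator and the
stored truth is sufficient to regenerate the noise-free curves bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .helix_builder import TripleHelix
from .curve_analysis import MeltingCurve
from .scattering import (ScatteringCurve, add_hydration, coarse_grain,
                         debye_curve, default_q_grid)

__all__ = [
    "SyntheticExperiment", "NoiseParams", "make_synthetic_curves",
    "make_melting_curve", "smear_curve",
]


@dataclass(frozen=True)
class NoiseParams:
    sigma_rel: float = 0.02       # relative noise floor
    q_inflation: float = 0.5      # c in sigma = sigma_rel * I * (1 + c Q), per nm^-1

    def __post_init__(self):
        if not (0.0 <= self.sigma_rel <= 0.2):
            raise ValueError("sigma_rel must be within [0, 0.2]")
        if self.q_inflation < 0:
            raise ValueError("q_inflation must be >= 0")


@dataclass
class SyntheticExperiment:
    truth: TripleHelix
    truth_bend: float | None          # degrees, if known
    curves: dict[str, ScatteringCurve]         # keyed by contrast
    clean_curves: dict[str, ScatteringCurve]   # noise-free references
    noise: NoiseParams
    seed: int
    protein_mass: float


def _model_curve(truth: TripleHelix, contrast: str, protein_mass: float,
                 q: np.ndarray) -> ScatteringCurve:
    dry = coarse_grain(truth)
    if contrast == "hydrated":
        spheres = add_hydration(dry, protein_mass)
    elif contrast == "dry":
        spheres = dry
    else:
        raise ValueError(f"unknown contrast {contrast!r}; use 'hydrated' "
                         "(X-ray) or 'dry' (neutron)")
    return debye_curve(spheres, q, label=f"synthetic-{contrast}")


def make_synthetic_curves(truth: TripleHelix, protein_mass: float,
                          contrasts=("hydrated", "dry"),
                          noise: NoiseParams = NoiseParams(),
                          seed: int = 0,
                          q: np.ndarray | None = None,
                          truth_bend: float | None = None,
                          smear_sigma_q: float = 0.0) -> SyntheticExperiment:
    """Noisy SAXS/SANS-like curves from a known model.

    Returns per-contrast curves with a sigma column; sigma(Q) =
    sigma_rel * I(Q) * (1 + c Q).  ``smear_sigma_q`` > 0 additionally
    convolves the noise-free curve with a Gaussian Q-resolution kernel
    before noise is applied (neutron-like smearing).
    """
    if not contrasts:
        raise ValueError("at least one contrast is required")
    q = default_q_grid() if q is None else np.asarray(q, dtype=np.float64)
    rng = np.random.default_rng(seed)
    curves: dict[str, ScatteringCurve] = {}
    clean: dict[str, ScatteringCurve] = {}
    for contrast in contrasts:
        base = _model_curve(truth, contrast, protein_mass, q)
        if smear_sigma_q > 0:
            base = smear_curve(base, smear_sigma_q)
        sigma = noise.sigma_rel * base.i * (1.0 + noise.q_inflation * base.q)
        noisy = base.i + rng.normal(0.0, 1.0, len(q)) * sigma
        clean[contrast] = base
        curves[contrast] = ScatteringCurve(q, noisy, sigma, contrast,
                                           label=f"synthetic-{contrast}-noisy")
    return SyntheticExperiment(truth, truth_bend, curves, clean, noise, seed,
                               protein_mass)


def smear_curve(curve: ScatteringCurve, sigma_q: float) -> ScatteringCurve:
    """Gaussian Q-resolution smearing (simple fixed-width kernel)."""
    if sigma_q <= 0:
        return curve
    out = np.empty_like(curve.i)
    for k, q0 in enumerate(curve.q):
        w = np.exp(-0.5 * ((curve.q - q0) / sigma_q) ** 2)
        out[k] = np.sum(w * curve.i) / np.sum(w)
    return ScatteringCurve(curve.q, out, curve.sigma, curve.contrast,
                           curve.label + "-smeared")


def make_melting_curve(tm: float, *, t_range: tuple[float, float] = (0.0, 70.0),
                       n_points: int = 141, width: float = 1.5,
                       folded_baseline: tuple[float, float] = (10.0, -0.02),
                       unfolded_baseline: tuple[float, float] = (-4.0, -0.05),
                       noise_sd: float = 0.0, seed: int = 0,
                       label: str = "") -> MeltingCurve:
    """Two-state melting curve with linear baselines.

    ``folded_baseline``/``unfolded_baseline`` are (intercept, slope) pairs of
    the triple-helix and unfolded-monomer ellipticity; ``width`` (C) sets the
    transition steepness; F(T) = 1/(1+exp((T-Tm)/width)).  T_m must lie
    inside the temperature window with enough margin for both baselines.
    """
    t0, t1 = t_range
    if not (t0 + 2.0 * width < tm < t1 - 2.0 * width):
        raise ValueError(f"Tm={tm} C is outside (or too close to the edge of) "
                         f"the temperature window {t_range}")
    af, bf = folded_baseline
    au, bu = unfolded_baseline
    T = np.linspace(t0, t1, n_points)
    if np.allclose(af + bf * T, au + bu * T):
        raise ValueError("degenerate baselines: folded and unfolded ellipticity "
                         "coincide over the window")
    from scipy.special import expit
    f = expit(-(T - tm) / width)
    signal = f * (af + bf * T) + (1 - f) * (au + bu * T)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        span = abs(signal.max() - signal.min())
        signal = signal + rng.normal(0.0, noise_sd * span, n_points)
    return MeltingCurve(T, signal, label=label or f"synthetic-melt-Tm{tm}")
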