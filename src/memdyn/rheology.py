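"""Passive microrheology via the generalized Stokes–Einstein relation.

A probe particle of radius R_g (here: the mean lipid radius of gyration)
embedded in a viscoelastic medium has complex shear modulus

    |G*|(ω) ≈ k_B T / (π R_g MSD(1/ω) Γ[1 + α(ω)]),
    G′ = |G*| cos(π α(ω) / 2),   G″ = |G*| sin(π α(ω) / 2),

where α(ω) is the local logarithmic slope of the MSD evaluated at t = 1/ω.
For a fitted power law MSD = 6 D t^α the slope is constant and the moduli
scale as ω^α; a tabulated MSD path uses log-log interpolation and central
finite differences.  Moduli are reported in kPa from (Å, ns, K) inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

from .constants import ANGSTROM_M, KB_J_PER_K
from .dynamics import PowerLawFit

PA_PER_KPA = 1e3


@dataclass
class Moduli:
    omega: np.ndarray          # 1/ns
    alpha: np.ndarray          # local log-slope at t = 1/ω
    g_star_kpa: np.ndarray
    g_prime_kpa: np.ndarray
    g_double_prime_kpa: np.ndarray
    temperature: float
    probe_radius: float        # Å

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "omega_per_ns": self.omega, "alpha": self.alpha,
            "Gstar_kPa": self.g_star_kpa, "Gprime_kPa": self.g_prime_kpa,
            "Gdoubleprime_kPa": self.g_double_prime_kpa,
        })


def _msd_at(model, t):
    """MSD(t) in Å² for a PowerLawFit or tabulated MSDSeries."""
    t = np.asarray(t, dtype=float)
    if isinstance(model, PowerLawFit):
        return 6.0 * model.d_alpha * t ** model.alpha
    pos = (model.t > 0) & (model.msd > 0)
    lt, lm = np.log(model.t[pos]), np.log(model.msd[pos])
    if np.any(np.log(t) < lt[0]) or np.any(np.log(t) > lt[-1]):
        raise ValueError("1/omega outside the tabulated MSD range")
    return np.exp(np.interp(np.log(t), lt, lm))


def local_log_slope(model, omega) -> np.ndarray:
    """α(ω) = d ln MSD / d ln t at t = 1/ω.

    Analytic (constant) for a power-law fit; central finite difference on
    the log-log interpolated curve for tabulated series.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    if isinstance(model, PowerLawFit):
        return np.full(omega.shape, model.alpha)
    t = 1.0 / omega
    h = 1e-4
    up = _msd_at(model, t * np.exp(h))
    dn = _msd_at(model, t * np.exp(-h))
    return (np.log(up) - np.log(dn)) / (2 * h)


def default_omega_grid(model, n: int = 40) -> np.ndarray:
    """Log-spaced ω spanning the inverse of the model's time range (1/ns)."""
    if isinstance(model, PowerLawFit):
        t_lo, t_hi = model.t_min, model.t_max
    else:
        pos = model.t[model.t > 0]
        t_lo, t_hi = pos[0], pos[-1]
    return np.logspace(np.log10(1.0 / t_hi), np.log10(1.0 / t_lo), n)


def gser_moduli(model, temperature: float, probe_radius: float,
                omega=None, n_omega: int = 40) -> Moduli:
    """Storage and loss moduli from an MSD model.

    ``temperature`` in K, ``probe_radius`` (R_g) in Å, ``omega`` in 1/ns.
    Raises on vanishing MSD at any requested frequency.
    """
    if temperature <= 0 or probe_radius <= 0:
        raise ValueError("temperature and probe radius must be positive")
    if omega is None:
        omega = default_omega_grid(model, n_omega)
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    alpha = local_log_slope(model, omega)
    if np.any(alpha <= 0) or np.any(alpha >= 2):
        raise ValueError("GSER approximation requires alpha(omega) in (0, 2)")
    msd = _msd_at(model, 1.0 / omega)
    if np.any(msd == 0):
        raise ZeroDivisionError("MSD vanishes at a requested frequency")
    g_star_pa = (KB_J_PER_K * temperature
                 / (np.pi * probe_radius * ANGSTROM_M
                    * msd * ANGSTROM_M ** 2 * gamma_fn(1.0 + alpha)))
    g_star = g_star_pa / PA_PER_KPA
    return Moduli(
        omega=omega, alpha=alpha, g_star_kpa=g_star,
        g_prime_kpa=g_star * np.cos(np.pi * alpha / 2.0),
        g_double_prime_kpa=g_star * np.sin(np.pi * alpha / 2.0),
        temperature=temperature, probe_radius=probe_radius)
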