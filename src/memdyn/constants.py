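"""Physical constants and unit conversions.

Internal units are Å (length), ns (time), amu (mass), K (temperature) and
kJ/mol (interaction energies); SI is used transiently inside formulas that
need ħ or k_B.
"""

import math

KB_J_PER_K = 1.380649e-23          # Boltzmann constant, J/K
HBAR_J_S = 1.054571817e-34         # reduced Planck constant, J*s
AMU_KG = 1.66053906660e-27         # atomic mass unit, kg
AVOGADRO = 6.02214076e23           # 1/mol
ANGSTROM_M = 1e-10                 # m per Å
NS_S = 1e-9                        # s per ns
R_KCAL_PER_MOL_K = 1.9872e-3       # gas constant, kcal/(mol*K)

#: dimensionless prefactor of the Schlitter determinant per (amu * Å^2 * K):
#: k_B*T*e^2/ħ^2 expressed so that it multiplies mass [amu] * variance [Å^2].
SCHLITTER_SCALE_PER_K = (
    KB_J_PER_K * math.e**2 / HBAR_J_S**2 * AMU_KG * ANGSTROM_M**2
)


def diffusion_A2ns_to_cm2s(d_alpha: float, alpha: float) -> float:
    """Convert a generalized diffusion coefficient from Å²/ns^α to cm²/s^α."""
    return d_alpha * 1e-16 / (1e-9) ** alpha


def diffusion_cm2s_to_A2ns(d_alpha: float, alpha: float) -> float:
    """Inverse of :func:`diffusion_A2ns_to_cm2s`."""
    return d_alpha / (1e-16 / (1e-9) ** alpha)


def sampling_plan(total_ns: float, timestep_fs: float, save_every: int):
    """Frame bookkeeping of an MD run.

    Returns ``(n_frames, frames_per_ns)`` for a run of ``total_ns``
    nanoseconds integrated at ``timestep_fs`` femtoseconds with one saved
    frame every ``save_every`` integration steps.
    """
    if total_ns <= 0 or timestep_fs <= 0 or save_every <= 0:
        raise ValueError("sampling plan requires positive arguments")
    n_steps = total_ns * 1e6 / timestep_fs
    n_frames = n_steps / save_every
    return int(round(n_frames)), n_frames / total_ns


# element -> (mass amu, atomic number)
ELEMENTS = {
    "H": (1.008, 1),
    "C": (12.011, 6),
    "N": (14.007, 7),
    "O": (15.999, 8),
    "P": (30.973762, 15),
    "NA": (22.98977, 11),
    "K": (39.0983, 19),
    "CL": (35.45, 17),
    "S": (32.06, 16),
}


def element_mass(element: str) -> float:
    return ELEMENTS[element.upper()][0]


def element_atomic_number(element: str) -> int:
    return ELEMENTS[element.upper()][1]
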