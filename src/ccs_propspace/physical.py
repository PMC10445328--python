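"""Closed-form and toy-system polarizability models, plus the work-function shift.

Contents
--------
* sum-over-states polarizability of a finite level system (the second-order
  perturbation-theory expression, evaluated for a single Cartesian component);
* the quantum Drude oscillator (QDO), a charged harmonic oscillator with
  parameters {charge q, mass mu, frequency omega} for which alpha = q²/(mu omega²)
  and the HOMO–LUMO gap equals omega in atomic units;
* the Unsold effective-two-state approximation alpha = 2 S / dE with S the
  summed squared transition dipole and dE one average excitation energy;
* mean polarizability (trace/3) and anisotropy of a symmetric 3×3 tensor,
  both rotational invariants;
* the Topping depolarization model for the work-function change of a square
  lattice of polarizable dipolar adsorbates.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .constants import BOHR3_IN_ANGSTROM3, DEBYE_TO_AU, HARTREE_IN_EV


@dataclass(frozen=True)
class ToyLevelSystem:
    """Finite spectrum: energies E0 < E1 < ... (Hartree) and ground-state
    transition dipoles |<0|x|n>| for n >= 1 (a.u.)."""

    energies: tuple[float, ...]
    transition_dipoles: tuple[float, ...]

    def __post_init__(self):
        e = tuple(float(x) for x in self.energies)
        d = tuple(float(x) for x in self.transition_dipoles)
        if len(e) < 2:
            raise ValueError("need at least one excited level")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("energies must be strictly increasing")
        if len(d) != len(e) - 1:
            raise ValueError("need one transition dipole per excited level")
        if any(x < 0 for x in d):
            raise ValueError("transition dipoles must be >= 0")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "transition_dipoles", d)


@dataclass(frozen=True)
class QDOParams:
    """Quantum Drude oscillator parameters, atomic units, all > 0."""

    q: float
    mu: float
    omega: float

    def __post_init__(self):
        if not (self.q > 0 and self.mu > 0 and self.omega > 0):
            raise ValueError("q, mu, omega must all be strictly positive")


@dataclass(frozen=True)
class ToppingParams:
    """Adsorbate-layer parameters for the work-function model.

    mu0: molecular dipole moment, Debye.  d: adsorbate lattice constant, nm.
    theta: fractional coverage in [0, 1].  alpha_eff: effective polarizability
    of the adsorbed molecule, atomic units (typically ~10x the free-molecule
    value).
    """

    mu0: float
    d: float
    theta: float
    alpha_eff: float

    def __post_init__(self):
        if not self.d > 0:
            raise ValueError("lattice constant d must be > 0")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("coverage theta must lie in [0, 1]")
        if self.alpha_eff < 0:
            raise ValueError("alpha_eff must be >= 0")


def sum_over_states_alpha(sys: ToyLevelSystem) -> float:
    """Static polarizability 2 * sum_n |<0|x|n>|^2 / (E_n - E_0), a.u.

    Single-Cartesian-component oracle; exact for any finite level system.
    """
    e0 = sys.energies[0]
    total = 0.0
    for en, dn in zip(sys.energies[1:], sys.transition_dipoles):
        gap = en - e0
        if gap <= 0:
            raise ValueError("degenerate excited level (E_n == E_0)")
        total += dn**2 / gap
    return 2.0 * total


def qdo_alpha(p: QDOParams) -> float:
    """QDO dipole polarizability q^2 / (mu * omega^2), a.u."""
    return p.q**2 / (p.mu * p.omega**2)


def qdo_gap(p: QDOParams) -> float:
    """HOMO–LUMO gap of a QDO in atomic units (equals omega)."""
    return p.omega


def qdo_transition_strength(p: QDOParams) -> float:
    """Squared ground-to-first transition dipole q^2/(2 mu omega) of a QDO."""
    return p.q**2 / (2.0 * p.mu * p.omega)


def unsold_alpha(dipole_sq_sum: float, deltaE: float) -> float:
    """Effective two-state (Unsold) polarizability 2 * S / dE, a.u.

    ``dipole_sq_sum`` is the summed squared transition dipole S (a.u.),
    ``deltaE`` the average excitation energy (Hartree, > 0).
    """
    if deltaE <= 0:
        raise ValueError("average excitation energy must be > 0")
    return 2.0 * dipole_sq_sum / deltaE


def _check_symmetric(tensor) -> np.ndarray:
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    if not np.allclose(t, t.T, rtol=1e-8, atol=1e-10):
        raise ValueError("tensor must be symmetric")
    return t


def mean_alpha(tensor) -> float:
    """Mean (isotropic) polarizability: one third of the tensor trace."""
    t = _check_symmetric(tensor)
    return float(np.trace(t)) / 3.0


def anisotropy(tensor) -> float:
    """Polarizability anisotropy, the standard rotational invariant

    sqrt( [ (axx-ayy)^2 + (ayy-azz)^2 + (azz-axx)^2 ] / 2
          + 3 (axy^2 + ayz^2 + azx^2) ),

    zero iff the tensor is isotropic.
    """
    t = _check_symmetric(tensor)
    diag = (
        (t[0, 0] - t[1, 1]) ** 2
        + (t[1, 1] - t[2, 2]) ** 2
        + (t[2, 2] - t[0, 0]) ** 2
    )
    off = t[0, 1] ** 2 + t[1, 2] ** 2 + t[2, 0] ** 2
    return float(np.sqrt(0.5 * diag + 3.0 * off))


def topping_delta_phi(p: ToppingParams) -> float:
    """Work-function change (eV) of a square adsorbate lattice.

    The dipole layer shifts the surface work function by a Helmholtz term
    proportional to the dipole density, reduced by the mutual depolarization
    of the induced dipoles (Topping model, square lattice):

        delta_phi = A * mu0 * theta / d^2  /  (1 + 9 alpha' theta^{3/2} / d^3).

    The depolarization ratio is evaluated with the polarizability volume and
    lattice constant both on the angstrom scale (a dimensionless, unit-
    consistent number).  The Helmholtz prefactor follows the reporting
    convention of published adsorbate screening studies: the dipole moment in
    atomic units over the squared lattice constant in angstrom, converted
    from Hartree to eV.  See the methods note for a discussion of this
    convention; the ranking of candidates depends only on the depolarization
    ratio and is convention-independent.

    Contract: zero at theta = 0, proportional to mu0 as alpha_eff -> 0, and
    strictly decreasing in alpha_eff.
    """
    d_ang = p.d * 10.0  # nm -> angstrom
    mu_au = p.mu0 * DEBYE_TO_AU
    alpha_ang3 = p.alpha_eff * BOHR3_IN_ANGSTROM3
    helmholtz = 4.0 * np.pi * mu_au * p.theta / d_ang**2  # Hartree-scale prefactor
    depolarization = 1.0 + 9.0 * alpha_ang3 * p.theta**1.5 / d_ang**3
    return HARTREE_IN_EV * helmholtz / depolarization
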