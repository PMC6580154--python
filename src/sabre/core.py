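"""Closed-form concentration-response models of the SABRE family.

SABRE (Signal Amplification, Binding affinity, Receptor-activation
Efficacy) is a two-state receptor model that separates three processes,
each with its own parameter:

* binding, through the equilibrium dissociation constant ``kd`` (molar);
* receptor activation, through the intrinsic efficacy ``epsilon``
  (fraction of ligand-bound receptors that are active, 0 for an
  antagonist up to 1 for a full agonist), with a basal receptor efficacy
  ``epsilon_r0`` (fraction of ligand-free receptors that are active) for
  constitutively active receptors;
* post-receptor signal transduction, through a unitless gain ``gamma``
  (>= 1, with gamma = 1 meaning response equals receptor activation).

The full four-parameter response is

    E/Emax = (eps*g*[L] + eps0*g*Kd) / ((eps*g - eps + 1)*[L]
                                        + (eps0*g - eps0 + 1)*Kd)

and fixing parameters walks down a nested ladder: ``epsilon_r0 = 0``
gives the three-parameter model, ``gamma = 1`` gives the Emax model for
partial agonists, and ``epsilon = 1`` gives the Clark equation.  The
operational (Black-Leff) model is provided for comparison; its
transducer ratio ``tau`` conflates activation and amplification.

All functions are vectorised over concentration (and over parameters,
with NumPy broadcasting) and validate their domains eagerly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "LigandParams",
    "SystemParams",
    "OperationalParams",
    "ThermoContext",
    "FlatResponseError",
    "clark_response",
    "emax_response",
    "amplify",
    "fraction_active",
    "sabre3_response",
    "sabre4_response",
    "constitutive_response_no_amp",
    "operational_response",
    "kobs",
    "max_response",
    "basal_response",
    "dg_from_kd",
    "kd_from_dg",
]

#: Universal gas constant, J/(K*mol).
GAS_CONSTANT = 8.314


class FlatResponseError(ValueError):
    """Raised when a concentration-response curve has no transition.

    A ligand whose efficacy equals the basal receptor efficacy (a neutral
    antagonist) produces a flat curve, so no EC50 exists.
    """


# ---------------------------------------------------------------------------
# validation helpers

def _validate(cond: bool | np.bool_, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _check_conc(conc) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    _validate(bool(np.all(conc >= 0)), "concentration must be >= 0")
    return conc


def _check_kd(kd) -> np.ndarray:
    kd = np.asarray(kd, dtype=float)
    _validate(bool(np.all(kd > 0)), "kd must be strictly positive")
    return kd


def _check_fraction(x, name: str, *, lo: float = 0.0, hi: float = 1.0,
                    lo_open: bool = False, hi_open: bool = False) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    ok_lo = np.all(x > lo) if lo_open else np.all(x >= lo)
    ok_hi = np.all(x < hi) if hi_open else np.all(x <= hi)
    _validate(bool(ok_lo and ok_hi),
              f"{name} must lie in {'(' if lo_open else '['}{lo}, "
              f"{hi}{')' if hi_open else ']'}")
    return x


def _check_gamma(gamma) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float)
    _validate(bool(np.all(gamma >= 1)), "gamma must be >= 1 (it is a gain)")
    return gamma


def _ret(x: np.ndarray):
    """Return a bare float for scalar input, an ndarray otherwise."""
    return float(x) if np.ndim(x) == 0 else x


# ---------------------------------------------------------------------------
# domain types

@dataclasses.dataclass(frozen=True)
class LigandParams:
    """Ligand-scope parameters: binding affinity and intrinsic efficacy."""

    kd: float
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        _check_kd(self.kd)
        _check_fraction(self.epsilon, "epsilon")


@dataclasses.dataclass(frozen=True)
class SystemParams:
    """Pathway/receptor-scope parameters: gain and basal efficacy.

    Both components of the gain (total receptor number and the
    transduction half-saturation constant) can be tissue dependent, so
    ``gamma`` lives at pathway scope, not ligand scope; ``epsilon_r0``
    is a property of the receptor system.
    """

    gamma: float = 1.0
    epsilon_r0: float = 0.0

    def __post_init__(self) -> None:
        _check_gamma(self.gamma)
        _check_fraction(self.epsilon_r0, "epsilon_r0", hi_open=True)


@dataclasses.dataclass(frozen=True)
class OperationalParams:
    """Operational (Black-Leff) model parameters."""

    kd: float
    tau: float

    def __post_init__(self) -> None:
        _check_kd(self.kd)
        _validate(self.tau >= 0, "tau must be >= 0")


@dataclasses.dataclass(frozen=True)
class ThermoContext:
    """Temperature context for the Kd <-> binding free-energy conversion."""

    temperature: float = 310.0  # kelvin
    gas_constant: float = GAS_CONSTANT  # J/(K*mol)

    def __post_init__(self) -> None:
        _validate(self.temperature > 0, "temperature must be > 0 K")


# ---------------------------------------------------------------------------
# nested response family

def clark_response(conc, kd):
    """Clark equation: full agonist, no amplification.

    ``f_resp = [L] / ([L] + Kd)``; half-saturation at ``conc == kd``.
    """
    conc = _check_conc(conc)
    kd = _check_kd(kd)
    return _ret(conc / (conc + kd))


def emax_response(conc, kd, epsilon):
    """Emax model for partial agonists: asymptote equals ``epsilon``."""
    conc = _check_conc(conc)
    kd = _check_kd(kd)
    epsilon = _check_fraction(epsilon, "epsilon")
    return _ret(epsilon * conc / (conc + kd))


def amplify(f_act, gamma):
    """Hyperbolic post-receptor amplification of an activation fraction.

    Implemented as the rational form ``g*f / ((g-1)*f + 1)``, which is
    algebraically the hyperbolic response in the odds transform
    ``L = f/(1-f)`` (``L / (L + 1/g)``) but stays finite at ``f = 1``,
    where it returns exactly 1.  Identity for ``gamma = 1``.
    """
    f = _check_fraction(f_act, "f_act")
    gamma = _check_gamma(gamma)
    return _ret(gamma * f / ((gamma - 1.0) * f + 1.0))


def fraction_active(conc, kd, epsilon, epsilon_r0):
    """Fraction of active receptors (bound-active plus free-active).

    ``f_act = eps0*Kd/(Kd+[L]) + eps*[L]/([L]+Kd)``: equals
    ``epsilon_r0`` at zero concentration and tends to ``epsilon`` at
    saturating ligand.
    """
    conc = _check_conc(conc)
    kd = _check_kd(kd)
    epsilon = _check_fraction(epsilon, "epsilon")
    epsilon_r0 = _check_fraction(epsilon_r0, "epsilon_r0", hi_open=True)
    return _ret((epsilon_r0 * kd + epsilon * conc) / (conc + kd))


def sabre3_response(conc, kd, epsilon, gamma):
    """Three-parameter model: no constitutive activity.

    ``f_resp = eps*g*[L] / ((eps*g - eps + 1)*[L] + Kd)``; identical to
    ``amplify(emax_response(...), gamma)``.  Asymptote
    ``eps*g/(eps*g - eps + 1)``, EC50 at ``Kd/(eps*g + 1 - eps)``.
    """
    conc = _check_conc(conc)
    kd = _check_kd(kd)
    epsilon = _check_fraction(epsilon, "epsilon")
    gamma = _check_gamma(gamma)
    eg = epsilon * gamma
    return _ret(eg * conc / ((eg - epsilon + 1.0) * conc + kd))


def sabre4_response(conc, kd, epsilon, gamma, epsilon_r0):
    """Full four-parameter model with constitutive activity.

    ``f_resp = (eps*g*[L] + eps0*g*Kd) / ((eps*g - eps + 1)*[L]
    + (eps0*g - eps0 + 1)*Kd)``.  Basal response (``[L] = 0``) is
    ``basal_response(epsilon_r0, gamma)``; the asymptote is
    ``max_response(epsilon, gamma)``.  A neutral antagonist
    (``epsilon == epsilon_r0``) gives a flat curve.
    """
    conc = _check_conc(conc)
    kd = _check_kd(kd)
    epsilon = _check_fraction(epsilon, "epsilon")
    gamma = _check_gamma(gamma)
    epsilon_r0 = _check_fraction(epsilon_r0, "epsilon_r0", hi_open=True)
    eg = epsilon * gamma
    e0g = epsilon_r0 * gamma
    num = eg * conc + e0g * kd
    den = (eg - epsilon + 1.0) * conc + (e0g - epsilon_r0 + 1.0) * kd
    return _ret(num / den)


def constitutive_response_no_amp(conc, kd, epsilon, epsilon_r0):
    """Constitutive activity without amplification (``gamma = 1``).

    Equal to :func:`fraction_active`; decreasing in concentration iff
    ``epsilon < epsilon_r0`` (inverse agonist).
    """
    return fraction_active(conc, kd, epsilon, epsilon_r0)


def operational_response(conc, kd, tau):
    """Operational (Black-Leff) model, for comparison with SABRE.

    ``f_resp = tau*[L] / ((tau+1)*[L] + Kd)``; asymptote
    ``tau/(tau+1)``, EC50 at ``Kd/(tau+1)``.
    """
    conc = _check_conc(conc)
    kd = _check_kd(kd)
    tau = np.asarray(tau, dtype=float)
    _validate(bool(np.all(tau >= 0)), "tau must be >= 0")
    return _ret(tau * conc / ((tau + 1.0) * conc + kd))


# ---------------------------------------------------------------------------
# summary quantities

def kobs(kd, epsilon, gamma, epsilon_r0=0.0):
    """Observed EC50: concentration of the half-maximal transition.

    ``K_obs = Kd * (eps0*g - eps0 + 1) / (eps*g - eps + 1)``.  With no
    constitutive activity this is ``Kd/(eps*g + 1 - eps)``, and for a
    full agonist simply ``Kd/gamma`` (amplification left-shifts the
    curve gamma-fold without changing its shape).
    """
    kd = _check_kd(kd)
    epsilon = _check_fraction(epsilon, "epsilon")
    gamma = _check_gamma(gamma)
    epsilon_r0 = _check_fraction(epsilon_r0, "epsilon_r0", hi_open=True)
    if np.any(np.asarray(epsilon) == np.asarray(epsilon_r0)):
        raise FlatResponseError(
            "epsilon equals epsilon_r0: flat response, no EC50")
    num = epsilon_r0 * gamma - epsilon_r0 + 1.0
    den = epsilon * gamma - epsilon + 1.0
    return _ret(kd * num / den)


def max_response(epsilon, gamma):
    """Maximum fractional effect of a ligand: ``eps*g/(eps*g + 1 - eps)``.

    Amplification can push a partial agonist's apparent maximum toward 1
    (apparent full agonism) even for small ``epsilon``.
    """
    epsilon = _check_fraction(epsilon, "epsilon")
    gamma = _check_gamma(gamma)
    eg = epsilon * gamma
    return _ret(np.where(eg == 0, 0.0, eg / (eg + 1.0 - epsilon)))


def basal_response(epsilon_r0, gamma):
    """Response with no ligand: ``eps0*g/(eps0*g + 1 - eps0)``."""
    epsilon_r0 = _check_fraction(epsilon_r0, "epsilon_r0", hi_open=True)
    gamma = _check_gamma(gamma)
    e0g = epsilon_r0 * gamma
    return _ret(np.where(e0g == 0, 0.0, e0g / (e0g + 1.0 - epsilon_r0)))


# ---------------------------------------------------------------------------
# thermodynamics

def dg_from_kd(kd, thermo: ThermoContext | None = None):
    """Gibbs free energy of binding (J/mol) from Kd: ``dG0 = -R*T*ln(Kd)``.

    A 1 nM binder at physiological temperature (310 K) corresponds to
    about 53.4 kJ/mol (12.8 kcal/mol).
    """
    thermo = thermo or ThermoContext()
    kd = _check_kd(kd)
    return _ret(-thermo.gas_constant * thermo.temperature * np.log(kd))


def kd_from_dg(dg, thermo: ThermoContext | None = None):
    """Inverse of :func:`dg_from_kd`: ``Kd = exp(-dG0/(R*T))`` (molar)."""
    thermo = thermo or ThermoContext()
    dg = np.asarray(dg, dtype=float)
    return _ret(np.exp(-dg / (thermo.gas_constant * thermo.temperature)))
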