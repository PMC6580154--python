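"""Linking fractional response to fractional occupancy.

In a system with post-receptor amplification, fractional response and
fractional occupancy no longer coincide: a full agonist in a 10-fold
gain system reaches half-maximal response at only ~9% occupancy
("receptor reserve").  These functions relate the two quantities, and
relate the responses of two pathways to each other, without reference to
ligand concentration (Kd cancels exactly).

All of these hold for the no-constitutive-activity regime
(``epsilon_r0 = 0``); occupancy linking under constitutive activity is
deliberately not provided.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import (
    _check_conc,
    _check_fraction,
    _check_gamma,
    _check_kd,
    _ret,
    max_response,
)

__all__ = [
    "OccupancyResponsePair",
    "occupancy",
    "response_from_occupancy",
    "occupancy_from_response",
    "occupancy_at_half_response",
    "relative_response",
]


@dataclasses.dataclass(frozen=True)
class OccupancyResponsePair:
    """One (occupancy, response) observation for a ligand on a pathway."""

    f_occup: float
    f_resp: float
    ligand_id: str = ""
    pathway_id: str = ""

    def __post_init__(self) -> None:
        _check_fraction(self.f_occup, "f_occup")
        _check_fraction(self.f_resp, "f_resp")


def occupancy(conc, kd):
    """Affinity-determined fractional occupancy ``[L]/([L]+Kd)``.

    Same algebraic form as the Clark response, but distinct semantics:
    this is the fraction of receptors *bound*, whatever they go on to do.
    """
    conc = _check_conc(conc)
    kd = _check_kd(kd)
    return _ret(conc / (conc + kd))


def response_from_occupancy(f_occup, epsilon, gamma):
    """Fractional response produced by a given fractional occupancy.

    ``f_resp = eps*g*f / (eps*(g-1)*f + 1)``.  At full occupancy the
    response is ``max_response(epsilon, gamma)``, which can be below 1
    for low-efficacy ligands.
    """
    f = _check_fraction(f_occup, "f_occup")
    epsilon = _check_fraction(epsilon, "epsilon")
    gamma = _check_gamma(gamma)
    return _ret(epsilon * gamma * f / (epsilon * (gamma - 1.0) * f + 1.0))


def occupancy_from_response(f_resp, epsilon, gamma):
    """Occupancy needed to produce a given fractional response.

    Exact inverse of :func:`response_from_occupancy` on its range:
    ``f_occup = f / (eps*g - eps*(g-1)*f)``.  Responses at or above the
    ligand's attainable maximum are rejected.
    """
    f = np.asarray(f_resp, dtype=float)
    _check_fraction(f, "f_resp")
    epsilon = _check_fraction(epsilon, "epsilon")
    gamma = _check_gamma(gamma)
    fmax = np.asarray(max_response(epsilon, gamma))
    if np.any(f >= fmax):
        raise ValueError(
            "response exceeds ligand's asymptote: f_resp must be below "
            f"max_response(epsilon, gamma) = {fmax}")
    return _ret(f / (epsilon * gamma - epsilon * (gamma - 1.0) * f))


def occupancy_at_half_response(epsilon, gamma):
    """Occupancy at which a ligand produces half-maximal response (0.5).

    ``f_occup = 1/(eps*(g+1))``.  For a full agonist this is
    ``1/(1+gamma)``: 9.1% at gamma=10, 0.99% at gamma=100 — the usual
    quantification of "spare receptors".  Requires ``eps*(g+1) > 1``;
    for weaker ligands half-maximal response is never reached.
    """
    epsilon = np.asarray(epsilon, dtype=float)
    _check_fraction(epsilon, "epsilon")
    gamma = _check_gamma(gamma)
    if np.any(epsilon * (gamma + 1.0) <= 1.0):
        raise ValueError("half-maximal response not attainable: "
                         "requires epsilon*(gamma+1) > 1")
    return _ret(1.0 / (epsilon * (gamma + 1.0)))


def relative_response(f_resp1, epsilon1, gamma1, epsilon2, gamma2):
    """Response along pathway 2 at the concentration producing ``f_resp1``.

    Eliminating occupancy between the two pathways gives

        f2 = eps2*g2*f1 / (eps1*g1 + [eps2*(g2-1) - eps1*(g1-1)]*f1)

    which is concentration-free (Kd cancels).  For balanced agonists
    (``eps1 == eps2``) this reduces to ``g2*f1/(g1 + (g2-g1)*f1)`` — still
    curvilinear whenever the gains differ, which is why curvature of a
    bias plot alone is not evidence of biased agonism.
    """
    f1 = np.asarray(f_resp1, dtype=float)
    _check_fraction(f1, "f_resp1")
    epsilon1 = _check_fraction(epsilon1, "epsilon1")
    epsilon2 = _check_fraction(epsilon2, "epsilon2")
    gamma1 = _check_gamma(gamma1)
    gamma2 = _check_gamma(gamma2)
    fmax1 = np.asarray(max_response(epsilon1, gamma1))
    if np.any(f1 > fmax1):
        raise ValueError("f_resp1 exceeds the pathway-1 asymptote")
    num = epsilon2 * gamma2 * f1
    den = (epsilon1 * gamma1
           + (epsilon2 * (gamma2 - 1.0) - epsilon1 * (gamma1 - 1.0)) * f1)
    return _ret(num / den)
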