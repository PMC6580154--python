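"""Seeded synthetic concentration-response data generation.

Emulates the multi-ligand, multi-pathway, multi-condition designs of
functional pharmacology: each ligand has a true (Kd, epsilon), each
pathway a (gamma, epsilon_r0), each condition a surviving receptor
fraction q, and responses are the closed-form model values plus additive
homoscedastic Gaussian noise on the fractional response (the noise model
matching unweighted least squares).  Out-of-range noisy responses are
retained, not clipped — the fitter should see realistic data — and are
flagged by the table.

``make_case_fixture`` provides a registry of deterministic designs, one
per branch of the model family (receptor reserve, strongly contrasting
gains on two pathways, irreversible-inactivation series, balanced and
biased two-pathway sets, constitutive activity).  Their generating
parameters are arbitrary test choices documented here, not claims about
any published dataset.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import LigandParams, SystemParams
from .fitting import MODEL_ROLES, DoseResponseTable, _eval_model

__all__ = ["SimDesign", "simulate_dataset", "make_case_fixture",
           "CASE_FIXTURES"]


@dataclasses.dataclass
class SimDesign:
    """Full description of a simulated concentration-response experiment.

    ``conc_grid`` may be None, in which case each ligand gets a 10-point
    log-spaced grid spanning Kd*10^-3 to Kd*10^+3 (so every curve is
    sampled around its own transition).
    """

    ligands: Mapping[str, LigandParams]
    pathways: Mapping[str, SystemParams] = dataclasses.field(
        default_factory=lambda: {"pathway1": SystemParams()})
    conditions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"control": 1.0})
    conc_grid: Sequence[float] | None = None
    n_grid: int = 10
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    taus: Mapping[str, float] | None = None  # operational model only

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.conc_grid is not None:
            grid = np.asarray(self.conc_grid, dtype=float)
            if np.any(np.diff(grid) <= 0):
                raise ValueError("conc_grid must be strictly increasing")


def simulate_dataset(design: SimDesign, model: str = "sabre3"
                     ) -> DoseResponseTable:
    """Generate a tidy dose-response table from a design and model variant.

    Fully reproducible from ``design.seed``; with ``noise_sd = 0`` the
    responses equal the closed-form model values exactly.
    """
    if model not in MODEL_ROLES:
        raise ValueError(f"unknown model {model!r}; choose from "
                         f"{sorted(MODEL_ROLES)}")
    if model == "operational" and design.taus is None:
        raise ValueError("operational model needs design.taus")
    rng = np.random.default_rng(design.seed)
    rows = []
    for lig, lp in design.ligands.items():
        if design.conc_grid is not None:
            grid = np.asarray(design.conc_grid, dtype=float)
        else:
            grid = np.geomspace(lp.kd * 1e-3, lp.kd * 1e3, design.n_grid)
        for path, sp in design.pathways.items():
            for cond, q in design.conditions.items():
                tau = design.taus.get(lig) if design.taus else None
                clean = _eval_model(model, grid, lp.kd, lp.epsilon,
                                    sp.gamma, sp.epsilon_r0, q, tau)
                for rep in range(design.n_replicates):
                    noise = (rng.normal(0.0, design.noise_sd, size=len(grid))
                             if design.noise_sd > 0 else 0.0)
                    resp = np.asarray(clean) + noise
                    for c, r in zip(grid, resp):
                        rows.append({"ligand": lig, "pathway": path,
                                     "condition": cond, "conc": c,
                                     "response": r, "replicate": rep})
    return DoseResponseTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# fixture registry

def _fx_reserve_series():
    """Five-ligand, one-pathway set with moderate receptor reserve.

    A full agonist down to a very weak partial agonist, one shared gain
    of 12 — the classic mismatch between occupancy and response.
    """
    design = SimDesign(
        ligands={
            "L1": LigandParams(kd=3e-7, epsilon=1.0),
            "L2": LigandParams(kd=1e-7, epsilon=0.60),
            "L3": LigandParams(kd=1e-6, epsilon=0.30),
            "L4": LigandParams(kd=3e-6, epsilon=0.10),
            "L5": LigandParams(kd=1e-5, epsilon=0.03),
        },
        pathways={"contraction": SystemParams(gamma=12.0)},
        noise_sd=0.02, seed=42)
    return design, "sabre3"


def _fx_dual_gain():
    """Five ligands read out on two pathways with a huge gain contrast.

    Gains of 2 and 2000 emulate consecutive vantage points along one
    cascade (near-linear transduction vs. strong amplification): in the
    amplified readout every agonist looks nearly full.
    """
    design = SimDesign(
        ligands={
            "A": LigandParams(kd=1e-8, epsilon=1.0),
            "B": LigandParams(kd=1e-7, epsilon=0.55),
            "C": LigandParams(kd=3e-7, epsilon=0.30),
            "D": LigandParams(kd=1e-6, epsilon=0.12),
            "E": LigandParams(kd=3e-6, epsilon=0.05),
        },
        pathways={"gtp": SystemParams(gamma=2.0),
                  "calcium": SystemParams(gamma=2000.0)},
        noise_sd=0.02, seed=7)
    return design, "sabre3"


def _fx_inactivation_series():
    """One full agonist before/after two levels of irreversible blockade."""
    design = SimDesign(
        ligands={"agonist": LigandParams(kd=1e-7, epsilon=1.0)},
        pathways={"response": SystemParams(gamma=40.0)},
        conditions={"control": 1.0, "inact_low": 0.3, "inact_high": 0.05},
        noise_sd=0.0, seed=11)
    return design, "sabre3"


def _fx_dual_inactivation():
    """Two agonists of very different efficacy, shared q per condition.

    The high-affinity/low-efficacy ligand loses its response faster under
    inactivation than the low-affinity full agonist — the apparent
    potency-order reversal that motivates global fitting.
    """
    design = SimDesign(
        ligands={"full": LigandParams(kd=3e-5, epsilon=1.0),
                 "partial": LigandParams(kd=1e-6, epsilon=0.05)},
        pathways={"ileum": SystemParams(gamma=200.0)},
        conditions={"control": 1.0, "alkylated": 0.02},
        noise_sd=0.0, seed=13)
    return design, "sabre3"


def _fx_balanced_bias():
    """Balanced agonists on two pathways differing only in gain (10 vs 1000)."""
    eps = {"A": 1.0, "B": 0.7, "C": 0.5, "D": 0.3, "E": 0.15}
    design = SimDesign(
        ligands={k: LigandParams(kd=10.0 ** (-8.5 + 0.5 * i), epsilon=e)
                 for i, (k, e) in enumerate(eps.items())},
        pathways={"camp": SystemParams(gamma=10.0),
                  "arrestin": SystemParams(gamma=1000.0)},
        noise_sd=0.0, seed=23)
    return design, "sabre3"


def _fx_constitutive():
    """Constitutively active receptor, no amplification.

    Full, partial, neutral and inverse agonists on a receptor whose
    ligand-free activity is 45% of maximum: the inverse agonist pushes
    the response below baseline.
    """
    design = SimDesign(
        ligands={"full": LigandParams(kd=1e-7, epsilon=1.0),
                 "partial": LigandParams(kd=1e-7, epsilon=0.70),
                 "neutral": LigandParams(kd=1e-7, epsilon=0.45),
                 "inverse": LigandParams(kd=1e-7, epsilon=0.05)},
        pathways={"coupling": SystemParams(gamma=1.0, epsilon_r0=0.45)},
        noise_sd=0.0, seed=31)
    return design, "constitutive_no_amp"


CASE_FIXTURES = {
    "reserve_series": _fx_reserve_series,
    "dual_gain": _fx_dual_gain,
    "inactivation_series": _fx_inactivation_series,
    "dual_inactivation": _fx_dual_inactivation,
    "balanced_bias": _fx_balanced_bias,
    "constitutive": _fx_constitutive,
}


def make_case_fixture(name: str) -> tuple[SimDesign, DoseResponseTable]:
    """Build a named deterministic fixture: (design, simulated table)."""
    try:
        builder = CASE_FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; available: "
                         f"{sorted(CASE_FIXTURES)}") from None
    design, model = builder()
    return design, simulate_dataset(design, model)
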