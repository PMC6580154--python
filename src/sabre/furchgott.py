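"""Irreversible receptor inactivation (Furchgott) analysis.

Treating a tissue with an irreversible antagonist (an alkylating agent
such as phenoxybenzamine or EEDQ) leaves only a fraction ``q`` of the
receptors functional.  Comparing concentration-response curves before
and after inactivation allows simultaneous estimation of the ligand's
Kd and of ``q``, classically through the double-reciprocal regression of
equiactive concentrations

    1/[L] = (1 - q)/(q*Kd) + (1/q) * 1/[L]'

whose slope is ``1/q`` and intercept ``(1-q)/(q*Kd)``.  The regression
makes no assumption about the transduction function, only that it is
unchanged by the treatment.

Within the SABRE model the same experiment has a closed form: a q-fold
loss of receptors appears as a q-fold loss of apparent efficacy,
``eps' = q*eps``, so the post-inactivation curve is the three-parameter
model with ``q*eps`` in place of ``eps``.  Fitting all conditions
globally with a single Kd and gain is the model-based alternative to the
classical regression; on clean data the two routes agree.
"""

from __future__ import annotations

import dataclasses
import math
import warnings as _warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    _check_conc,
    _check_fraction,
    _check_gamma,
    _check_kd,
    _ret,
    sabre3_response,
)
from .fitting import DoseResponseTable, FitResult, SharingScheme, fit_global

__all__ = [
    "InactivationCondition",
    "EquiactivePair",
    "FurchgottResult",
    "inactivated_response",
    "equiactive_pairs",
    "furchgott_regression",
    "fit_inactivation_series",
    "apparent_efficacies",
]


@dataclasses.dataclass(frozen=True)
class InactivationCondition:
    """One inactivation level: label plus surviving receptor fraction q."""

    condition_id: str
    q: float = 1.0

    def __post_init__(self) -> None:
        _check_fraction(self.q, "q", lo_open=True)


@dataclasses.dataclass(frozen=True)
class EquiactivePair:
    """Concentrations producing the same response pre/post inactivation."""

    conc_pre: float
    conc_post: float
    response_level: float

    def __post_init__(self) -> None:
        if self.conc_pre <= 0 or self.conc_post <= 0:
            raise ValueError("equiactive concentrations must be positive")


@dataclasses.dataclass
class FurchgottResult:
    """Classical double-reciprocal regression outcome."""

    q: float
    kd: float
    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    flags: list[str]


def inactivated_response(conc, kd, epsilon, gamma, q):
    """Response after irreversible inactivation to a fraction q of receptors.

    ``f_resp = q*eps*g*[L] / ((q*eps*g + 1 - q*eps)*[L] + Kd)`` —
    identical to the three-parameter model with apparent efficacy
    ``eps' = q*eps``.
    """
    conc = _check_conc(conc)
    kd = _check_kd(kd)
    epsilon = _check_fraction(epsilon, "epsilon")
    gamma = _check_gamma(gamma)
    q = _check_fraction(q, "q", lo_open=True)
    return _ret(np.asarray(sabre3_response(conc, kd, q * epsilon, gamma)))


def _invert_curve(conc: np.ndarray, resp: np.ndarray,
                  levels: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear interpolation of log-conc at response levels.

    Ties in response are collapsed; levels outside the attained range
    come back as NaN.
    """
    order = np.argsort(conc)
    conc, resp = conc[order], resp[order]
    if np.any(conc <= 0):
        raise ValueError("equiactive interpolation needs positive "
                         "concentrations")
    if np.any(np.diff(resp) < -1e-9):
        _warnings.warn("response curve is not monotone nondecreasing in "
                       "concentration; interpolation uses its running "
                       "maximum")
        resp = np.maximum.accumulate(resp)
    logc = np.log(conc)
    keep = np.concatenate(([True], np.diff(resp) > 0))
    r, lc = resp[keep], logc[keep]
    out = np.interp(levels, r, lc, left=np.nan, right=np.nan)
    out[(levels < r[0]) | (levels > r[-1])] = np.nan
    return np.exp(out)


def equiactive_pairs(curve_pre, curve_post,
                     levels: Sequence[float] | None = None
                     ) -> list[EquiactivePair]:
    """Extract equiactive concentration pairs from two response curves.

    ``curve_pre`` and ``curve_post`` are ``(conc, response)`` array
    pairs for the control and inactivated preparations.  Each requested
    response level (default: deciles of the overlapping response range)
    is inverted on both curves by monotone piecewise-linear interpolation
    in (log concentration, response) space.  Levels outside the overlap
    are skipped with a warning; fewer than 3 usable pairs is an error.
    """
    c_pre, r_pre = (np.asarray(a, dtype=float) for a in curve_pre)
    c_post, r_post = (np.asarray(a, dtype=float) for a in curve_post)
    lo = max(r_pre.min(), r_post.min())
    hi = min(r_pre.max(), r_post.max())
    if levels is None:
        if hi <= lo:
            raise ValueError("response ranges of the two curves do not "
                             "overlap")
        levels = lo + (hi - lo) * np.arange(1, 10) / 10.0
    levels = np.asarray(levels, dtype=float)

    pre = _invert_curve(c_pre, r_pre, levels)
    post = _invert_curve(c_post, r_post, levels)
    pairs: list[EquiactivePair] = []
    for lev, a, b in zip(levels, pre, post):
        if math.isnan(a) or math.isnan(b):
            _warnings.warn(f"response level {lev:.4g} outside the overlap "
                           "of the two curves; skipped")
            continue
        pairs.append(EquiactivePair(float(a), float(b), float(lev)))
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} usable equiactive pairs; "
                         "need at least 3")
    return pairs


def furchgott_regression(pairs: Sequence[EquiactivePair]) -> FurchgottResult:
    """Classical Furchgott double-reciprocal regression.

    Ordinary least squares of ``1/conc_pre`` on ``1/conc_post`` gives
    ``q = 1/slope`` and ``Kd = (1 - q)/(q * intercept)``.  Unweighted OLS
    in reciprocal space is the method as classically stated; note that
    the reciprocal transform distorts the error structure, so noisy data
    are better served by :func:`fit_inactivation_series`.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 equiactive pairs")
    x = np.array([1.0 / p.conc_post for p in pairs])
    y = np.array([1.0 / p.conc_pre for p in pairs])
    reg = stats.linregress(x, y)
    slope, intercept = float(reg.slope), float(reg.intercept)
    flags: list[str] = []
    q = 1.0 / slope if slope > 0 else math.nan
    if slope <= 1.0:
        flags.append("slope <= 1: no detectable inactivation")
        kd = math.nan
    elif intercept <= 0.0:
        flags.append("intercept <= 0: inconsistent data, Kd undefined")
        kd = math.nan
    else:
        kd = (1.0 - q) / (q * intercept)
    r2 = float(reg.rvalue) ** 2
    for f in flags:
        _warnings.warn(f)
    return FurchgottResult(q=q, kd=kd, slope=slope, intercept=intercept,
                           r_squared=r2, n_pairs=len(pairs), flags=flags)


def fit_inactivation_series(data: DoseResponseTable | pd.DataFrame,
                            scheme: SharingScheme | None = None, *,
                            n_starts: int = 16, seed: int = 0) -> FitResult:
    """Model-based fit of a pre/post-inactivation curve family.

    Globally fits the three-parameter model with a free per-condition
    surviving fraction ``q`` (reference condition anchored at ``q = 1``),
    a single Kd per ligand and one shared gain.  Because only the
    product ``q*eps`` is identifiable within one condition, the
    reference anchoring fixes the efficacy scale.  The per-condition
    apparent efficacies ``eps' = q*eps`` are reported in
    ``result.extras["apparent_efficacy"]``.
    """
    if not isinstance(data, DoseResponseTable):
        data = DoseResponseTable(data)
    if scheme is None:
        scheme = SharingScheme(q="free")
    fit = fit_global(data, "sabre3", scheme, n_starts=n_starts, seed=seed)
    fit.extras["apparent_efficacy"] = apparent_efficacies(fit, data)
    return fit


def apparent_efficacies(fit: FitResult,
                        data: DoseResponseTable) -> pd.DataFrame:
    """Per (ligand, condition) apparent efficacy ``eps' = q*eps``."""
    rows = []
    for lig in data.ligands:
        eps = fit.params.get(f"epsilon[{lig}]", math.nan)
        for cond in data.conditions:
            q = fit.params.get(f"q[{cond}]", 1.0)
            rows.append({"ligand": lig, "condition": cond, "q": q,
                         "epsilon": eps, "apparent_efficacy": q * eps})
    return pd.DataFrame(rows)
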