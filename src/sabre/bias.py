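"""Biased-agonism quantification.

If every ligand shares one gain per pathway, a ligand whose intrinsic
efficacies differ between two pathways of the same receptor is a
candidate biased agonist.  The primary route is Kd-anchored per-pathway
fitting followed by comparison of the efficacy ratio ``eps_m/eps_n``
per ligand — no reference agonist is needed, and pathway-specific
amplification is cleanly separated from ligand-specific efficacy.  A
ligand is flagged when the ratio +/- 2 standard errors excludes 1.

Relative-response ("bias") plots — one pathway's fractional response
against the other's at matched concentrations — are concentration-free
and can be generated or fitted directly, but direct fitting is the
fallback route: under strong amplification the efficacies it yields
carry large uncertainties.
"""

from __future__ import annotations

import dataclasses
import math
import warnings as _warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core import max_response
from .occupancy import relative_response, response_from_occupancy
from .fitting import FitResult, _aicc, _cov_from_jac

__all__ = [
    "BiasResult",
    "bias_table",
    "bias_plot_curve",
    "fit_relative_response",
]


@dataclasses.dataclass
class BiasResult:
    """Efficacy-ratio bias assessment for one ligand and pathway pair."""

    ligand_id: str
    pathway_pair: tuple[str, str]
    epsilon_m: float
    epsilon_n: float
    ratio: float
    ratio_se: float
    interval: tuple[float, float]
    flagged: bool


def _eps_and_se(fit: FitResult, ligand: str) -> tuple[float, float]:
    name = f"epsilon[{ligand}]"
    if name not in fit.params:
        raise KeyError(name)
    eps = fit.params[name]
    se = fit.standard_errors.get(name, 0.0)
    return eps, se


def bias_table(fit_m: FitResult, fit_n: FitResult,
               pathway_pair: tuple[str, str] = ("m", "n"),
               ) -> list[BiasResult]:
    """Per-ligand efficacy ratios between two per-pathway fits.

    Both fits must cover the same ligands with the same fixed Kd values
    and each its own shared gain.  The ratio's standard error is the
    first-order delta method, ``SE(r) = r*sqrt((SE_m/e_m)^2 +
    (SE_n/e_n)^2)``; the cross-fit covariance is taken as zero since the
    two pathways are fitted separately.  Ligands missing from either fit
    are skipped with a warning; a near-zero denominator efficacy makes
    the ratio undefined (NaN, not flagged).
    """
    ligs_m = {k.split("[", 1)[1].rstrip("]") for k in fit_m.params
              if k.startswith("epsilon[")}
    ligs_n = {k.split("[", 1)[1].rstrip("]") for k in fit_n.params
              if k.startswith("epsilon[")}
    for missing in sorted(ligs_m ^ ligs_n):
        _warnings.warn(f"ligand {missing!r} missing from one fit; skipped")
    out: list[BiasResult] = []
    for lig in sorted(ligs_m & ligs_n):
        em, sem = _eps_and_se(fit_m, lig)
        en, sen = _eps_and_se(fit_n, lig)
        if en <= 1e-12:
            out.append(BiasResult(lig, pathway_pair, em, en, math.nan,
                                  math.nan, (math.nan, math.nan), False))
            continue
        ratio = em / en
        rel_m = (sem / em) ** 2 if em > 0 else 0.0
        se = ratio * math.sqrt(rel_m + (sen / en) ** 2)
        interval = (ratio - 2.0 * se, ratio + 2.0 * se)
        # numerical tie guard: solver-precision deviations from 1 with
        # near-zero SE (noiseless data) must not read as bias
        tol = 1e-6 * max(ratio, 1.0)
        flagged = not (interval[0] - tol <= 1.0 <= interval[1] + tol)
        out.append(BiasResult(lig, pathway_pair, em, en, ratio, se,
                              interval, flagged))
    return out


def bias_plot_curve(epsilon1, gamma1, epsilon2, gamma2,
                    f_resp1: np.ndarray | None = None,
                    n_points: int = 101) -> pd.DataFrame:
    """Relative-response ("bias plot") curve for one ligand.

    Returns a DataFrame of (f_resp1, f_resp2) along a grid of
    pathway-1 responses, with an ``at_half_occupancy`` marker column set
    on the grid point closest to the responses produced at 50% occupancy
    (ligand concentration equal to Kd).  Balanced ligands on pathways
    with unequal gains still give a curved line; only equal efficacies
    *and* gains give the diagonal.
    """
    fmax1 = max_response(epsilon1, gamma1)
    if f_resp1 is None:
        f_resp1 = np.linspace(0.0, fmax1, n_points)
    f_resp1 = np.asarray(f_resp1, dtype=float)
    f2 = relative_response(f_resp1, epsilon1, gamma1, epsilon2, gamma2)
    mark1 = response_from_occupancy(0.5, epsilon1, gamma1)
    mark2 = response_from_occupancy(0.5, epsilon2, gamma2)
    out = pd.DataFrame({"f_resp1": f_resp1, "f_resp2": f2})
    out["at_half_occupancy"] = False
    out.loc[(out["f_resp1"] - mark1).abs().idxmin(), "at_half_occupancy"] = True
    out.attrs["half_occupancy_point"] = (float(mark1), float(mark2))
    return out


def fit_relative_response(data: pd.DataFrame | Mapping[str, Sequence], *,
                          n_starts: int = 24, seed: int = 0,
                          max_iter: int = 500) -> FitResult:
    """Direct least-squares fit of relative-response curves.

    ``data`` holds columns ``ligand``, ``f_resp1``, ``f_resp2`` — the
    two pathways' fractional responses at matched concentrations.  Fits
    one gain per pathway (shared over ligands) and per-ligand efficacies
    on both pathways.  This route needs no binding data but is weakly
    identified: the relative-response curve depends only on the per-ligand
    efficacy ratio eps2/eps1 and the two gains (the absolute efficacy
    scale cancels), so individual efficacies are reported with a standing
    identifiability warning while ``result.extras["epsilon_ratio"]``
    carries the well-determined ratios with delta-method standard
    errors.  Under strong amplification even the ratios can carry large
    uncertainties, which is flagged as well.
    """
    df = pd.DataFrame(data)
    ligands = sorted(df["ligand"].astype(str).unique())
    f1 = df["f_resp1"].to_numpy(dtype=float)
    f2 = df["f_resp2"].to_numpy(dtype=float)
    lig_idx = np.array([ligands.index(v) for v in df["ligand"].astype(str)])
    nl = len(ligands)
    warnings_list: list[str] = []
    if nl == 1:
        warnings_list.append(
            "single-ligand relative-response fit is under-determined: only "
            "combinations of (eps1*g1, eps2*g2) are constrained")

    # x = [eps1 (nl), eps2 (nl), log10(g1-1+d), log10(g2-1+d)]
    delta = 1e-6

    def unpack(x):
        e1 = x[:nl]
        e2 = x[nl:2 * nl]
        g1 = 10.0 ** x[2 * nl] + 1.0 - delta
        g2 = 10.0 ** x[2 * nl + 1] + 1.0 - delta
        return e1, e2, g1, g2

    def resid(x):
        e1, e2, g1, g2 = unpack(x)
        a = e1[lig_idx]
        b = e2[lig_idx]
        num = b * g2 * f1
        den = a * g1 + (b * (g2 - 1.0) - a * (g1 - 1.0)) * f1
        return num / den - f2

    lo = np.concatenate([np.full(2 * nl, 1e-6), [-6.0, -6.0]])
    hi = np.concatenate([np.full(2 * nl, 1.0), [7.0, 7.0]])
    s_lo = np.concatenate([np.full(2 * nl, 0.05), [-2.0, -2.0]])
    s_hi = np.concatenate([np.full(2 * nl, 0.98), [4.0, 4.0]])
    from scipy.stats import qmc
    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    unit = sampler.random(n=max(n_starts - 1, 1))
    starts = [0.5 * (s_lo + s_hi)] + [s_lo + u * (s_hi - s_lo) for u in unit]

    best = None
    for x0 in starts[:n_starts]:
        sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                     ftol=1e-13, xtol=1e-14, gtol=1e-12,
                                     max_nfev=max_iter * (len(lo) + 1))
        ss = 2.0 * sol.cost
        if best is None or ss < best[0] - 1e-15:
            best = (ss, sol)
    sol = best[1]
    r = resid(sol.x)
    ss = float(r @ r)
    n = len(f1)
    k = len(lo)
    cov_x = _cov_from_jac(sol.jac, n, ss)
    e1, e2, g1, g2 = unpack(sol.x)
    dnat = np.concatenate([np.ones(2 * nl),
                           [math.log(10.0) * 10.0 ** sol.x[2 * nl],
                            math.log(10.0) * 10.0 ** sol.x[2 * nl + 1]]])
    cov = cov_x * np.outer(dnat, dnat)
    names = ([f"epsilon1[{l}]" for l in ligands]
             + [f"epsilon2[{l}]" for l in ligands]
             + ["gamma1", "gamma2"])
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    estimates = dict(zip(names, np.concatenate([e1, e2, [g1, g2]])))
    estimates = {k_: float(v) for k_, v in estimates.items()}
    se_d = {k_: float(v) for k_, v in zip(names, se)}
    warnings_list.append(
        "relative-response data determine only the per-ligand efficacy "
        "ratio eps2/eps1 and the pathway gains, not the absolute "
        "efficacies; see extras['epsilon_ratio']")
    ratio_rows = []
    for i, lig in enumerate(ligands):
        a, b = float(e1[i]), float(e2[i])
        r = b / a
        var = (r ** 2) * (cov[i, i] / a ** 2 + cov[nl + i, nl + i] / b ** 2
                          - 2.0 * cov[i, nl + i] / (a * b))
        r_se = math.sqrt(max(var, 0.0))
        ratio_rows.append({"ligand": lig, "ratio": r, "ratio_se": r_se})
        if r > 0 and r_se > r:
            warnings_list.append(
                f"efficacy ratio for ligand {lig!r} has standard error "
                "exceeding its value; efficacies are poorly identified "
                "from relative-response data alone (strong amplification)")
    obs_sst = float(np.sum((f2 - f2.mean()) ** 2))
    fit = FitResult(
        model="relative_response",
        estimates=estimates,
        standard_errors=se_d,
        covariance=pd.DataFrame(cov, index=names, columns=names),
        r_squared=1.0 - ss / obs_sst if obs_sst > 0 else math.nan,
        aicc=_aicc(n, k, ss),
        n_obs=n,
        n_free=k,
        converged=bool(sol.success),
        residuals=r,
        warnings=warnings_list,
        ss_res=ss,
        params=dict(estimates),
    )
    fit.extras["epsilon_ratio"] = pd.DataFrame(ratio_rows)
    for w in warnings_list:
        _warnings.warn(w, stacklevel=2)
    return fit
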