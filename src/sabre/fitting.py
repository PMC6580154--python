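"""Global nonlinear least-squares fitting of the SABRE model family.

A single fit can span many ligands, pathways, and receptor-inactivation
conditions, with a declarative :class:`SharingScheme` saying which
parameters are free, fixed to supplied values, or shared:

* ``kd`` and ``epsilon`` (or ``tau`` for the operational model) are
  ligand-scope parameters;
* ``gamma`` and ``epsilon_r0`` are pathway-scope (one shared gain per
  response system — the key to disentangling efficacy from
  amplification);
* ``q`` (surviving receptor fraction after irreversible inactivation) is
  condition-scope, with the reference condition pinned at ``q = 1``.

Internally the optimiser works in scale-free coordinates — ``log10(kd)``
and ``log10(gamma - 1 + delta)`` with ``delta = 1e-6`` so that
``gamma = 1`` is exactly reachable — while the fraction parameters
(``epsilon``, ``epsilon_r0``, ``q``) are box-bounded on their natural
scale so that boundary values such as a full agonist's ``epsilon = 1``
are exactly representable.  A deterministic Latin-hypercube multi-start
(16 starts by default, seeded) guards against local minima; the best
sum of squares wins, ties broken by fewer function evaluations then by
start order.
"""

from __future__ import annotations

import dataclasses
import math
import warnings as _warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

__all__ = [
    "DoseResponseTable",
    "SharingScheme",
    "FitResult",
    "LadderReport",
    "fit_global",
    "fit_response_vs_occupancy",
    "model_ladder",
    "predict",
    "residual_summary",
    "normalize_to_reference",
    "MODEL_ROLES",
]

_DELTA = 1e-6  # offset making gamma = 1 / tau = 0 reachable in log coords

#: Parameter roles used by each model variant.
MODEL_ROLES: dict[str, tuple[str, ...]] = {
    "clark": ("kd",),
    "emax": ("kd", "epsilon"),
    "sabre3": ("kd", "epsilon", "gamma"),
    "sabre4": ("kd", "epsilon", "gamma", "epsilon_r0"),
    "constitutive_no_amp": ("kd", "epsilon", "epsilon_r0"),
    "operational": ("kd", "tau"),
}

_ROLE_SCOPE = {
    "kd": "ligand",
    "epsilon": "ligand",
    "tau": "ligand",
    "gamma": "pathway",
    "epsilon_r0": "pathway",
    "q": "condition",
}

# models where receptor inactivation enters as apparent efficacy eps' = q*eps
_Q_MODELS = ("emax", "sabre3")


# ---------------------------------------------------------------------------
# data container

class DoseResponseTable:
    """Tidy table of concentration-response records.

    Wraps a pandas DataFrame with columns ``ligand``, ``pathway``,
    ``condition``, ``conc`` (molar, >= 0), ``response`` (fractional) and
    ``replicate``.  Missing ``pathway``/``condition``/``replicate``
    columns default to a single pathway, a ``control`` condition, and
    replicate 0.  Responses outside [-0.05, 1.05] are retained but
    flagged in :attr:`range_flags`.
    """

    COLUMNS = ("ligand", "pathway", "condition", "conc", "response",
               "replicate")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("ligand", "conc", "response"):
            if col not in df.columns:
                raise ValueError(f"missing required column '{col}'")
        if "pathway" not in df.columns:
            df["pathway"] = "pathway1"
        if "condition" not in df.columns:
            df["condition"] = "control"
        if "replicate" not in df.columns:
            df["replicate"] = 0
        df["conc"] = pd.to_numeric(df["conc"])
        df["response"] = pd.to_numeric(df["response"])
        if (df["conc"] < 0).any():
            rows = df.index[df["conc"] < 0].tolist()
            raise ValueError(f"negative concentration in rows {rows}")
        self._df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        out = ~self._df["response"].between(-0.05, 1.05)
        #: indices of responses outside the tolerated [-0.05, 1.05] band
        self.range_flags: list[int] = self._df.index[out].tolist()

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "DoseResponseTable":
        return cls(pd.DataFrame.from_records(records))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def ligands(self) -> list[str]:
        return sorted(self._df["ligand"].astype(str).unique())

    @property
    def pathways(self) -> list[str]:
        return sorted(self._df["pathway"].astype(str).unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self._df["condition"].astype(str).unique())

    def __len__(self) -> int:
        return len(self._df)

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sharing scheme and parameter table

@dataclasses.dataclass
class SharingScheme:
    """Declares which parameters are free, fixed, or shared.

    Each field accepts ``"free"``, a scalar (fixed for every label in the
    scope), or a mapping ``label -> value`` (fixed per label).  ``kd``,
    ``epsilon`` and ``tau`` are per-ligand; ``gamma`` and ``epsilon_r0``
    per-pathway; ``q`` per-condition.  When ``q`` is free the reference
    condition (default: ``"control"`` if present, else the first
    condition) stays fixed at 1, anchoring the epsilon/q confounding.
    """

    kd: str | float | Mapping[str, float] = "free"
    epsilon: str | float | Mapping[str, float] = "free"
    gamma: str | float | Mapping[str, float] = "free"
    epsilon_r0: str | float | Mapping[str, float] = "free"
    q: str | float | Mapping[str, float] = 1.0
    tau: str | float | Mapping[str, float] = "free"
    reference_condition: str | None = None


@dataclasses.dataclass
class _Param:
    name: str           # e.g. "epsilon[ACh]"
    role: str
    label: str
    free: bool
    value: float        # fixed value (if not free) / placeholder
    lo: float
    hi: float
    scale: str          # "linear" | "log10" | "log10_offset"
    offset: float = 0.0  # theta = 10**x + offset for "log10_offset"
    start_lo: float = 0.0  # start box, in internal coordinates
    start_hi: float = 1.0

    # internal <-> natural coordinate maps
    def to_internal(self, theta: float) -> float:
        if self.scale == "linear":
            return theta
        if self.scale == "log10":
            return math.log10(theta)
        return math.log10(max(theta - self.offset, 1e-300))

    def to_natural(self, x: float) -> float:
        if self.scale == "linear":
            return x
        if self.scale == "log10":
            return 10.0 ** x
        return 10.0 ** x + self.offset

    def dnatural_dinternal(self, x: float) -> float:
        if self.scale == "linear":
            return 1.0
        return math.log(10.0) * 10.0 ** x

    @property
    def bounds_internal(self) -> tuple[float, float]:
        if self.scale == "linear":
            return (self.lo, self.hi)
        if self.scale == "log10":
            return (math.log10(self.lo), math.log10(self.hi))
        return (math.log10(self.lo - self.offset),
                math.log10(self.hi - self.offset))


def _resolve(setting, labels: Sequence[str], role: str) -> dict[str, float] | None:
    """Resolve a scheme field to a fixed mapping, or None when free."""
    if isinstance(setting, str):
        if setting != "free":
            raise ValueError(f"scheme field {role!r}: unknown setting {setting!r}")
        return None
    if isinstance(setting, Mapping):
        missing = [la for la in labels if la not in setting]
        if missing:
            raise ValueError(f"scheme fixes {role} but misses labels {missing}")
        return {la: float(setting[la]) for la in labels}
    return {la: float(setting) for la in labels}


def _build_params(model: str, table: DoseResponseTable,
                  scheme: SharingScheme) -> list[_Param]:
    if model not in MODEL_ROLES:
        raise ValueError(f"unknown model {model!r}; choose from "
                         f"{sorted(MODEL_ROLES)}")
    roles = list(MODEL_ROLES[model])
    conditions = table.conditions
    q_setting = scheme.q
    q_active = (isinstance(q_setting, str) or isinstance(q_setting, Mapping)
                or float(q_setting) != 1.0) or len(conditions) > 1
    if q_active:
        q_fixed = _resolve(q_setting, conditions, "q")
        q_all_one = q_fixed is not None and all(v == 1.0 for v in q_fixed.values())
        if not q_all_one:
            if model not in _Q_MODELS:
                raise ValueError(
                    "receptor-inactivation fraction q is only defined for the "
                    f"{_Q_MODELS} variants (apparent efficacy eps' = q*eps)")
            roles.append("q")

    pos = table.df["conc"][table.df["conc"] > 0]
    cmin = float(pos.min()) if len(pos) else 1e-9
    cmax = float(pos.max()) if len(pos) else 1e-3
    kd_start = (math.log10(cmin) - 2.0, math.log10(cmax) + 1.0)

    scope_labels = {"ligand": table.ligands, "pathway": table.pathways,
                    "condition": conditions}
    defaults = {
        # role: (lo, hi, scale, offset, start box in internal coords)
        "kd": (1e-18, 1e6, "log10", 0.0, kd_start),
        "epsilon": (0.0, 1.0, "linear", 0.0, (0.02, 0.98)),
        "epsilon_r0": (0.0, 1.0 - 1e-9, "linear", 0.0, (0.01, 0.9)),
        "gamma": (1.0, 1e7, "log10_offset", 1.0 - _DELTA, (-3.0, 5.0)),
        "q": (_DELTA, 1.0, "linear", 0.0, (0.05, 1.0)),
        "tau": (0.0, 1e7, "log10_offset", -_DELTA, (-2.0, 5.0)),
    }

    ref_cond = scheme.reference_condition
    if ref_cond is None:
        ref_cond = "control" if "control" in conditions else conditions[0]

    params: list[_Param] = []
    for role in roles:
        labels = scope_labels[_ROLE_SCOPE[role]]
        fixed = _resolve(getattr(scheme, role), labels, role)
        lo, hi, scale, offset, (s_lo, s_hi) = defaults[role]
        for label in labels:
            free = fixed is None
            value = math.nan if free else fixed[label]
            if role == "q" and free and label == ref_cond:
                free, value = False, 1.0  # anchor: reference condition q = 1
            params.append(_Param(f"{role}[{label}]", role, label, free, value,
                                 lo, hi, scale, offset, s_lo, s_hi))
    return params


# ---------------------------------------------------------------------------
# fit result

@dataclasses.dataclass
class FitResult:
    """Outcome of a global fit.

    ``estimates`` and ``standard_errors`` are flat dicts keyed by
    ``role[label]`` names; ``params`` additionally contains the fixed
    parameters, so :func:`predict` can rebuild the model curve.
    """

    model: str
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    covariance: pd.DataFrame
    r_squared: float
    aicc: float
    n_obs: int
    n_free: int
    converged: bool
    residuals: np.ndarray
    warnings: list[str]
    ss_res: float
    params: dict[str, float]          # all parameters, fixed included
    extras: dict = dataclasses.field(default_factory=dict)

    def __repr__(self) -> str:  # compact, table-free
        est = ", ".join(f"{k}={v:.4g}" for k, v in self.estimates.items())
        return (f"FitResult(model={self.model!r}, r2={self.r_squared:.4f}, "
                f"n_obs={self.n_obs}, n_free={self.n_free}, "
                f"converged={self.converged}, {est})")


# ---------------------------------------------------------------------------
# model evaluation

def _eval_model(model: str, conc, kd, eps, gamma, eps_r0, q, tau):
    eps_eff = eps * q if eps is not None and q is not None else eps
    if model == "clark":
        return conc / (conc + kd)
    if model == "emax":
        return eps_eff * conc / (conc + kd)
    if model == "sabre3":
        eg = eps_eff * gamma
        return eg * conc / ((eg - eps_eff + 1.0) * conc + kd)
    if model == "sabre4":
        eg = eps * gamma
        e0g = eps_r0 * gamma
        return ((eg * conc + e0g * kd)
                / ((eg - eps + 1.0) * conc + (e0g - eps_r0 + 1.0) * kd))
    if model == "constitutive_no_amp":
        return (eps_r0 * kd + eps * conc) / (conc + kd)
    if model == "operational":
        return tau * conc / ((tau + 1.0) * conc + kd)
    raise ValueError(f"unknown model {model!r}")


class _Design:
    """Index maps from records to parameter labels, and the predictor."""

    def __init__(self, model: str, table: DoseResponseTable,
                 params: list[_Param]):
        self.model = model
        self.params = params
        df = table.df
        self.conc = df["conc"].to_numpy(dtype=float)
        self.obs = df["response"].to_numpy(dtype=float)
        self.by_role: dict[str, dict[str, int]] = {}
        order: list[_Param] = []
        for p in params:
            self.by_role.setdefault(p.role, {})[p.label] = len(order)
            order.append(p)
        self.order = order
        scope_col = {"ligand": "ligand", "pathway": "pathway",
                     "condition": "condition"}
        self.idx: dict[str, np.ndarray] = {}
        for role, labels in self.by_role.items():
            col = df[scope_col[_ROLE_SCOPE[role]]].astype(str)
            self.idx[role] = np.array([labels[v] for v in col])

    def predict_theta(self, theta: np.ndarray, conc=None) -> np.ndarray:
        conc = self.conc if conc is None else conc

        def role_vec(role, default=None):
            if role not in self.by_role:
                return default
            return theta[self.idx[role]]

        kd = role_vec("kd")
        eps = role_vec("epsilon")
        gamma = role_vec("gamma")
        eps_r0 = role_vec("epsilon_r0")
        q = role_vec("q", default=1.0 if eps is not None else None)
        tau = role_vec("tau")
        return _eval_model(self.model, conc, kd, eps, gamma, eps_r0, q, tau)


def _theta_full(design: _Design, x_free: np.ndarray) -> np.ndarray:
    theta = np.empty(len(design.order))
    j = 0
    for i, p in enumerate(design.order):
        if p.free:
            theta[i] = p.to_natural(x_free[j])
            j += 1
        else:
            theta[i] = p.value
    return theta


# ---------------------------------------------------------------------------
# the fitting engine

def _multistart_fit(design: _Design, weights: np.ndarray | None,
                    n_starts: int, seed: int, max_iter: int,
                    warnings_out: list[str]):
    free = [p for p in design.order if p.free]
    k = len(free)
    obs = design.obs
    w = np.ones_like(obs) if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)

    def resid(x):
        return sw * (design.predict_theta(_theta_full(design, x)) - obs)

    if k == 0:
        r = resid(np.empty(0))
        return None, r, free

    lo = np.array([p.bounds_internal[0] for p in free])
    hi = np.array([p.bounds_internal[1] for p in free])
    s_lo = np.maximum(np.array([p.start_lo for p in free]), lo)
    s_hi = np.minimum(np.array([p.start_hi for p in free]), hi)

    sampler = qmc.LatinHypercube(d=k, seed=seed)
    unit = sampler.random(n=max(n_starts - 1, 1))
    starts = [s_lo + u * (s_hi - s_lo) for u in unit]
    if n_starts > 1:
        starts.insert(0, 0.5 * (s_lo + s_hi))  # deterministic centre start

    best = None
    for x0 in starts[:n_starts]:
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                ftol=1e-13, xtol=1e-14, gtol=1e-12,
                max_nfev=max_iter * (k + 1))
        except Exception as exc:  # pragma: no cover - defensive
            warnings_out.append(f"start failed: {exc}")
            continue
        ss = 2.0 * sol.cost
        if (best is None or ss < best[0] - 1e-15
                or (abs(ss - best[0]) <= 1e-15 and sol.nfev < best[1].nfev)):
            best = (ss, sol)
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    return best[1], resid(best[1].x), free


def _cov_from_jac(J: np.ndarray, n_obs: int, ss: float) -> np.ndarray:
    """Asymptotic covariance s^2 (J'J)^-1 via SVD of J itself.

    Inverting J'J directly squares the condition number and can silently
    truncate a near-flat (weakly identified) direction, yielding
    overconfident standard errors; working on J keeps such directions
    and lets their variance blow up honestly.
    """
    k = J.shape[1]
    dof = max(n_obs - k, 1)
    s2 = ss / dof
    U, s, Vt = np.linalg.svd(J, full_matrices=False)
    cutoff = np.finfo(float).eps * max(J.shape) * (s[0] if len(s) else 0.0)
    inv_s2 = np.where(s > cutoff, 1.0 / np.maximum(s, 1e-300) ** 2, 0.0)
    return s2 * (Vt.T * inv_s2) @ Vt


def _covariance(sol, free: list[_Param], n_obs: int, ss: float):
    k = len(free)
    if sol is None or k == 0:
        return np.zeros((0, 0))
    cov_x = _cov_from_jac(sol.jac, n_obs, ss)
    d = np.array([p.dnatural_dinternal(x) for p, x in zip(free, sol.x)])
    return cov_x * np.outer(d, d)


def _aicc(n: int, k: int, ss: float) -> float:
    ss = max(ss, 1e-300)
    aic = n * math.log(ss / n) + 2 * k
    if n - k - 1 <= 0:
        return math.inf
    return aic + 2 * k * (k + 1) / (n - k - 1)


def _finish(model: str, design: _Design, sol, resid, free,
            warnings_list: list[str], n_obs: int) -> FitResult:
    ss = float(resid @ resid)
    obs = design.obs
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss / ss_tot if ss_tot > 0 else math.nan
    k = len(free)
    cov = _covariance(sol, free, n_obs, ss)
    names = [p.name for p in free]
    se = dict(zip(names, np.sqrt(np.clip(np.diag(cov), 0, None))))
    theta = _theta_full(design, sol.x if sol is not None else np.empty(0))
    all_params = {p.name: float(t) for p, t in zip(design.order, theta)}
    estimates = {p.name: all_params[p.name] for p in free}
    converged = bool(sol.success) if sol is not None else True
    if not converged:
        warnings_list.append("optimiser did not report convergence: "
                             + str(getattr(sol, "message", "")))
    return FitResult(
        model=model,
        estimates=estimates,
        standard_errors=se,
        covariance=pd.DataFrame(cov, index=names, columns=names),
        r_squared=r2,
        aicc=_aicc(n_obs, k, ss),
        n_obs=n_obs,
        n_free=k,
        converged=converged,
        residuals=np.asarray(resid),
        warnings=warnings_list,
        ss_res=ss,
        params=all_params,
    )


def _check_identifiability(fit: FitResult, design: _Design) -> None:
    """Warn when only the eps*gamma products are determined (high gain).

    Scaling every efficacy by c and the gain by 1/c keeps all eps*gamma
    products fixed; if the sum of squares is flat along that ray the
    individual efficacies are not identifiable from response data alone.
    """
    if "gamma" not in design.by_role or "epsilon" not in design.by_role:
        return
    free_names = set(fit.estimates)
    if not any(n.startswith("epsilon[") for n in free_names):
        return
    theta = np.array([fit.params[p.name] for p in design.order])
    # scale every efficacy by c and each gain by ~1/c; pick the direction
    # that stays inside the bounds (gamma can sit at its upper bound)
    alt = None
    for c in (0.5, 2.0):
        cand = theta.copy()
        ok = True
        for i, p in enumerate(design.order):
            if p.role == "epsilon":
                cand[i] = theta[i] * c
                ok &= p.lo <= cand[i] <= p.hi
            elif p.role == "gamma":
                cand[i] = 1.0 + (theta[i] - 1.0) / c  # eps*gamma ~ fixed
                ok &= p.lo <= cand[i] <= p.hi
        if ok:
            alt = cand
            break
    if alt is None:
        return
    obs = design.obs
    ss_alt = float(np.sum((design.predict_theta(alt) - obs) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_alt - fit.ss_res <= 1e-3 * max(ss_tot, 1e-12):
        fit.warnings.append(
            "identifiability: sum of squares is nearly flat when all "
            "efficacies are scaled down and the gain scaled up (only the "
            "eps*gamma products are well determined; strong amplification)")


def fit_global(data: DoseResponseTable | pd.DataFrame, model: str,
               scheme: SharingScheme | None = None, *,
               weights: np.ndarray | None = None,
               n_starts: int = 16, seed: int = 0,
               max_iter: int = 500) -> FitResult:
    """Fit one model variant globally across ligands/pathways/conditions.

    Minimises the (optionally weighted) sum of squared response residuals
    with bounded least squares; standard errors come from the
    Jacobian-based asymptotic covariance ``s^2 (J'J)^-1``.  Raises if
    there are fewer observations than free parameters and warns below
    the recommended 5-10 well-distributed points per adjustable
    parameter.
    """
    if not isinstance(data, DoseResponseTable):
        data = DoseResponseTable(data)
    scheme = scheme or SharingScheme()
    params = _build_params(model, data, scheme)
    warnings_list: list[str] = []
    if data.range_flags:
        warnings_list.append(
            f"{len(data.range_flags)} response(s) outside [-0.05, 1.05]")
    design = _Design(model, data, params)
    n_obs = len(data)
    k = sum(p.free for p in params)
    if n_obs < k:
        raise ValueError(f"{n_obs} observations cannot constrain {k} free "
                         "parameters")
    if k and n_obs < 5 * k:
        warnings_list.append(
            f"only {n_obs} observations for {k} adjustable parameters; "
            "adequate fitting requires 5-10 well-distributed data points "
            "per adjustable parameter")
    sol, resid, free = _multistart_fit(design, weights, n_starts, seed,
                                       max_iter, warnings_list)
    fit = _finish(model, design, sol, resid, free, warnings_list, n_obs)
    fit.extras["design"] = design
    fit.extras["scheme"] = scheme
    _check_identifiability(fit, design)
    for w in fit.warnings:
        _warnings.warn(w, stacklevel=2)
    return fit


# ---------------------------------------------------------------------------
# response-versus-occupancy fitting

class _OccDesign(_Design):
    """Design over (f_occup, f_resp) pairs; the hyperbola in occupancy."""

    def __init__(self, pairs: pd.DataFrame, params: list[_Param]):
        self.model = "occupancy"
        self.params = params
        self.conc = pairs["f_occup"].to_numpy(dtype=float)  # abscissa
        self.obs = pairs["f_resp"].to_numpy(dtype=float)
        self.by_role = {}
        order: list[_Param] = []
        for p in params:
            self.by_role.setdefault(p.role, {})[p.label] = len(order)
            order.append(p)
        self.order = order
        col = {"ligand": pairs["ligand"].astype(str),
               "pathway": pairs["pathway"].astype(str)}
        self.idx = {role: np.array([labels[v]
                                    for v in col[_ROLE_SCOPE[role]]])
                    for role, labels in self.by_role.items()}

    def predict_theta(self, theta, conc=None):
        f = self.conc if conc is None else conc
        eps = theta[self.idx["epsilon"]]
        gamma = theta[self.idx["gamma"]]
        return eps * gamma * f / (eps * (gamma - 1.0) * f + 1.0)


def fit_response_vs_occupancy(pairs, scheme: SharingScheme | None = None, *,
                              n_starts: int = 16, seed: int = 0,
                              max_iter: int = 500) -> FitResult:
    """Fit fractional response directly against fractional occupancy.

    ``pairs`` is a DataFrame (or sequence of
    :class:`~sabre.occupancy.OccupancyResponsePair`) with columns
    ``ligand``, ``f_occup``, ``f_resp`` and optional ``pathway``.
    Occupancies are normally precomputed from independently measured Kd.
    One shared gain per pathway and one efficacy per ligand are fitted.
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame([dataclasses.asdict(p) for p in pairs]).rename(
            columns={"ligand_id": "ligand", "pathway_id": "pathway"})
    pairs = pairs.copy()
    if "pathway" not in pairs.columns:
        pairs["pathway"] = "pathway1"
    else:
        pairs["pathway"] = pairs["pathway"].replace("", "pathway1")
    scheme = scheme or SharingScheme()
    ligands = sorted(pairs["ligand"].astype(str).unique())
    pathways = sorted(pairs["pathway"].astype(str).unique())
    warnings_list: list[str] = []
    if len(ligands) == 1:
        warnings_list.append(
            "single-ligand occupancy fit: epsilon and gamma are only "
            "constrained through eps*gamma and eps*(gamma-1); estimates "
            "are degenerate")

    params: list[_Param] = []
    eps_fixed = _resolve(scheme.epsilon, ligands, "epsilon")
    for la in ligands:
        free = eps_fixed is None
        params.append(_Param(f"epsilon[{la}]", "epsilon", la, free,
                             math.nan if free else eps_fixed[la],
                             0.0, 1.0, "linear", 0.0, 0.02, 0.98))
    g_fixed = _resolve(scheme.gamma, pathways, "gamma")
    for la in pathways:
        free = g_fixed is None
        params.append(_Param(f"gamma[{la}]", "gamma", la, free,
                             math.nan if free else g_fixed[la],
                             1.0, 1e7, "log10_offset", 1.0 - _DELTA,
                             -3.0, 5.0))

    design = _OccDesign(pairs, params)
    n_obs = len(pairs)
    k = sum(p.free for p in params)
    if n_obs < k:
        raise ValueError(f"{n_obs} pairs cannot constrain {k} parameters")
    if k and n_obs < 5 * k:
        warnings_list.append(
            f"only {n_obs} observations for {k} adjustable parameters; "
            "adequate fitting requires 5-10 well-distributed data points "
            "per adjustable parameter")
    sol, resid, free = _multistart_fit(design, None, n_starts, seed,
                                       max_iter, warnings_list)
    fit = _finish("occupancy", design, sol, resid, free, warnings_list, n_obs)
    fit.extras["design"] = design
    _check_identifiability(fit, design)
    for w in fit.warnings:
        _warnings.warn(w, stacklevel=2)
    return fit


# ---------------------------------------------------------------------------
# nested model ladder

_LADDER = ("clark", "emax", "sabre3", "sabre4")


@dataclasses.dataclass
class LadderReport:
    """Nested-model comparison along clark -> emax -> sabre3 -> sabre4."""

    fits: dict[str, FitResult]
    f_tests: pd.DataFrame   # simpler, richer, F, p, df
    recommended: str
    alpha: float

    def summary(self) -> pd.DataFrame:
        rows = [{"model": m, "n_free": f.n_free, "ss_res": f.ss_res,
                 "r_squared": f.r_squared, "aicc": f.aicc}
                for m, f in self.fits.items()]
        return pd.DataFrame(rows)


def extra_ss_f_test(fit_simple: FitResult, fit_rich: FitResult,
                    n_obs: int) -> tuple[float, float]:
    """Extra-sum-of-squares F test between two nested fits."""
    df1 = n_obs - fit_simple.n_free
    df2 = n_obs - fit_rich.n_free
    if df1 <= df2 or df2 <= 0:
        return math.nan, math.nan
    num = max(fit_simple.ss_res - fit_rich.ss_res, 0.0) / (df1 - df2)
    den = fit_rich.ss_res / df2
    if den == 0.0:
        f = 0.0 if num == 0.0 else math.inf
    else:
        f = num / den
    p = float(stats.f.sf(f, df1 - df2, df2)) if math.isfinite(f) else 0.0
    return f, p


def model_ladder(data: DoseResponseTable | pd.DataFrame,
                 scheme: SharingScheme | None = None, *,
                 models: Sequence[str] = _LADDER, alpha: float = 0.05,
                 n_starts: int = 16, seed: int = 0) -> LadderReport:
    """Fit the nested model sequence and recommend the simplest adequate one.

    Starts from the most constrained form and releases constraints
    sequentially; each release is kept only if the extra-sum-of-squares F
    test says it significantly improves the fit (AICc is reported
    alongside).
    """
    models = [m for m in _LADDER if m in models]
    if not models:
        raise ValueError("models must contain at least one of "
                         f"{_LADDER}")
    if not isinstance(data, DoseResponseTable):
        data = DoseResponseTable(data)
    fits = {m: fit_global(data, m, scheme, n_starts=n_starts, seed=seed)
            for m in models}
    rows = []
    improved_upon: dict[str, bool] = {m: False for m in models}
    for i, simple in enumerate(models):
        for rich in models[i + 1:]:
            f, p = extra_ss_f_test(fits[simple], fits[rich], len(data))
            rows.append({"simpler": simple, "richer": rich, "F": f, "p": p})
            if not math.isnan(p) and p < alpha:
                improved_upon[simple] = True
    # simplest model that no richer model significantly improves upon
    recommended = next((m for m in models if not improved_upon[m]),
                       models[-1])
    return LadderReport(fits=fits, f_tests=pd.DataFrame(rows),
                        recommended=recommended, alpha=alpha)


# ---------------------------------------------------------------------------
# prediction and diagnostics

def predict(fit: FitResult, data: DoseResponseTable | pd.DataFrame) -> np.ndarray:
    """Model responses at each record of ``data`` under a fitted model."""
    if not fit.converged:
        _warnings.warn("predicting from a fit that did not converge")
    if not isinstance(data, DoseResponseTable):
        data = DoseResponseTable(data)
    design: _Design = fit.extras["design"]
    df = data.df
    scope_col = {"ligand": "ligand", "pathway": "pathway",
                 "condition": "condition"}
    theta_map = fit.params

    def vec(role, default=None):
        if role not in design.by_role:
            return default
        col = df[scope_col[_ROLE_SCOPE[role]]].astype(str)
        out = np.empty(len(df))
        for i, label in enumerate(col):
            name = f"{role}[{label}]"
            if name not in theta_map:
                raise ValueError(f"unknown {_ROLE_SCOPE[role]} label "
                                 f"{label!r} for fitted model")
            out[i] = theta_map[name]
        return out

    conc = df["conc"].to_numpy(dtype=float)
    eps = vec("epsilon")
    return _eval_model(fit.model, conc, vec("kd"), eps, vec("gamma"),
                       vec("epsilon_r0"),
                       vec("q", default=1.0 if eps is not None else None),
                       vec("tau"))


def residual_summary(fit: FitResult,
                     data: DoseResponseTable | pd.DataFrame | None = None) -> dict:
    """Residual diagnostics: SS_res, RMSE, and per-ligand r-squared."""
    out = {"ss_res": fit.ss_res,
           "rmse": math.sqrt(fit.ss_res / fit.n_obs),
           "r_squared": fit.r_squared,
           "max_abs_residual": float(np.max(np.abs(fit.residuals)))}
    design: _Design = fit.extras["design"]
    lig_role = next((r for r in ("kd", "epsilon", "tau")
                     if r in getattr(design, "idx", {})), None)
    if lig_role is not None:
        labels = design.by_role[lig_role]
        if labels:
            obs = design.obs
            res = fit.residuals
            per = {}
            lig_idx = design.idx[lig_role]
            for label, j in labels.items():
                m = lig_idx == j
                if m.sum() > 1:
                    sst = float(np.sum((obs[m] - obs[m].mean()) ** 2))
                    ssr = float(np.sum(res[m] ** 2))
                    per[label] = 1.0 - ssr / sst if sst > 0 else math.nan
            out["r_squared_by_ligand"] = per
    return out


def normalize_to_reference(data: DoseResponseTable | pd.DataFrame,
                           ligand: str) -> DoseResponseTable:
    """Rescale all responses by the fitted top of a reference full agonist.

    Fits a two-parameter hyperbola (top, EC50) to the reference ligand's
    records and divides every response in the table by the fitted top,
    turning raw readouts into fractional responses.
    """
    if not isinstance(data, DoseResponseTable):
        data = DoseResponseTable(data)
    df = data.df
    sub = df[df["ligand"].astype(str) == str(ligand)]
    if sub.empty:
        raise ValueError(f"reference ligand {ligand!r} not in table")
    conc = sub["conc"].to_numpy(dtype=float)
    resp = sub["response"].to_numpy(dtype=float)

    def resid(p):
        top, lec50 = p
        return top * conc / (conc + 10.0 ** lec50) - resp

    pos = conc[conc > 0]
    x0 = [max(resp.max(), 1e-6), math.log10(np.median(pos))]
    sol = optimize.least_squares(resid, x0)
    top = float(sol.x[0])
    if top <= 0:
        raise ValueError("fitted reference top is non-positive")
    out = df.copy()
    out["response"] = out["response"] / top
    return DoseResponseTable(out)
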