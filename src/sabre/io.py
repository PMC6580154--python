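"""Reading/writing dose-response tables, configs, and structured reports.

The single ingest format is a long (tidy) delimited text file with a
header: required columns ``ligand``, ``conc``, ``response``; optional
``pathway``, ``condition``, ``replicate``.  Concentrations are molar by
default; with ``log_conc=True`` (the ``--log-conc`` CLI flag) the column
is read as log10-molar, matching the way concentration axes are usually
tabulated.  Configuration is a flat YAML key-value document.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import LigandParams, SystemParams
from .datasim import SimDesign
from .fitting import DoseResponseTable, FitResult, SharingScheme

__all__ = [
    "read_dose_response",
    "write_dose_response",
    "read_config",
    "scheme_from_config",
    "design_from_config",
    "ReportBundle",
    "fit_to_dict",
]

_REQUIRED = ("ligand", "conc", "response")


def read_dose_response(path, *, log_conc: bool = False,
                       sep: str = ",") -> DoseResponseTable:
    """Read a tidy dose-response CSV, validating as it goes.

    Unparseable numbers and negative concentrations raise errors naming
    the offending data rows (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    for col in ("conc", "response"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()] + 1
        if len(bad):
            raise ValueError(
                f"column '{col}': unparseable value(s) in data row(s) "
                f"{bad.tolist()} of {path}")
        df[col] = parsed
    if log_conc:
        df["conc"] = 10.0 ** df["conc"]
    neg = df.index[df["conc"] < 0] + 1
    if len(neg):
        raise ValueError(f"negative concentration in data row(s) "
                         f"{neg.tolist()} of {path}")
    return DoseResponseTable(df)


def write_dose_response(table: DoseResponseTable, path) -> None:
    table.to_csv(path)


def read_config(path) -> dict:
    """Load a flat YAML config document."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config {path} must be a mapping")
    return dict(cfg)


def scheme_from_config(cfg: Mapping) -> SharingScheme:
    """Build a SharingScheme from config keys (kd, epsilon, gamma, ...)."""
    kwargs = {}
    for field in ("kd", "epsilon", "gamma", "epsilon_r0", "q", "tau",
                  "reference_condition"):
        if field in cfg:
            kwargs[field] = cfg[field]
    return SharingScheme(**kwargs)


def design_from_config(cfg: Mapping) -> tuple[SimDesign, str]:
    """Build a simulation design (and model label) from a config mapping.

    Expected keys: ``model``; ``ligands`` mapping label -> {kd, epsilon};
    optional ``pathways`` mapping label -> {gamma, epsilon_r0};
    optional ``conditions`` mapping label -> q; ``noise_sd``,
    ``n_replicates``, ``n_grid``, ``conc_grid``, ``seed``.
    """
    model = cfg.get("model", "sabre3")
    ligands = {str(k): LigandParams(**v) for k, v in cfg["ligands"].items()}
    pathways = {str(k): SystemParams(**v)
                for k, v in cfg.get("pathways",
                                    {"pathway1": {}}).items()}
    conditions = {str(k): float(v)
                  for k, v in cfg.get("conditions", {"control": 1.0}).items()}
    design = SimDesign(
        ligands=ligands, pathways=pathways, conditions=conditions,
        conc_grid=cfg.get("conc_grid"), n_grid=int(cfg.get("n_grid", 10)),
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        n_replicates=int(cfg.get("n_replicates", 1)),
        seed=int(cfg.get("seed", 0)),
        taus={str(k): float(v) for k, v in cfg["taus"].items()}
        if "taus" in cfg else None)
    return design, model


# ---------------------------------------------------------------------------
# structured report

def fit_to_dict(fit: FitResult) -> dict:
    """JSON-ready representation of a FitResult (full float precision)."""
    return {
        "model": fit.model,
        "estimates": fit.estimates,
        "standard_errors": fit.standard_errors,
        "covariance": {"names": list(fit.covariance.index),
                       "matrix": fit.covariance.to_numpy().tolist()},
        "r_squared": fit.r_squared,
        "aicc": fit.aicc,
        "n_obs": fit.n_obs,
        "n_free": fit.n_free,
        "converged": fit.converged,
        "ss_res": fit.ss_res,
        "residuals": np.asarray(fit.residuals).tolist(),
        "params": fit.params,
        "warnings": list(fit.warnings),
    }


@dataclasses.dataclass
class ReportBundle:
    """Serializable bundle of everything a run produced.

    Round-trips losslessly through JSON: floats are serialized at full
    ``repr`` precision.
    """

    metadata: dict = dataclasses.field(default_factory=dict)
    fit: dict | None = None
    predictions: list | None = None
    model_selection: dict | None = None
    bias: list | None = None
    furchgott: dict | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2,
                          allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ReportBundle":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                with open(source) as fh:
                    data = json.load(fh)
            except (OSError, ValueError):
                data = json.loads(source)
        return cls(**data)
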