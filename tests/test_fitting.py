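"""Global fitting: recovery, sharing, model selection, diagnostics."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import sabre
from sabre.core import LigandParams, SystemParams
from sabre.datasim import SimDesign, simulate_dataset
from sabre.fitting import extra_ss_f_test, normalize_to_reference
from sabre.occupancy import response_from_occupancy


def _quiet_fit(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sabre.fit_global(*args, **kwargs)


@pytest.fixture
def two_ligand_sabre3():
    design = SimDesign(
        ligands={"L1": LigandParams(1e-7, 1.0), "L2": LigandParams(1e-6, 0.25)},
        pathways={"p": SystemParams(gamma=10.0)}, n_grid=8)
    return design, simulate_dataset(design, "sabre3")


def test_clark_noiseless_recovery():
    design = SimDesign(ligands={"L": LigandParams(1e-7)}, n_grid=8)
    table = simulate_dataset(design, "clark")
    fit = _quiet_fit(table, "clark")
    assert fit.estimates["kd[L]"] == pytest.approx(1e-7, rel=1e-6)
    assert fit.ss_res <= 1e-12


def test_sabre3_kd_anchored_recovery(two_ligand_sabre3):
    """With independently supplied Kd fixed, shared gain and per-ligand
    efficacies are recovered from noiseless curves."""
    design, table = two_ligand_sabre3
    scheme = sabre.SharingScheme(kd={"L1": 1e-7, "L2": 1e-6})
    fit = _quiet_fit(table, "sabre3", scheme)
    assert fit.ss_res <= 1e-12
    assert fit.estimates["epsilon[L1]"] == pytest.approx(1.0, rel=1e-4)
    assert fit.estimates["epsilon[L2]"] == pytest.approx(0.25, rel=1e-4)
    assert fit.estimates["gamma[p]"] == pytest.approx(10.0, rel=1e-4)


def test_noisy_recovery_bounds_and_bound_respect(two_ligand_sabre3):
    design, _ = two_ligand_sabre3
    noisy = dataclasses.replace(design, noise_sd=0.02, n_grid=10, seed=17)
    table = simulate_dataset(noisy, "sabre3")
    fit = _quiet_fit(table, "sabre3",
                     sabre.SharingScheme(kd={"L1": 1e-7, "L2": 1e-6}))
    assert 0.0 <= fit.estimates["epsilon[L1]"] <= 1.0
    assert 0.0 <= fit.estimates["epsilon[L2]"] <= 1.0
    assert fit.estimates["gamma[p]"] >= 1.0
    assert fit.estimates["epsilon[L2]"] == pytest.approx(0.25, abs=0.1)


def test_unit_invariance():
    """Rescaling conc and supplied Kd by a common factor leaves the
    unitless estimates and r^2 unchanged and rescales fitted Kd."""
    design = SimDesign(
        ligands={"ag": LigandParams(1e-7, 1.0)},
        pathways={"r": SystemParams(gamma=40.0)},
        conditions={"control": 1.0, "a": 0.3, "b": 0.05},
        n_grid=10, noise_sd=0.01, seed=5)
    table = simulate_dataset(design, "sabre3")
    scheme = sabre.SharingScheme(q="free")
    fit1 = _quiet_fit(table, "sabre3", scheme)
    scaled = table.df.copy()
    scaled["conc"] *= 1e3
    fit2 = _quiet_fit(sabre.DoseResponseTable(scaled), "sabre3", scheme)
    assert fit2.estimates["epsilon[ag]"] == pytest.approx(
        fit1.estimates["epsilon[ag]"], rel=1e-5)
    assert fit2.estimates["gamma[r]"] == pytest.approx(
        fit1.estimates["gamma[r]"], rel=1e-4)
    assert fit2.estimates["kd[ag]"] == pytest.approx(
        1e3 * fit1.estimates["kd[ag]"], rel=1e-4)
    assert fit2.r_squared == pytest.approx(fit1.r_squared, abs=1e-9)


def test_too_few_observations_raises_and_guidance_warning():
    df = pd.DataFrame({"ligand": ["L"] * 2, "conc": [1e-8, 1e-6],
                       "response": [0.1, 0.9]})
    with pytest.raises(ValueError, match="observations"):
        sabre.fit_global(df, "sabre3")
    design = SimDesign(ligands={"L": LigandParams(1e-7, 0.5)},
                       pathways={"p": SystemParams(gamma=5.0)}, n_grid=6)
    table = simulate_dataset(design, "sabre3")
    with pytest.warns(UserWarning, match="5-10 well-distributed"):
        fit = sabre.fit_global(table, "sabre3")
    assert any("5-10" in w for w in fit.warnings)


def test_q_rejected_for_constitutive_models():
    design = SimDesign(ligands={"L": LigandParams(1e-7, 0.5)},
                       conditions={"control": 1.0, "inact": 0.3}, n_grid=8)
    table = simulate_dataset(design, "sabre3")
    with pytest.raises(ValueError, match="q is only defined"):
        sabre.fit_global(table, "sabre4", sabre.SharingScheme(q="free"))


def test_identifiability_warning_high_gain():
    """Strong amplification: only eps*gamma is determined and the fit
    says so."""
    design = SimDesign(
        ligands={"A": LigandParams(1e-8, 1.0), "B": LigandParams(1e-7, 0.5)},
        pathways={"p": SystemParams(gamma=10000.0)},
        n_grid=10, noise_sd=0.01, seed=3)
    table = simulate_dataset(design, "sabre3")
    fit = _quiet_fit(table, "sabre3",
                     sabre.SharingScheme(kd={"A": 1e-8, "B": 1e-7}),
                     n_starts=6)
    assert any("eps*gamma" in w for w in fit.warnings)


# ---------------------------------------------------------------------------
# response-versus-occupancy fitting

def test_fit_response_vs_occupancy_exact_recovery():
    rows = []
    for lig, eps in [("a", 1.0), ("b", 0.5), ("c", 0.1)]:
        for f in np.linspace(0.05, 0.95, 10):
            rows.append({"ligand": lig, "f_occup": f,
                         "f_resp": response_from_occupancy(f, eps, 12.0)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sabre.fit_response_vs_occupancy(pd.DataFrame(rows))
    assert fit.estimates["gamma[pathway1]"] == pytest.approx(12.0, rel=1e-6)
    for lig, eps in [("a", 1.0), ("b", 0.5), ("c", 0.1)]:
        assert fit.estimates[f"epsilon[{lig}]"] == pytest.approx(eps,
                                                                 rel=1e-6)


def test_fit_response_vs_occupancy_single_ligand_degenerate():
    rows = [{"ligand": "only", "f_occup": f,
             "f_resp": response_from_occupancy(f, 1.0, 8.0)}
            for f in np.linspace(0.05, 0.95, 12)]
    with pytest.warns(UserWarning, match="degenerate"):
        fit = sabre.fit_response_vs_occupancy(pd.DataFrame(rows))
    assert any("degenerate" in w for w in fit.warnings)


def test_fit_response_vs_occupancy_identity_data():
    """Responses equal to occupancies force gamma=1, eps=1."""
    f = np.linspace(0.05, 0.95, 15)
    rows = [{"ligand": "x", "f_occup": v, "f_resp": v} for v in f]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sabre.fit_response_vs_occupancy(pd.DataFrame(rows))
    assert fit.estimates["epsilon[x]"] == pytest.approx(1.0, abs=1e-5)
    assert fit.estimates["gamma[pathway1]"] == pytest.approx(1.0, abs=1e-4)


# ---------------------------------------------------------------------------
# model ladder

def test_ladder_selects_clark_on_clark_data():
    design = SimDesign(ligands={"L": LigandParams(1e-7)}, n_grid=10,
                       noise_sd=0.01, seed=3)
    table = simulate_dataset(design, "clark")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = sabre.model_ladder(table, sabre.SharingScheme(kd={"L": 1e-7}))
    assert report.recommended == "clark"


def test_ladder_selects_sabre3_on_amplified_data():
    design = SimDesign(ligands={"L": LigandParams(1e-7, 0.3)},
                       pathways={"p": SystemParams(gamma=30.0)},
                       n_grid=10, noise_sd=0.01, seed=3)
    table = simulate_dataset(design, "sabre3")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = sabre.model_ladder(table, sabre.SharingScheme(kd={"L": 1e-7}))
    assert report.recommended == "sabre3"
    assert set(report.fits) == {"clark", "emax", "sabre3", "sabre4"}


def test_f_statistic_zero_for_identical_ss():
    a = dataclasses.replace
    base = dict(model="clark", estimates={}, standard_errors={},
                covariance=pd.DataFrame(), r_squared=0.9, aicc=0.0,
                n_obs=20, converged=True, residuals=np.zeros(1),
                warnings=[], params={})
    simple = sabre.FitResult(n_free=1, ss_res=0.5, **base)
    rich = sabre.FitResult(n_free=3, ss_res=0.5, **base)
    f, p = extra_ss_f_test(simple, rich, 20)
    assert f == 0.0 and p == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# prediction and diagnostics

def test_predict_reproduces_training_residuals(two_ligand_sabre3):
    design, table = two_ligand_sabre3
    fit = _quiet_fit(table, "sabre3",
                     sabre.SharingScheme(kd={"L1": 1e-7, "L2": 1e-6}))
    pred = sabre.predict(fit, table)
    np.testing.assert_allclose(
        pred - table.df["response"].to_numpy(), fit.residuals, atol=1e-12)
    with pytest.raises(ValueError, match="unknown"):
        sabre.predict(fit, pd.DataFrame(
            {"ligand": ["nope"], "conc": [1e-7], "response": [0.5]}))


def test_predict_basal_and_monotone_for_sabre4():
    design = SimDesign(
        ligands={"L": LigandParams(1e-7, 0.9)},
        pathways={"p": SystemParams(gamma=5.0, epsilon_r0=0.2)}, n_grid=12)
    table = simulate_dataset(design, "sabre4")
    fit = _quiet_fit(table, "sabre4", sabre.SharingScheme(kd={"L": 1e-7}))
    grid = pd.DataFrame({"ligand": "L", "pathway": "p",
                         "conc": np.concatenate(([0.0],
                                                 np.geomspace(1e-11, 1e-3,
                                                              200))),
                         "response": 0.0})
    pred = sabre.predict(fit, grid)
    assert pred[0] == pytest.approx(
        sabre.basal_response(fit.params["epsilon_r0[p]"],
                             fit.params["gamma[p]"]), rel=1e-10)
    assert np.all(np.diff(pred) >= -1e-12)


def test_residual_summary_contents(two_ligand_sabre3):
    _, table = two_ligand_sabre3
    fit = _quiet_fit(table, "sabre3",
                     sabre.SharingScheme(kd={"L1": 1e-7, "L2": 1e-6}))
    summary = sabre.residual_summary(fit)
    assert summary["ss_res"] == pytest.approx(fit.ss_res)
    assert set(summary["r_squared_by_ligand"]) == {"L1", "L2"}


def test_normalize_to_reference():
    design = SimDesign(ligands={"ref": LigandParams(1e-7, 1.0),
                                "other": LigandParams(1e-6, 0.4)}, n_grid=10)
    table = simulate_dataset(design, "emax")
    raw = table.df.copy()
    raw["response"] *= 1.8   # raw assay units, not fractional
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalized = normalize_to_reference(raw, "ref")
    np.testing.assert_allclose(normalized.df["response"],
                               table.df["response"], atol=1e-6)


def test_dose_response_table_validation():
    with pytest.raises(ValueError, match="required column"):
        sabre.DoseResponseTable(pd.DataFrame({"conc": [1.0]}))
    with pytest.raises(ValueError, match="negative"):
        sabre.DoseResponseTable(pd.DataFrame(
            {"ligand": ["a"], "conc": [-1.0], "response": [0.5]}))
    t = sabre.DoseResponseTable(pd.DataFrame(
        {"ligand": ["a", "a"], "conc": [1e-8, 1e-6],
         "response": [0.2, 1.5]}))
    assert t.range_flags == [1]
    assert t.pathways == ["pathway1"] and t.conditions == ["control"]
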