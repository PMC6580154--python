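# sabre-pharm

Simulation, global fitting, and interpretation of complex
concentration–response data with the SABRE receptor model family
(**S**ignal **A**mplification, **B**inding affinity, **R**eceptor-activation
**E**fficacy).

## Who this is for

Quantitative pharmacologists analysing functional assay data where
fractional response does not match fractional receptor occupancy:
partial agonist series with receptor reserve, responses measured before
and after irreversible receptor inactivation (Furchgott experiments),
multi-pathway readouts suspected of biased agonism, and constitutively
active receptors with inverse agonists.

## The model

SABRE is a two-state receptor model that separates three processes,
each with its own parameter:

* **binding** — the equilibrium dissociation constant *K*<sub>d</sub>
  (molar), an ensemble average over active and inactive receptor
  conformations, directly comparable to binding-assay measurements and
  related to the binding free energy by ΔG° = −*RT* ln *K*<sub>d</sub>;
* **activation** — the intrinsic efficacy ε ∈ [0, 1], the fraction of
  ligand-bound receptors that are active (0 for an antagonist, 1 for a
  full agonist), plus a basal receptor efficacy ε<sub>R0</sub> ∈ [0, 1)
  for constitutive activity;
* **amplification** — a pathway-specific gain γ ≥ 1 describing the
  hyperbolic post-receptor transduction cascade.

The full four-parameter fractional response is

    E/Emax = (εγ[L] + ε_R0 γ K_d) / ((εγ − ε + 1)[L] + (ε_R0 γ − ε_R0 + 1) K_d)

and fixing parameters walks down a nested ladder: ε<sub>R0</sub> = 0
gives the three-parameter model with maximal response εγ/(εγ + 1 − ε)
and EC₅₀ = *K*<sub>d</sub>/(εγ + 1 − ε); γ = 1 gives the E<sub>max</sub>
model for partial agonists; ε = 1 gives the Clark equation.  The
operational (Black–Leff) model, whose transducer ratio τ conflates
activation and amplification, is included for comparison.

Because efficacy and gain are separate, the model links response to
independently measured occupancy (f_resp = εγ f_occup / (ε(γ−1) f_occup + 1)),
turns irreversible inactivation of a fraction 1−q of receptors into an
apparent efficacy ε′ = qε, and quantifies biased agonism as per-ligand
efficacy ratios between pathways — no reference agonist needed.

## Worked example

Five ligands (a full agonist down to a very weak partial agonist) read
out on one pathway with 12-fold amplification, σ = 0.02 Gaussian noise;
a single shared gain plus five efficacies are fitted with the
independently known *K*<sub>d</sub> values held fixed:

```python
import sabre
from sabre.datasim import make_case_fixture

design, table = make_case_fixture("reserve_series")
kd = {name: lp.kd for name, lp in design.ligands.items()}
fit = sabre.fit_global(table, "sabre3", sabre.SharingScheme(kd=kd), seed=0)
print(f"r^2 = {fit.r_squared:.4f}, gain gamma = "
      f"{fit.estimates['gamma[contraction]']:.2f} +/- "
      f"{fit.standard_errors['gamma[contraction]']:.2f}")
for name in design.ligands:
    est = fit.estimates[f"epsilon[{name}]"]
    se = fit.standard_errors[f"epsilon[{name}]"]
    print(f"  epsilon[{name}] = {est:.3f} +/- {se:.3f}")
occ = sabre.occupancy_at_half_response(1.0, fit.estimates["gamma[contraction]"])
print(f"full agonist reaches half-maximal response at {100*occ:.1f}% occupancy")
```

prints

```
r^2 = 0.9985, gain gamma = 14.10 +/- 1.33
  epsilon[L1] = 0.865 +/- 0.068
  epsilon[L2] = 0.549 +/- 0.043
  epsilon[L3] = 0.266 +/- 0.022
  epsilon[L4] = 0.086 +/- 0.008
  epsilon[L5] = 0.027 +/- 0.003
full agonist reaches half-maximal response at 6.6% occupancy
```

The fit explains 99.9% of the variance with one shared gain; the
efficacy ladder (generating values 1.0, 0.60, 0.30, 0.10, 0.03) is
recovered within roughly two standard errors at this noise level, and
the fitted gain translates into a receptor reserve: half-maximal
response at only ~7% occupancy for the full agonist.

## Command line

```sh
sabre simulate  --config design.yaml --out data.csv
sabre fit       --data data.csv --config fit.yaml --out report.json
sabre furchgott --data inactivation.csv --out furchgott.json
sabre bias      --data two_pathway.csv --kd-file kd.yaml --out bias.json
sabre curves    --model sabre3 --kd 1e-7 --epsilon 1 --gamma 10 --out curve.csv
```

Data files are tidy CSV (`ligand, conc, response` plus optional
`pathway, condition, replicate`); concentrations are molar, or
log₁₀-molar with `--log-conc`.  Configs are flat YAML.

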