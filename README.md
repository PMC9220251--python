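# proteokin

Kinetic analysis of porphyrinoid modulation of the human 20S proteasome.

Cationic porphyrins and corroles modulate the chymotrypsin-like activity
of the 20S proteasome core particle in strikingly different ways
depending on their charge distribution: some act as classical
competitive inhibitors at the substrate gate, others bind the α-ring
grooves cooperatively and *activate* the enzyme, and at least one
corrole does both — activating in the nanomolar range and inhibiting
competitively in the micromolar range. `proteokin` is a toolbox for
quantifying these phenotypes from fluorogenic initial-rate assays
(Suc-LLVY-AMC, AMC fluorescence read over 45 min):

- **Michaelis–Menten estimation** per modulator concentration
  (v = kcat·E0·S/(Km+S)), by direct nonlinear fit or Lineweaver–Burk
  double-reciprocal regression;
- **competitive KI estimation** from apparent-Km series
  (appKm = Km0·(1+I/KI)) or by a global fit of the competitive rate law
  to all wells;
- **a two-state concerted (MWC-type) allosteric model** in which the
  enzyme equilibrates between states A and B (allosteric constants L_U,
  L_L), a modulator binds n equivalent concerted sites (association
  constants K_AU, K_AL, K_BU, K_BL) and m competitive sites (K_AI,
  K_BI), giving closed forms for observed kcat, Km and efficiency
  versus modulator concentration;
- **fitting, minimal-model selection of (n, m), and mechanism
  classification** (NONE / COMPETITIVE / ALLOSTERIC_ACTIVATOR /
  ALLOSTERIC_INHIBITOR / BIPHASIC_ACTIVATOR_COMPETITIVE);
- **a synthetic plate-assay generator** with per-well seeded lognormal
  noise, so the whole pipeline is testable without laboratory data.

See `docs/methods.md` for the models, numerical choices, and the
identifiability limits of the two-state fit.

## Worked example

Evaluate the biphasic corrole archetype on the assay's modulator grid
and select the minimal site numbers:

```python
from proteokin import reference
from proteokin.inference import select_site_numbers
from proteokin.simulate import default_modulator_grid
from proteokin.twostate import dose_response

dr = dose_response(reference.TMPC_LIKE, default_modulator_grid())
sel = select_site_numbers(dr, n_candidates=(1, 2, 3, 4), m_candidates=(0, 1),
                          base=reference.TMPC_LIKE, seed=1)
print(sel.table.to_string(index=False))
print(f"selected n={sel.n_sites}, m={sel.m_sites}, label={sel.label}")
```

```
 n  m          rss        aicc  n_free
 1  0 1.883439e+00  -32.966942       4
 1  1 9.516768e-04 -175.727013       6
 2  0 1.244210e+00  -41.258916       4
 2  1 4.766709e-06 -281.658400       6
 3  0 5.957284e-01  -55.988341       4
 3  1 3.195503e-30 -713.493896       6
 4  0 2.994646e-01  -69.744112       4
 4  1 1.614324e-07 -349.364894       6
selected n=3, m=1, label=BIPHASIC_ACTIVATOR_COMPETITIVE
```

Three concerted allosteric sites plus one competitive site is the
smallest model whose corrected information criterion matches the best
candidate — the enzyme needs a cluster of three bound modulator
molecules to switch states, and an additional competitive site to
explain the Km increase at micromolar concentrations. The label records
the biphasic phenotype: catalytic efficiency rises above its
modulator-free value (activation, peaking below 0.5 µM) and then falls
below it (competitive inhibition above ~1 µM). On a single noisy plate
the competitive site (m = 1) remains decisive but the candidate values
of n tie within the selection margin — resolving the cooperativity
requires noiseless or replicate-averaged dose responses (see
`docs/methods.md`).

Estimating a competitive KI from a simulated plate (the tight
competitive archetype, true KI = 3.6e-7 M, 5% per-well noise):

```python
from proteokin.simulate import AssayDesign, CompetitiveMechanism, simulate_assay
from proteokin.inhibition import fit_competitive_global

df = simulate_assay(AssayDesign(seed=1), CompetitiveMechanism(ki=reference.KI_H2T4_M))
fit = fit_competitive_global(df["velocity_M_per_s"], df["substrate_M"],
                             df["modulator_M"], df["enzyme_M"])
print(f"KI = {fit.ki:.3e} M  (Km0 = {fit.km0:.3e} M)")
```

```
KI = 3.452e-07 M  (Km0 = 3.373e-05 M)
```

The same operations are available from the shell:

```bash
proteokin simulate --mechanism competitive --ki 3.6e-7 --seed 1 --out rates.csv
proteokin fit-competitive rates.csv
proteokin fold-ratio 1.4e-6 3.6e-7     # ratio=3.89 nearest-integer fold=4
```

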