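# gramscreen

Analytics for a gramicidin-channel-based screen of bilayer-modifying
potency and its relation to cytotoxicity.

Many bioactive small molecules are amphiphiles that partition into
lipid bilayers and change their mechanical properties, which perturbs
membrane proteins indiscriminately and can cause off-target effects and
cytotoxicity. The screen this package analyzes quantifies a drug's
bilayer-modifying potency through the gramicidin monomer↔dimer
equilibrium: ANTS-loaded large unilamellar vesicles doped with
gramicidin are stopped-flow mixed with the channel-permeant quencher
Tl⁺, and the initial fluorescence-quench rate reports the number of
conducting dimers. It is aimed at biophysicists and medicinal chemists
who run (or want to model) such screens.

## The model

The quench trace is a Stern–Volmer readout of a stretched-exponential
Tl⁺ filling process across a dispersed vesicle population:

    F(t) / F(0) = 1 / (1 + K_SV·[Tl⁺]_e·(1 − exp{1 − (1 + t/τ₀)^β}))

with K_SV = 60 M⁻¹, [Tl⁺]_e = 25 mM, time scale τ₀ > 0 and dispersity
exponent 0 < β ≤ 1. Fitting a trace over 2 ms–1 s yields the initial
quench rate

    Rate(0) = (1 + K_SV·[Tl⁺]_e)·β/τ₀ = 2.5·β/τ₀,

and a drug's potency is **NormRate** = Rate_drug(0)/Rate_cntrl(0),
mapped onto an equilibrium-shift energy ΔΔG ≈ −RT·ln NormRate and onto
categories low/moderate/high at NormRate 1.25 and 1.5. Cohort
statistics (2×2 odds ratios with Woolf intervals, probability-vs-bin
curves, Mann–Whitney comparisons, box summaries, silhouettes) link
potency to HepG2 CC20 cytotoxicity across a drug library. A synthetic
generator produces vesicle populations, stopped-flow sessions, and
drug-library tables with known planted structure so every stage is
testable end to end.

## Worked example

Simulate a vesicle population, measure a 5-trace control session and a
5-trace session of a potent bilayer modifier, and evaluate its potency:

```python
import numpy as np
from gramscreen import (simulate_luv_population, simulate_quench_trace,
                        fit_trace, norm_rate, delta_delta_g, categorize)

pop = simulate_luv_population(2000, seed=11)
control = np.mean([fit_trace(simulate_quench_trace(pop, seed=i)).rate0
                   for i in range(5)])
drug = np.mean([fit_trace(simulate_quench_trace(pop, drug_normrate=4.0,
                                                seed=50 + i)).rate0
                for i in range(5)])
nr = norm_rate(drug, control)
print(f"control rate: {control:.2f} 1/s")
print(f"drug rate:    {drug:.2f} 1/s")
print(f"NormRate:     {nr:.2f} ({categorize(nr)})")
print(f"ddG_bilayer:  {delta_delta_g(nr):+.2f} kcal/mol")
```

prints

```
control rate: 2.80 1/s
drug rate:    11.36 1/s
NormRate:     4.06 (high)
ddG_bilayer:  -0.83 kcal/mol
```

The control session recovers the assay's typical drug-free rate
(~2.9 s⁻¹); the simulated drug quadruples the conducting-dimer density,
and the fitted sessions recover a NormRate of 4.06 — a "high"-potency
bilayer modifier that lowers the dimerization free energy by
0.83 kcal/mol.

`QuenchTraceFitter` is a scikit-learn-style estimator
(`fit`/`predict`/`score`), so single traces can also be fitted with the
usual estimator idiom and composed with sklearn tooling.

A CLI mirrors the pipeline:

```sh
gramscreen simulate-traces --out session/ --seed 1
gramscreen fit session/ --out fits.csv
gramscreen simulate-library --out library.csv --seed 1
gramscreen potency --drugs library.csv --out potency.csv
gramscreen cohort --drugs library.csv --out-dir cohort/
gramscreen report --drugs library.csv
```

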