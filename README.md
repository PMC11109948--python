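# h4zip

Kinetic analysis of combinatorial histone H4 tail acetylation.

The N-terminal tail of histone H4 carries four acetylatable lysines (K5,
K8, K12, K16), giving 2⁴ = 16 combinatorial acetylation *motifs*.  The
MYST acetyltransferase MOF, working inside the MSL core complex, acetylates
nucleosomal H4 with striking K16 selectivity, yet on longer incubation the
tail becomes oligo-acetylated in a "zip"-like order (K16 → K12 → K8 → K5).
Targeted mass spectrometry can quantify every motif's relative abundance
over time; the mechanistic question is whether the enzyme is *distributive*
(one acetylation per binding event) or *processive* (it stays bound and
continues along the tail).

`h4zip` is a reusable, tested pipeline for answering that question from
motif time-course data:

- **State space** — the 16-motif acetylation lattice (8 motifs for a K16R
  mutant tail), with single-site acetylation edges only (no deacetylase in
  the assay).
- **Model families** — three ODE mechanisms over the lattice, all with
  substrate as a fraction of total H4 and time in minutes:
  - *mass action*: enzyme in excess, dS_m/dt = Σ k·S linear kinetics;
  - *Michaelis–Menten*: one shared enzyme pool with equilibrium complex,
    edge flux `kcat·E_tot·S_m/(Km + ΣS)`;
  - *processive*: explicit enzyme–substrate binding (kon, koff), on-complex
    catalysis per edge, and an optional within-array hand-off reaction
    (`k_transfer`) for the spatial variant.
- **Calibration** — multi-start maximum likelihood (bounded trust-region
  least squares on log₁₀ parameters), AIC ranking with the ΔAIC ≥ 10
  rejection rule.
- **Uncertainty** — posterior sampling under bounded uniform priors
  (affine-invariant ensemble sampler), 99% credibility intervals, ensemble
  prediction bands, per-motif site-preference profiles, and the K16R
  counterfactual ("disable every reaction involving K16").
- **MS quantification** — MS1 peak areas → relative motif abundances with
  light (enzymatic) vs heavy (D3-chemical) acetyl bookkeeping, theoretical
  m/z values, and 0.003% detection-limit masking.
- **Synthetic data** — scenario presets that emulate the statistical
  structure of the experiments (3 replicates, 0–60 min, measurement noise),
  so every stage is testable without downloads.

## Worked example

```python
from h4zip import *
from h4zip.synthetic import get_preset, generate_dataset

preset = get_preset("wildtype")     # processive, K16-selective
bundle = generate_dataset(preset, seed=1)      # 16 motifs x 5 times x 3 reps

agg = aggregate_motifs(bundle.dataset)
print(agg.pivot_table(index="category", columns="time_min",
                      values="mean", sort=False).round(3))

net = build_network(preset.sites)
fits = [fit(FamilySpec(family=f, network=net), bundle.dataset,
            LikelihoodSpec(), n_starts=4, seed=2)
        for f in ("mass_action", "michaelis_menten", "processive")]
print(compare(fits).table[["family", "aic", "delta_aic", "rejected"]].round(1))
```

prints

```
time_min        0.0    5.0    15.0   30.0   60.0
category
unmod          0.957  0.389  0.114  0.019  0.000
K16ac          0.001  0.522  0.754  0.743  0.596
other mono-ac  0.009  0.016  0.010  0.006  0.001
di-/tri-ac     0.031  0.072  0.120  0.229  0.399
tetra-ac       0.002  0.001  0.001  0.003  0.003

          family     aic  delta_aic  rejected
      processive -1533.3        0.0     False
     mass_action -1432.2      101.1      True
michaelis_menten -1430.2      103.1      True
```

Reading the output: K16 mono-acetylation dominates at 5 min (~52% here)
and then declines in favor of K16-anchored di-/tri-acetylation — the zip
signature — while motifs lacking K16ac stay near zero.  Fitting all three
mechanisms to the same data, the processive family wins decisively
(ΔAIC ≈ 100 over mass action; a ΔAIC of 10 already rejects), because the
enzyme-saturated kinetics cannot be mimicked by first-order models.  The
Michaelis–Menten family always trails mass action by exactly 2 AIC units
on this closed substrate pool — see `docs/methods.md` for why it is
observationally equivalent to mass action here.

The same pipeline runs from the shell:

```sh
h4zip simulate --preset wildtype --seed 1 --out dataset.csv
h4zip fit dataset.csv --seed 2 --out comparison.csv
h4zip all --seed 17 --outdir run/      # simulate→fit→compare→sample→predict
```

## Layout

- `src/h4zip/motifs.py` — motif state space and acetylation lattice
- `src/h4zip/kinetics.py` — the three ODE model families and simulation
- `src/h4zip/msquant.py` — targeted-MS quantification and acetyl bookkeeping
- `src/h4zip/estimation.py` — MLE calibration, AIC comparison
- `src/h4zip/uncertainty.py` — posterior sampling, bands, counterfactuals
- `src/h4zip/synthetic.py` — scenario presets and dataset/peak-table generators
- `src/h4zip/report.py`, `pipeline.py`, `cli.py` — tables, orchestration, CLI
- `docs/methods.md` — model equations, assumptions, numerical choices
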