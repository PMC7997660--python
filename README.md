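# procswitch

Analysis of single-molecule optical-trap hairpin-unwinding experiments in
which a helicase switches between low- and high-processivity states, and an
ssDNA-binding protein tips the switch.

A DNA hairpin (89 bp stem, dT4 loop, long dsDNA handles) is held at constant
force between two trapped beads while a single helicase unwinds it.  Each
broken base pair releases two nucleotides of ssDNA, so the tether extension
reports base pairs unwound in real time.  The enzyme works in repeated
*bursts* — forward unwinding followed by rezipping to the hairpin base — and
each burst's *processivity* (maximum base pairs opened) falls into one of
two populations separated at ~25 bp.  The fraction of high-processivity
bursts grows with the concentration of the single-stranded DNA binding
protein RPA2, which also transiently melts ~5 bp of the duplex on its own.
`procswitch` provides the full analysis chain for such data, plus a
synthetic-trace generator with ground-truth injection logs so every stage
can be validated without instrument data.

## What is in the box

| module | contents |
| --- | --- |
| `procswitch.wlc` | extensible worm-like chain (Marko–Siggia + stretch) conversions between force, extension and bp unwound |
| `procswitch.simulate` | Gillespie simulation of the four-state switch scheme, first-passage datasets, full constant-force trace synthesis with injection logs |
| `procswitch.steps` | Kerssemakers-style iterative chi-square step fitting, melting-event detection (paired steps during unwinding; threshold excursions on bare hairpins), on-rate estimation, step classification, event alignment, 2D KDE |
| `procswitch.bursts` | robust local-quadratic (rloess) smoothing, burst segmentation and classification against the 25 bp threshold, unwinding-portion selection, velocity profiles, summary tables |
| `procswitch.kinetics` | the four-state kinetic model: closed-form first-passage probability, `FirstPassageModel`/`FirstPassageResults` global fit across concentrations with bootstrap CIs, k1-vs-concentration rate law, burst-fraction and burst-duration models |
| `procswitch.io` / `procswitch.cli` | TSV trace/table formats, validated YAML configuration, `procswitch` command-line pipeline |

## The kinetic model

The enzyme starts bound in the low-processivity state.  With

* k1 — low → high switching rate (depends on [RPA2]),
* k−1 — high → low,
* k2 — threshold-crossing (scored >25 bp) from the high state,
* k_off — dissociation from the low state (k′off from the high state is 0),

the master equations for the state probabilities P_low, P_high, P_off,
P_>25 give a closed-form probability that a molecule has crossed the
threshold by time t:

    P_>25(t) = k D / (λ− − λ+) · [ (1 − e^{−λ+ t})/λ+ − (1 − e^{−λ− t})/λ− ]

    λ± = (k + B + C)/2 ± sqrt( ((k + B + C)/2)² − (A·k + B·C) )

with the grouped parameters A = k2 + k′off, B = k_off, C = k−1 + k2 + k′off,
D = k2 and k = k1([RPA2]).  The model is fitted globally: A, B, C, D are
shared across concentrations, one k per concentration, with k′off = 0
(A = D) by default.  The fitted k1 values follow a straight line in
concentration whose slope is an effective second-order rate constant for
the protein activating the switch and whose intercept is the basal
interconversion rate.

## Worked example

Simulate first-passage data at the published best-fit rates
(k−1 = 0.18 s⁻¹, k2 = 0.17 s⁻¹, k_off = 0.037 s⁻¹, k1 from 0.02 to
1.15 s⁻¹ across 0–50 nM) and refit them globally:

```python
import procswitch as ps
from procswitch.kinetics import FirstPassageModel

k1 = {0.0: 0.02, 2.0: 0.059, 5.0: 0.065, 10.0: 0.200, 50.0: 1.15}
rates = {c: ps.KineticRates(k1=v, k_minus1=0.18, k2=0.17, k_off=0.037)
         for c, v in k1.items()}
data = ps.simulate_first_passage(rates, n_molecules=100, t_max=60.0, seed=1)
res = FirstPassageModel(data).fit(n_boot=100, seed=1)
print(res.summary())
```

prints

```
Processivity-switch first-passage fit
=============================================
concentrations (nM): 0, 2, 5, 10, 50
molecules per concentration: 100, 100, 100, 100, 100
k'_off constraint: fixed to 0 (A = D)
loss (neg. log-likelihood): 1224

rate constants (s^-1)   [95% bootstrap CI]
  k_minus1       0.3129   [-0.1183, 0.7441]
  k2             0.1816   [0.0977, 0.2654]
  k_off          0.0305   [0.0201, 0.0409]
  k_off_prime    0.0000   [0.0000, 0.0000]
  k1_0nM         0.0211   [-0.0046, 0.0467]
  k1_2nM         0.0912   [0.0006, 0.1818]
  k1_5nM         0.0709   [-0.0053, 0.1471]
  k1_10nM        0.2598   [-0.0033, 0.5230]
  k1_50nM        1.5811   [-0.5967, 3.7590]

k1 rate law: slope 1.64e+07 M^-1 s^-1 (se 6.6e+06), intercept 0.0212 s^-1 (se 0.013)
mean bound lifetime 1/k_off: 32.8 s
```

The generating k2 = 0.17 s⁻¹, k_off = 0.037 s⁻¹ and the k1 ladder are
recovered within their confidence intervals; the rate-law slope
(~1.6×10⁷ M⁻¹ s⁻¹) and intercept (~0.02 s⁻¹) are the second-order
activation constant and basal switching rate; 1/k_off is the mean time the
enzyme stays bound (tens of seconds).

## Command-line pipeline

```sh
procswitch simulate --out-dir run/traces --n-molecules 10 --conc 0 --conc 10 --seed 7
procswitch detect  run/traces/trace_*.tsv --out-dir run/events
procswitch bursts  run/traces/trace_*.tsv --out-dir run/bursts
procswitch fpt     run/traces/trace_*.tsv --out run/fpt.tsv
procswitch fit     run/fpt.tsv --out-dir run/fit
procswitch report  --run-dir run/bursts
```

All stages read/write plain TSV with `# key=value` headers; identical
configuration and seed reproduce byte-identical outputs, and every output
table carries the configuration hash.

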