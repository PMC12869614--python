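# liverdce

Pharmacokinetic analysis of liver DCE-MRI with hepatospecific gadolinium
contrast agents, for imaging scientists studying hepatocyte transporter
function in large-animal (dog, pig) models.

Hepatospecific agents such as Gd-EOB-DTPA and Gd-BOPTA are taken up by
hepatocytes through OATP transporters and effluxed into bile through MRPs,
so the rates at which they enter and leave the liver are direct probes of
hepatic function. `liverdce` implements the full quantitative chain from
ROI-mean scanner signal to fitted rate constants:

1. **SPGR conversion** — the spoiled-gradient-echo steady-state equation is
   inverted with fixed pre-contrast T1 values (581/1172/1480 ms for
   liver/spleen/blood) to get R1(t), then concentration
   `C(t) = (R1(t) − R1(0)) / r1` with agent- and tissue-specific in-situ
   relaxivities. The spleen acts as a surrogate for the liver's
   extravascular extracellular space (EES):
   `Ce = ΔR1_spleen / (r1_spleen · ve_spleen)`, and the hepatocyte
   concentration follows from the partition
   `Ci = (Ct − ve·Ce) / (1 − ve)` with `ve = 0.23`, `vh = 1 − ve = 0.77`.
2. **Noise filtering** — a blended moving-median filter: 3-sample median up
   to 5 min post-bolus, 7-sample median beyond 30 min, linear cross-fade in
   between.
3. **Kinetic models** — on a uniform grid with spacing Δt, as discrete
   causal convolutions:
   - single-input reference-region (TRISTAN) model:
     `Ci[n] = Δt · Σₘ exp(−k2·(tₙ−tₘ)/vh) · (k1/vh) · Ce[m]`,
     the closed-form solution of `vh·dCi/dt = k1·Ce − k2·Ci`;
   - dual-input biexponential (Berks) model:
     `Ct[n] = Δt · (α⁺e^{−β⁺t} + α⁻e^{−β⁻t}) * Cp[n]` with plasma input
     `Cp = (fa·Ca + (1−fa)·Cv) / (1 − Hct)` from the abdominal aorta and
     portal vein.
4. **Multistart fitting** — seeded narrow/wide random starting estimates
   (TRISTAN: 20 + 80; Berks: 500 + 500), a bounded local minimizer from
   every start with all parameters constrained to `[2⁻⁵², 1.0]`, under both
   least-squares (LSQ) and least-absolute-residual (LAR) criteria, with and
   without filtering. Rates are fitted in s⁻¹ and reported in min⁻¹.

Because suitable raw animal studies are rarely at hand, the package ships a
first-class synthetic-study generator (`liverdce.synthetic`): gamma-variate
arterial bolus with biexponential washout, dispersed portal curve, spleen
EES surrogate, and a liver curve produced by either forward model, all
rendered to noisy SPGR signals at the dog (7.65 s) or pig (13.4 s) frame
interval — with the generating parameters retained so every pipeline stage
can be validated by parameter recovery.

## Worked example

`examples/04_rate_recovery.py` simulates the built-in dog Gd-EOB-DTPA
scenario (60 min, 0.5 % signal noise), converts the rendered signals, and
fits the reference-region model by LAR multistart on unfiltered data:

```
k1: recovered 0.9841 min^-1, truth 1.000 min^-1 (1.6% error)
k2: recovered 0.0267 min^-1, truth 0.027 min^-1 (1.2% error)
objective (LAR): 3.15e-02, 68/100 starts converged
```

The uptake rate k1 (hepatocyte influx) and efflux rate k2 both come back
within a few percent of the generating values after passing through the
complete signal → concentration → fit chain. The other examples cover
conversion round trips, the median filter, forward-model evaluation, the
CSV/report pipeline, and 4D-phantom preprocessing; each prints a short
interpretation of its numbers.

A thin CLI wraps the same library calls:

```sh
liverdce simulate --scenario dog_eob --out curves.csv
liverdce analyze --curves curves.csv --species dog --agent Gd-EOB-DTPA \
    --tr 0.005 --flip-angle 15 --frame-interval 7.65 --out report
liverdce recover --scenario pig_eob
```

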