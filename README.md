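# methanokinetics

Analysis toolkit for **closed-batch gas-conversion kinetics of
hydrogenotrophic methanogens** — the workflow behind CO₂-based biological
methane production (CO₂-BMP) screening, where archaea convert a pressurized
H₂/CO₂ headspace to CH₄ in sealed serum bottles or high-pressure bioreactors
and the falling headspace pressure is the primary online measurement.

It is written for bioprocess scientists who log pressure traces from sealed
cultivations and want reproducible rate statistics instead of spreadsheet
arithmetic: methane evolution rates, conversion turnover, cycle-resolved
repetitive-batch results, nutrient-demand clustering and a small
sequence-analysis helper for the methyl-coenzyme M reductase motif that
marks high-performance strains.

## The model

The reaction is

    4 H₂ + CO₂ → CH₄ + 2 H₂O

Product water condenses at cultivation temperature, so each mole of CH₄
removes a net 4 mol of gas from a fixed headspace: for the standard 4:1
H₂:CO₂ mixture, complete conversion leaves exactly **p₀/5** of the initial
pressure (2 bar from 10 bar, 10 bar from 50 bar). Pressure is therefore an
online readout of the reaction extent ξ = (n(p₀) − n(p))/4 with
n = PV/RT, and the volumetric **methane evolution rate** is

    MER(t) = −(dp/dt) · V_gas / (4 R T V_liquid)    [mmol L⁻¹ h⁻¹]

with CUR = MER and HUR = 4·MER by stoichiometry. From the resampled,
smoothed MER curve the pipeline derives MER_max (peak), MER_global
(active-window average over [x_start, x_end], the threshold crossings at
0.1 mmol L⁻¹ h⁻¹), MER_total (whole-run average), k_min (most negative
pressure slope, bar h⁻¹, marking the MER peak), turnover_max
(= 100·(p₀ − p_min)/(0.8 p₀) for the 4:1 mixture) and the time to full
conversion. Growth statistics from OD₅₇₈ series include per-interval
specific growth rates μᵢ = ln(ODᵢ₊₁/ODᵢ)/Δtᵢ and the biomass increase
rate, mean over intervals of OD_max·μᵢ/(ODᵢ·μ_average).

Repetitive closed batch (RCB) traces — repressurized after each complete
conversion — are segmented at pressure jumps and every cycle (RCB1…RCBn)
is evaluated separately. A screening stage correlates responses with
medium composition: regularized iterative-PCA imputation of missing
entries, column standardization, PCA, and k-means on the first two
components with between-SS/total-SS quality reporting. The motif module
maps residue numbers through a gapped alignment of MCR subunit alpha and
classifies the Tyr⁴⁴⁴-Gly⁴⁴⁵-Tyr⁴⁴⁶ motif (Y/F substitution classes).

A seeded simulator (`methanokinetics.synthetic`) generates realistic
pressure/OD traces (Monod-on-p_H₂ gas-limited growth, RK4, sensor noise),
cluster-structured screening matrices and gapped alignments with ground
truth attached, so every stage is testable without lab data.

## Worked example

```
$ python examples/closed_batch_kinetics.py
recorded samples        : 601 (5-min grid)
MER_max                 :  11.28 mmol L-1 h-1 (truth 11.76) at t = 23.5 h
MER_global              :   2.56 mmol L-1 h-1 (active-window average)
MER_total               :   2.48 mmol L-1 h-1 (whole-run average)
k_min                   :  -0.78 bar h-1 at t = 23.5 h
turnover_max            :  100.0 %
time to full conversion :   27.0 h (truth 26.6)
active window           : [0.0, 46.5] h
```

A simulated 10-bar closed batch converts fully in ~27 h; the pipeline
recovers the true peak rate within 5% from the noisy trace, and k_min's
timestamp coincides with the MER peak. `examples/rcb_cycles.py`,
`examples/nutrient_screening.py` and `examples/motif_scan.py` walk the
other stages the same way; the `methanokinetics` console script exposes
them as `simulate`, `kinetics`, `rcb`, `screen` and `motif` subcommands,
e.g.

```
methanokinetics kinetics --pressure p.csv --headspace-ml 100 \
    --liquid-ml 60 --temp-c 65 --out kinetics.tsv
```

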