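"""Segment a repetitive-closed-batch trace and evaluate every cycle.

The same culture converts four successive headspace fills; biomass carried
across cycles makes each conversion faster than the last.  The segmenter
finds the repressurization jumps, and each cycle gets the full kinetics
treatment plus a full-conversion verdict.
"""

from methanokinetics import evaluate_cycles, segment_cycles
from methanokinetics.synthetic import SimParams, simulate_rcb

params = SimParams(seed=1)
series, truths = simulate_rcb(params, n_cycles=4)
segments = segment_cycles(series)
evaluations = evaluate_cycles(segments, params.vessel)

print(f"{'cycle':<6}{'MER_max':>9}{'truth':>8}{'k_min':>8}{'turnover':>10}{'full?':>7}")
for ev, truth in zip(evaluations, truths):
    r = ev.result
    print(f"{ev.label:<6}{r.mer_max:9.2f}{truth.mer_max:8.2f}{r.k_min:8.2f}"
          f"{r.turnover_max:9.1f}%{'yes' if ev.full_conversion else 'no':>7}")

# MER_max rises cycle over cycle (mmol L-1 h-1): the culture accumulates
# catalytically active biomass.  Every cycle ends at the one-fifth residual,
# so full conversion is declared for all four.
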