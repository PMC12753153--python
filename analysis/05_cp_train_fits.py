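#!/usr/bin/env python
"""Full Carr-Purcell train analysis: one or two spin populations?

Generates a full-train echo decay (tau = 290 ns, 140 echoes) from the
two-component reference parameters with 1 % noise, fits both the single
stretched exponential and the sum of two stretched exponentials, and lets
the corrected-AIC criterion decide.  A single-population (nitroxide-like)
train is analyzed the same way as a control.
Writes results/cp_train.json.
"""

import json
from pathlib import Path

import numpy as np

from gdrelax.decay_fit import select_model
from gdrelax.synth import GeneratorSpec, PYMTA, gen_decay

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

t = np.arange(1, 141) * 0.58
fast, slow = PYMTA.train_fast, PYMTA.train_slow

two_pop = gen_decay(GeneratorSpec(
    kind="sse",
    params=dict(A=fast["fraction"], Tm_f=fast["Tm"], beta_f=fast["beta"],
                Tm_s=slow["Tm"], beta_s=slow["beta"]),
    time_us=t, noise=0.01, seed=1,
))
one_pop = gen_decay(GeneratorSpec(
    kind="se", params=dict(A=1.0, Tm=7.0, beta=1.1),
    time_us=t, noise=0.01, seed=1,
))

report = {}
for name, trace in (("gd_complex_train", two_pop), ("nitroxide_like_train", one_pop)):
    sel = select_model(trace)
    entry = {"selected": sel.chosen, "delta_aicc": sel.delta_aicc,
             "se": {"Tm_us": sel.se.Tm, "beta": sel.se.beta}}
    if sel.chosen == "SSE":
        entry["sse"] = {"A_fast": sel.sse.A, "Tm_f_us": sel.sse.Tm_f,
                        "beta_f": sel.sse.beta_f, "Tm_s_us": sel.sse.Tm_s,
                        "beta_s": sel.sse.beta_s}
        print(f"{name}: two populations resolved "
              f"(Tm_f = {sel.sse.Tm_f:.2f} µs, Tm_s = {sel.sse.Tm_s:.2f} µs, "
              f"fast fraction {sel.sse.A:.2f}; dAICc = {sel.delta_aicc:.0f})")
    else:
        print(f"{name}: single stretched exponential is sufficient "
              f"(Tm = {sel.se.Tm:.2f} µs, beta = {sel.se.beta:.2f}; "
              f"dAICc = {sel.delta_aicc:.1f})")
    report[name] = entry

# slow-component Tm exceeds the Hahn-echo Tm by about a factor of two
report["slow_over_hahn"] = PYMTA.train_slow["Tm"] / PYMTA.hahn_tm_us
print(f"slow-component Tm / Hahn Tm = {report['slow_over_hahn']:.2f}")

with open(OUT / "cp_train.json", "w") as f:
    json.dump(report, f, indent=1)
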