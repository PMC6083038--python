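"""Whole-cell passive properties and the series-resistance exclusion rule.

Computes membrane capacitance, conductance and series resistance from a
hyperpolarising test pulse, and applies the quality-control rule that
discards recordings whose series resistance rose by more than 30%.
"""

from axotrace import passive_membrane, rs_exclusion

# a -10 mV test step: 0.4 pC capacitive charge, 100 pA steady state,
# 2000 pA capacitive transient peak
pm = passive_membrane(Q=0.4, dV=10.0, Iss=100.0, Ip=2000.0)
print(f"Cm = {pm.Cm:.1f} pF   (Q / dV)")
print(f"Gm = {pm.Gm:.1f} nS   (Iss / dV)")
print(f"Rs = {pm.Rs:.1f} MOhm (dV / Ip)")

for series in ([10.0, 11.5, 12.0], [10.0, 12.9, 13.5]):
    verdict = "exclude" if rs_exclusion(series) else "keep"
    rise = 100.0 * (max(series) / series[0] - 1.0)
    print(f"Rs series {series} MOhm: {rise:.0f} % rise -> {verdict}")
# Recordings are excluded when Rs rises more than 30% over its initial value,
# since a drifting access resistance distorts event amplitudes and kinetics.
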