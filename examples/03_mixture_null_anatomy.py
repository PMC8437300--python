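"""Anatomy of the mixture-null calibration.

Constructs two stage p-value series with known composition (60% double
nulls, 25% beta-only alternatives, 10% alpha-only alternatives, 5% true
mediators), then shows the estimated component proportions, the
Grenander-deconvolved power curves, and how the mixture CDF maps a raw
Pmax into an adjusted significance value.
"""

import numpy as np

from iusmmt import (estimate_null_proportions, grenander_alt_cdf,
                    iusmmt_pvalues, pmax_null_cdf)

rng = np.random.default_rng(3)
S = 10_000
comp = rng.choice(4, size=S, p=[0.60, 0.25, 0.10, 0.05])
alpha_alt = np.isin(comp, (2, 3))
beta_alt = np.isin(comp, (1, 3))
pa = np.where(alpha_alt, rng.beta(0.15, 1.0, S), rng.uniform(size=S))
pb = np.where(beta_alt, rng.beta(0.25, 1.0, S), rng.uniform(size=S))

props = estimate_null_proportions(pa, pb)
print(f"estimated proportions  k00={props.k00:.3f} k01={props.k01:.3f} "
      f"k10={props.k10:.3f} k11={props.k11:.3f}")
print("truth                  k00=0.600 k01=0.250 k10=0.100 k11=0.050")

p10 = grenander_alt_cdf(pa, props.k00 + props.k01)
p01 = grenander_alt_cdf(pb, props.k00 + props.k10)
for u in (0.01, 0.05):
    print(f"power curves at u={u}: p10(u)={p10(u):.3f} "
          f"p01(u)={p01(u):.3f}  mixture-null CDF="
          f"{pmax_null_cdf(u, props, p10, p01):.4f}")

calib = iusmmt_pvalues(pa, pb)
med = calib.table.sort_values("p_max").iloc[len(calib.table) // 2]
print(f"a mid-rank gene: Pmax={med['p_max']:.3f} -> adjusted "
      f"{med['p_iusmmt']:.3f}")
print("The adjusted value is the probability, under the estimated "
      "composite null, that Pmax falls below the observed value; it is "
      "always <= Pmax, which is where the power gain over the naive "
      "intersection-union test comes from.")
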