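"""Genome-wide mediation scan on a simulated study.

Simulates a sparse-alternative study (10% of genes are true mediators),
runs both stage tests for every gene, calibrates the three-component
mixture null from the two p-value series, and compares the discoveries
of the mixture-adjusted test (IUSMMT) with the naive max-P
intersection-union test (IUT) at FDR 0.05.
"""

import numpy as np

from iusmmt import ScanConfig, run_mediation_scan
from iusmmt.simulator import scenario_config, simulate_study

study = simulate_study(scenario_config(
    "sparse_alternative", n=250, S=500, seed=1, tau2=0.02, beta=0.2))

table, calib = run_mediation_scan(
    study.genes, ScanConfig(tau3_grid="fast", run_reverse=True))

k = calib.proportions
print(f"estimated null proportions: k00={k.k00:.3f} k01={k.k01:.3f} "
      f"k10={k.k10:.3f} k11={k.k11:.3f}   (truth: 0.90/0/0/0.10)")

labels = np.array(study.truth_labels)
is_alt = labels == "11"
print(f"true mediators: {is_alt.sum()} of {len(labels)} genes")
print(f"IUSMMT discoveries (FDR 0.05): {table['sig_iusmmt'].sum()} "
      f"({(table['sig_iusmmt'] & is_alt).sum()} true)")
print(f"IUT discoveries    (FDR 0.05): {table['sig_iut'].sum()} "
      f"({(table['sig_iut'] & is_alt).sum()} true)")
print(f"passenger flags among discoveries: "
      f"{int(table['passenger_flag'].sum())}")
print("The mixture calibration converts each gene's Pmax into an "
      "adjusted significance value; because the adjusted value never "
      "exceeds Pmax, every IUT discovery is also an IUSMMT discovery.")
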