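"""Parameter recovery: how reliable are the fitted parameters?

Simulates a cohort from known parameters, refits every subject (MAP here
for speed; pass fit="hierarchical" for the full procedure), and reports
the true-vs-estimated Pearson correlation per parameter.
"""

import numpy as np

from twostep import CohortSpec, TaskConfig, run_recovery

spec = CohortSpec(n_per_group={"HC": 24, "ED": 0})
report = run_recovery(spec, TaskConfig(), fit="map", rng=np.random.default_rng(4))

print(f"fit method: {report.fit_method}; {report.n_subjects} subjects, "
      f"{report.n_trials} trials per condition")
print(report.to_frame().to_string(index=False))
print(f"\naverage PCC across parameters and cells: {report.average_pcc:.3f}")
print("Above 0.5 counts as fair reliability; the hierarchical fit at full")
print("study scale pushes the average into the 0.8s.")
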