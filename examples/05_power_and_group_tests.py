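"""Power analysis and group comparisons from summary statistics.

Reproduces the design-stage sample sizes and the post-hoc powers of a
two-group (healthy control vs eating disorder) study, and the two-sample
t tests comparing questionnaire totals from printed means and SDs.
"""

from twostep import (
    GroupSummary,
    achieved_power_t,
    required_n_t_independent,
    required_n_t_paired,
    two_sample_t_from_summary,
)

print("a-priori sample sizes (alpha 0.05, two-tailed, power 0.80):")
print(f"  between groups, d = 0.75  -> n = {required_n_t_independent(0.75, 0.8)} per group")
print(f"  within group,  dz = 0.75  -> n = {required_n_t_paired(0.75, 0.8)} pairs")

print("\npost-hoc power at the realised sample sizes (35 ED / 32 HC):")
print(f"  between groups, d = 0.88 -> {achieved_power_t(0.88, n1=35, n2=32):.2f}")
print(f"  within group,  dz = 1.04 -> {achieved_power_t(1.04, n=35, design='paired'):.2f}")

print("\ntwo-sample t tests from group summaries (pooled variance):")
rows = [
    ("EAT-26", GroupSummary(2.94, 2.72, 32), GroupSummary(25.83, 10.67, 35)),
    ("AAI", GroupSummary(4.59, 2.87, 32), GroupSummary(23.94, 7.26, 35)),
    ("OCI-R", GroupSummary(5.5, 3.59, 32), GroupSummary(22.83, 11.09, 35)),
    ("Age", GroupSummary(26.38, 4.61, 32), GroupSummary(30.57, 4.45, 35)),
]
for name, hc, ed in rows:
    t, df, p = two_sample_t_from_summary(hc, ed)
    print(f"  {name:7s} t({df}) = {t:6.2f}, p = {p:.2e}")
print("\nLarge negative t values: the eating-disorder group scores far higher")
print("on every questionnaire and is older on average.")
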