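"""Generate a synthetic cohort and run the group statistics battery.

The cohort has three groups (controls, first-degree relatives, people
with psychotic psychopathology) whose log10 bi-stable switch rates are
shifted by a medium effect (Cohen's d = 0.58, relatives halfway), with
two sessions per subject at test-retest ICC(3,k) = 0.88 and clinical
covariates rank-coupled to switch rate.
"""

from cylsfm import CohortSpec, cohort_metrics, generate_cohort, run_battery
from cylsfm.scoring import pooled_durations_by_group

spec = CohortSpec(seed=8, n_per_group={"control": 25, "relative": 25, "pwpp": 35})
cohort = generate_cohort(spec)
metrics = cohort_metrics(cohort)
durations = pooled_durations_by_group(cohort, metrics)
report = run_battery(metrics, durations, cohort.sessions_frame())

for name in (
    "bistable_rate_kw",
    "bistable_rate_control_vs_pwpp",
    "cohens_d_pwpp_vs_control",
    "retest_icc_rate",
    "exclusion_contingency",
    "durations_ks_control_vs_pwpp",
    "clinical_BPRS_D",
    "GABA_pooled",
):
    r = report[name]
    parts = [f"{name:32s} stat={r.statistic:7.3f}"]
    if r.df is not None:
        parts.append(f"df={r.df:g}")
    if r.p == r.p:  # not NaN
        parts.append(f"p={r.p:.4f}")
    if r.p_bonferroni is not None:
        parts.append(f"p_bonf={r.p_bonferroni:.4f}")
    print("  ".join(parts))
# Omnibus Kruskal-Wallis and the control-vs-PwPP post-hoc pick up the
# group shift; ICC shows stable rates across sessions; the KS test shows
# shorter percept durations in the psychosis group; the disorganization
# scale correlates positively with switch rate.
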