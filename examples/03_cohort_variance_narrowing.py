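"""Cohort synthesis and the variance-narrowing analysis.

Generates the default 525 + 126 two-age-group cohort (elderly copy numbers
drawn as survivors of the non-elderly distribution), summarises both
groups, tests location and dispersion differences, and fits the
survivor-truncation model back from the data.
"""

from rdnacn import (
    CohortConfig,
    describe,
    dispersion_permutation_test,
    fit_survivor_model,
    generate_cohort,
    ks_test,
    mann_whitney,
)

cohort = generate_cohort(CohortConfig(seed=11))
ne = cohort[cohort.cohort == "NE"].cn_true.to_numpy()
e = cohort[cohort.cohort == "E"].cn_true.to_numpy()

for label, vals in (("NE (17-71 y)", ne), ("E  (72-91 y)", e)):
    s = describe(vals)
    print(f"{label}: n={s.n}  range {s.min:.0f}-{s.max:.0f}  "
          f"mean {s.mean:.0f} +- {s.sd:.0f}  median {s.median:.0f}  CV {s.cv:.2f}")

mw = mann_whitney(ne, e)
ks = ks_test(ne, e)
print(f"\nlocation:   Mann-Whitney p = {mw.p_value:.3g}, KS p = {ks.p_value:.3g}")
for stat in ("cv_diff", "range_diff"):
    t = dispersion_permutation_test(ne, e, stat, n_perm=9999, seed=0)
    print(f"dispersion: {stat} = {t.observed:.3g}, permutation p = {t.p_value:.2g}")

fit = fit_survivor_model(ne, e, mode="hard")
print(f"\nsurvivor-truncation fit: bounds [{fit.lower:.0f}, {fit.upper:.0f}], "
      f"predicted E mean {fit.predicted_mean:.0f} +- {fit.predicted_sd:.0f} "
      f"(CV {fit.predicted_cv:.2f}), KS goodness-of-fit p = {fit.ks_p:.2f}")
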