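"""Matched case-control analysis of glycan traits and an outcome.

Within the HIV-positive group, matches each case 1:1 to a control on age
and BMI (exact on ethnicity), checks covariate balance, and fits
adjusted logistic models for each glycan group with BH FDR across the
panel.  The generator links case status to the agalactosylated and
bisected groups *through their age-driven variation*, so the unmatched
odds ratios sit above 1 while age-matching plus age adjustment absorbs
most of that signal — a worked illustration of what matching does.
"""

import glycoage as ga

bundle = ga.generate_cohort(ga.GeneratorConfig(seed=2025))
traits = ga.derive_traits_frame(bundle.profiles).join(bundle.cohort)

pos_all = traits[traits.hiv == "positive"]
print("unmatched, unadjusted odds ratios (planted link visible):")
for t in ("agalactosylated", "bisected"):
    r = ga.adjusted_logistic(pos_all, "outcome", t)
    print(f"  {t:24s} OR {r.odds_ratio:5.2f} [{r.ci_low:.2f}, {r.ci_high:.2f}]"
          f"  p {r.p:.2g}")

pos = traits[traits.hiv == "positive"]
cases, pool = pos[pos.outcome == 1], pos[pos.outcome == 0]
print(f"cases {len(cases)}, available controls {len(pool)}")

spec = ga.MatchSpec(numeric=("age", "bmi"), exact_on=("ethnicity",))
match = ga.nearest_neighbor_match(cases, pool, spec, seed=3)
print(f"matched pairs: {len(match.pairs)}, unmatched: {len(match.unmatched_cases)}")
print("covariate balance (standardized mean difference):")
for _, row in match.balance.iterrows():
    print(f"  {row.covariate:5s} before {row.smd_before:+.3f} -> "
          f"after {row.smd_after:+.3f}")

matched_ids = list(match.pairs.case_id) + list(match.pairs.control_id)
matched = traits.loc[matched_ids]

panel = ["agalactosylated", "terminal_galactosylated", "sialylated",
         "fucosylated", "bisected"]
ors = ga.odds_ratio_panel(matched, "outcome", panel, covariates=("age",))
print("\nmatched, age-adjusted odds ratios per 1 percent of trait:")
for _, r in ors.iterrows():
    print(f"  {r.variable:24s} OR {r.odds_ratio:5.2f} "
          f"[{r.ci_low:.2f}, {r.ci_high:.2f}]  q {r.fdr_q:.3f}")
print("(after matching on age the age-mediated part of the planted link is "
      "gone, so these ORs shrink toward 1 — the design isolates "
      "age-independent effects, of which the generator plants none)")
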