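"""Mixed-design ANOVA and t-tests on scalar traits.

Builds a stomatal-conductance table with a treatment effect (excision
closes stomata) and a time-of-day effect, runs the repeated-measures
two-way ANOVA, then compares end-of-day leaf water potential between
treatments with a Welch t-test, and checks for a sampling-date effect.
"""

import pandas as pd

import leafphys as lp

design = lp.ExperimentDesign(
    "maize", n_reps_per_treatment=12, seed=2,
    effects={"gs": lp.EffectSpec(baseline=0.20, treatment_delta=-0.05,
                                 time_delta=-0.02, noise_sd=0.025),
             "water_potential": lp.EffectSpec(baseline=-0.237,
                                              treatment_delta=0.044,
                                              noise_sd=0.02)})

gs = lp.generate_trait_table(design, "gs")
anova = lp.two_way_rm_anova(gs)
print("stomatal conductance, mixed-design two-way ANOVA:")
for effect in ("treatment", "time", "interaction"):
    r = getattr(anova, effect)
    print(f"  {effect:11s} F({r.df_num},{r.df_den}) = {r.F:7.2f}   p = {r.p:.4g}")
# treatment is tested against plant-to-plant variation, time and the
# interaction against the within-plant AM-PM differences.

wp = lp.generate_trait_table(design, "water_potential", repeated=False)
t = lp.compare_treatments_t(wp.loc[wp.treatment == "excised", "value"],
                            wp.loc[wp.treatment == "attached", "value"])
print(f"\nwater potential: t = {t.t:.2f} (df {t.df:.1f}), p = {t.p:.4g}, "
      f"excised - attached = {t.mean_difference:+.3f} MPa")

dates = pd.DataFrame({"date": ["d1"] * 6 + ["d2"] * 6,
                      "gs": list(gs["value"][:12])})
check = lp.sampling_date_check(dates)
print("\nsampling-date check (combine batches when p >= 0.05):")
print(check.round(4).to_string(index=False))
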