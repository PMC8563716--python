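"""Synthetic behavioral data through the preprocessing and GLME stages.

Generates 40 participants per condition with a known logit structure,
plants three reaction-time violators, applies the exclusion rules, and
fits the binomial mixed model (participant random intercept) with and
without the repetition term.  With the generator's ground truth in hand
you can see the fitter recover the role and condition effects and the
BIC prefer the repetition model.
"""

import hipporpe as hp

cfg = hp.BehavioralGenConfig(n_participants=40, seed=2024)
data = hp.generate_participants(cfg)
ids = sorted(set(data.table["participant_id"]))
data = hp.inject_exclusion_cases(data, rt_violators=ids[:3])

kept, report = hp.preprocess_behavior(data.table)
print("Exclusion report:")
print(report)

print("\nBase GLME (logit scale, exception/early reference):")
fit = hp.fit_behavioral_glme(kept[kept["phase"] == "learning"], "base")
print(fit.summary().round(3).to_string(index=False))
print(f"random-intercept SD: {fit.random_effect_sd:.3f} "
      f"(generator used {cfg.participant_sd}); BIC {fit.bic:.1f}")

fit_rep = hp.fit_behavioral_glme(kept[kept["phase"] == "learning"], "with_repetition")
print(f"\nrepetition-model BIC {fit_rep.bic:.1f} "
      f"({'lower — preferred' if fit_rep.bic < fit.bic else 'higher'})")
print("\nThe generator gave exceptions a delayed-condition advantage in both")
print(f"the intercept ({cfg.intercepts[('exception', 'early')]} -> "
      f"{cfg.intercepts[('exception', 'delayed')]}) and the per-repetition slope")
print(f"({cfg.slopes[('exception', 'early')]} -> {cfg.slopes[('exception', 'delayed')]}); "
      "the base model folds both into its")
print("condition[delayed] coefficient, the repetition model separates them.")
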