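"""Fit the hierarchical model to a small synthetic cohort and report it.

Generates 16 subjects from the study-like hierarchy (anxiety raising the
punishment learning rate, women lower on punishment learning and response
bias), samples the joint posterior with a short NUTS run, and prints the
coefficient table.  A real analysis would use more subjects and the full
sampling plan (4 chains x 5000 iterations); this keeps the demo to about a
minute.
"""

from pporl import (CohortSpec, SamplerConfig, convergence_report, fit,
                   generate_cohort, group_contrasts, summarize_posterior)

cohort = generate_cohort(CohortSpec(n_subjects=16))
print(f"cohort: {cohort.n_subjects} subjects, "
      f"{cohort.behavior[0].n_trials} trials each")

config = SamplerConfig(n_chains=2, n_iterations=700, n_warmup=250, seed=0,
                       max_treedepth=6)
draws = fit(cohort, config)
report = convergence_report(draws)
print(f"max split R-hat {report.max_rhat:.3f} "
      f"(criterion < 1.1), divergences {report.n_divergent}")

print("\nPosterior summary (latent scale; learning rates are probit):")
print(summarize_posterior(draws).round(2).to_string(index=False))

print("\nDiagnosis contrasts (history present minus absent):")
print(group_contrasts(draws).round(2).to_string(index=False))
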