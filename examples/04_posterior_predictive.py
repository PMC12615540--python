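"""Posterior predictive check: simulated play-proportion bands vs data.

Fits a small cohort, then re-simulates behaviour from posterior draws and
prints, per deck and 10-presentation block, the observed play proportion
against the predictive mean with 50% and 95% credible bands.  Observed
values should sit inside the 95% band almost everywhere when the model
fits.
"""

from pporl import (CohortSpec, SamplerConfig, fit, generate_cohort,
                   posterior_predictive)

cohort = generate_cohort(CohortSpec(n_subjects=16))
draws = fit(cohort, SamplerConfig(n_chains=2, n_iterations=400, n_warmup=150,
                                  seed=1, max_treedepth=6))
bands = posterior_predictive(draws, cohort, n_reps=200, seed=2)

inside = ((bands["observed"] >= bands["lo95"])
          & (bands["observed"] <= bands["hi95"]))
print(bands.round(3).to_string(index=False))
print(f"\nobserved inside the 95% band in {inside.sum()}/{len(bands)} cells")
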