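"""Estimate SDT parameters and covariate effects in one probit model.

Trial-level urgent/non-urgent decisions are regressed on the case class
(coded +0.5 / -0.5) and responder covariates, with per-responder random
deviations on the intercept (criterion) and the class slope (d').
Under this coding the intercept is -c and the class slope is d', so
covariate main effects shift the criterion and class interactions shift
discrimination -- no 0.5 correction needed.
"""

from sdtrefer import (
    GlmSdtSpec,
    SimConfig,
    fit_probit_sdt,
    generate_study,
    glm_to_sdt,
)

ds, truth = generate_study(SimConfig(seed=1, n_responders=120))
res = fit_probit_sdt(ds, GlmSdtSpec(covariates=["practice_ppv_percent", "gender"]))

print(res.coefficients.round(4).to_string(index=False))
print(f"\nrandom-effect SDs: { {k: round(v, 3) for k, v in res.re_sd.items()} }")

effects = glm_to_sdt(res)
print("\ncriterion effects:", {k: round(v, 3) for k, v in effects["criterion"].items()})
print("d' effects:       ", {k: round(v, 3) for k, v in effects["d_prime"].items()})
print()
print("A positive PPV coefficient on the criterion side means responders "
      "from practices whose referrals more often convert to a cancer "
      "diagnosis are less inclined to refer; a negative gender (female) "
      "effect on the criterion means women are more inclined to refer.")
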