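"""Occiput morphotype dummies and detransformation correction factors.

Simulates species where rabbit-like occiputs shift ln mass by +0.715 and
monotreme-like occiputs by -1.146 (narrow vs wide condyles relative to body
size), fits the model with and without morphotype dummies, and prints the
three correction factors of the better model.
"""

from ocwmass import (
    AllometricModelSpec,
    ModelTerm,
    SimulationConfig,
    accuracy_report,
    correction_factors,
    fit_model,
    simulate_dataset,
)

ds = simulate_dataset(SimulationConfig(n_species=404, lambda_signal=0.0, seed=2))

plain = fit_model(ds.species, AllometricModelSpec.power(2 / 3))
dummies = fit_model(
    ds.species,
    AllometricModelSpec(terms=(ModelTerm("ocw", 2 / 3),),
                        covariates=("rabbit_like", "monotreme_like")),
)

for name, fit in (("OCW only", plain), ("OCW + morphotype dummies", dummies)):
    cf = correction_factors(fit)
    rep = accuracy_report(fit, cf)
    print(f"{name}: AIC {fit.aic:.0f}, %PEcf {rep.mean_abs_pe_cf:.2f}, "
          f"%SEE {rep.pct_see:.2f}")

print(f"\nrecovered shifts: rabbit {dummies.params['rabbit_like']:+.3f} "
      f"(true +0.715), monotreme {dummies.params['monotreme_like']:+.3f} "
      f"(true -1.146)")
cf = correction_factors(dummies)
print(f"correction factors: QMLE {cf.qmle:.3f}, smearing {cf.smearing:.3f}, "
      f"ratio {cf.ratio:.3f}, mean {cf.mean_cf:.3f}")
print("Adding the two shape dummies should cut %PE and %SEE noticeably, "
      "mirroring how condyle shape, not allometry, separates these clades.")
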