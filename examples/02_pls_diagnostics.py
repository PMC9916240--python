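"""Fit the soil sub-model and read its chemometric diagnostics.

Generates a default synthetic study, fits a 3-component PLS from the 34
featuring variables to the measured C_nm, and prints the fit (R2) and
cross-validated predictivity (Q2) statistics. Q2(cum) above 0.5 is the
conventional threshold for a usefully predictive model.
"""
from omstab import fit_submodel, generate_dataset
from omstab.coupling import SubModelSpec

dataset = generate_dataset(seed=1)
model = fit_submodel(dataset, SubModelSpec("soil"), holdout_families=("W01", "W26"))

print(f"soil sub-model, n = {model.n_samples} incubated samples, "
      f"A = {model.n_components} components")
print(f"  R2X(cum) = {model.r2x_cum:.3f}   (input variance explained)")
print(f"  R2Y(cum) = {model.r2y_cum:.3f}   (C_nm variance explained)")
print(f"  Q2(cum)  = {model.q2_cum:.3f}   (predicted variance, 7-group CV)")
print(f"  RMSEE    = {model.rmsee[0]:.3f} C_nm points  (training fit)")
print(f"  RMSEcv   = {model.rmsecv[0]:.3f} C_nm points  (cross-validated)")

print("\nper-component Q2 (a component below ~0.05 adds no predictivity):")
for a, q2 in enumerate(model.q2, start=1):
    print(f"  component {a}: {q2:+.3f}")
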