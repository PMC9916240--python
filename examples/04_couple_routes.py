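"""Chain the three sub-models: predict C_nm along each management route.

Fits the AD, composting and soil sub-models on a synthetic study (holding
out two waste families), then predicts the soil stability of one raw waste
under the four management routes from its characterization alone, and
validates the chain on the held-out families.
"""
from omstab import fit_coupled, generate_dataset, validate_holdout

HOLDOUT = ("W01", "W26")

dataset = generate_dataset(seed=1)
model = fit_coupled(dataset, holdout_families=HOLDOUT)

for stage, sub in (("AD", model.ad), ("composting", model.compost),
                   ("soil", model.soil)):
    print(f"{stage:10s} sub-model: R2Y(cum) = {sub.r2y_cum:.3f}, "
          f"Q2(cum) = {sub.q2_cum:.3f}")

waste = dataset.samples["W02"]
print(f"\npredicted C_nm of {waste.sample_id} (raw waste) per route:")
for route, kwargs in (
    ("raw", {}),
    ("AD", {"hrt_days": 40.0}),
    ("compost", {"dc_days": 50.0}),
    ("AD+compost", {"hrt_days": 40.0, "dc_days": 50.0}),
):
    cnm, _ = model.predict(waste.features, route, **kwargs)
    print(f"  {route:11s} -> {cnm:5.1f}%")
print("  -> each treatment stage stabilizes the organic matter further")

report = validate_holdout(dataset, model, HOLDOUT)
print(f"\nholdout validation ({', '.join(HOLDOUT)}; never seen in training):")
print(report.to_frame().round(1).to_string(index=False))
print(f"holdout RMSE = {report.rmse:.2f} C_nm points")
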