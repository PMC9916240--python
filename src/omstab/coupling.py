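"""Chained sub-model pipeline: digestion → composting → soil.

Three multi-response PLS sub-models are fitted on paired data:

* **AD** — 34 featuring variables of the raw waste plus the hydraulic
  retention time (HRT, days) → 34 variables of the solid digestate;
* **composting** — 34 variables of the waste or digestate plus the
  composting duration (DC, days) → 34 variables of the compost;
* **soil** — 34 variables of any material → its non-mineralized carbon
  C_nm (%) after soil incubation.

Chained along a management route (direct spreading, AD, composting, or
AD then composting), the models predict the stability of the final product
from the raw waste's characterization alone.  Predicted 34-vectors are
*re-closed* (negative entries clipped, the AC block and each 7-zone Pf
block rescaled to 100%) before feeding the next stage, and the adjustment
magnitude is logged so chain degradation can be audited.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characterize import FEATURE_NAMES, FRACTIONS, SampleRecord, ac_slice, pf_slice
from .dataset import StudyDataset, parse_family
from .pls import PLSModel, ScalingSpec, fit_pls_cv

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_SUBSETS",
    "SubModelSpec",
    "CoupledModel",
    "ValidationReport",
    "fit_submodel",
    "fit_coupled",
    "reclose_profile",
    "couple_predict",
    "validate_holdout",
    "ablation_run",
]

#: named feature subsets used in the ablation study
FEATURE_SUBSETS: dict[str, list[str]] = {
    "all": list(FEATURE_NAMES),
    "accessibility": [FEATURE_NAMES[0]] + [n for n in FEATURE_NAMES if n.endswith("_AC")],
    "complexity": [FEATURE_NAMES[0]] + [n for n in FEATURE_NAMES if "_Pf_" in n],
}

ROUTES = ("raw", "AD", "compost", "AD+compost")


@dataclass
class SubModelSpec:
    """Configuration of one stage sub-model."""

    stage: str  # AD | compost | soil
    n_components: int = 3
    n_cv_groups: int = 7
    feature_subset: str = "all"
    exclude_ids: tuple[str, ...] = ()
    scaling: ScalingSpec = field(default_factory=ScalingSpec)

    def __post_init__(self) -> None:
        if self.stage not in ("AD", "compost", "soil"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.feature_subset not in FEATURE_SUBSETS:
            raise ValueError(f"unknown feature subset {self.feature_subset!r}")

    @property
    def duration_name(self) -> str | None:
        return {"AD": "HRT", "compost": "DC", "soil": None}[self.stage]

    def input_names(self) -> list[str]:
        names = list(FEATURE_SUBSETS[self.feature_subset])
        if self.duration_name:
            names.append(self.duration_name)
        return names

    def output_names(self) -> list[str]:
        if self.stage == "soil":
            return ["C_nm"]
        return list(FEATURE_SUBSETS[self.feature_subset])


def _subset_indices(subset: str) -> np.ndarray:
    return np.array([FEATURE_NAMES.index(n) for n in FEATURE_SUBSETS[subset]])


def _excluded(sid: str, spec: SubModelSpec, holdout_families: tuple[str, ...]) -> bool:
    return sid in spec.exclude_ids or parse_family(sid) in holdout_families


def fit_submodel(
    dataset: StudyDataset,
    spec: SubModelSpec,
    holdout_families: tuple[str, ...] = (),
) -> PLSModel:
    """Fit one stage sub-model from the paired study data.

    Holdout families and explicitly excluded sample ids never enter the
    training matrices.  The fitted model records its training sample ids
    for provenance and leakage checks.
    """
    idx = _subset_indices(spec.feature_subset)
    rows_x, rows_y, train_ids = [], [], []
    if spec.stage == "soil":
        for sid, cnm in sorted(dataset.cnm.items()):
            if _excluded(sid, spec, holdout_families):
                continue
            rows_x.append(dataset.samples[sid].features[idx])
            rows_y.append([cnm])
            train_ids.append(sid)
    else:
        pairs = dataset.ad_pairs if spec.stage == "AD" else dataset.compost_pairs
        for pair in pairs:
            if _excluded(pair.input_id, spec, holdout_families) or _excluded(
                pair.output_id, spec, holdout_families
            ):
                continue
            for sid in (pair.input_id, pair.output_id):
                if sid not in dataset.samples:
                    raise ValueError(f"unpaired sample id {sid!r} in {spec.stage} pairs")
            x = np.append(
                dataset.samples[pair.input_id].features[idx], pair.duration_days
            )
            rows_x.append(x)
            rows_y.append(dataset.samples[pair.output_id].features[idx])
            train_ids.append(pair.output_id)
            train_ids.append(pair.input_id)
    if not rows_x:
        raise ValueError(f"no training pairs left for stage {spec.stage!r}")
    X = np.vstack(rows_x)
    Y = np.vstack(rows_y)
    model = fit_pls_cv(
        X,
        Y,
        spec.n_components,
        n_groups=min(spec.n_cv_groups, X.shape[0]),
        x_names=spec.input_names(),
        y_names=spec.output_names(),
        x_scaling=spec.scaling,
        y_scaling=spec.scaling,
    )
    model.training_ids = sorted(set(train_ids))  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# re-closure of predicted compositions
# ---------------------------------------------------------------------------


def reclose_profile(
    vector: np.ndarray, feature_names: list[str] | None = None
) -> tuple[np.ndarray, float]:
    """Make a predicted feature vector a valid composition again.

    Negative entries are clipped to zero, the AC block is rescaled to sum
    100, each fraction's 7-zone Pf block is rescaled to sum 100, and any
    carbon-content variable is kept strictly positive.  Returns the closed
    vector and the total L1 adjustment applied (0 for an already valid
    profile — the operation is idempotent).
    """
    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    v = np.asarray(vector, dtype=float)
    if v.shape != (len(names),):
        raise ValueError(f"expected {len(names)} entries, got shape {v.shape}")
    out = v.copy()

    blocks: list[list[int]] = []
    ac_idx = [i for i, n in enumerate(names) if n.endswith("_AC")]
    if ac_idx:
        blocks.append(ac_idx)
    for f in FRACTIONS:
        pf_idx = [i for i, n in enumerate(names) if n.startswith(f"{f}_Pf_")]
        if pf_idx:
            blocks.append(pf_idx)

    for block in blocks:
        vals = np.clip(out[block], 0.0, None)
        total = vals.sum()
        if total <= 0:
            raise ValueError("composition block collapsed to zero after clipping")
        out[block] = vals / total * 100.0

    for i, n in enumerate(names):
        if n == "OM_TC" and out[i] <= 0:
            out[i] = 1e-6

    adjustment = float(np.abs(out - v).sum())
    if adjustment > 1e-9:
        logger.info("re-closure adjusted profile by %.4g (L1)", adjustment)
    return out, adjustment


# ---------------------------------------------------------------------------
# coupled model
# ---------------------------------------------------------------------------


@dataclass
class CoupledModel:
    """The three fitted sub-models wired per management route."""

    ad: PLSModel
    compost: PLSModel
    soil: PLSModel
    feature_subset: str = "all"
    holdout_families: tuple[str, ...] = ()

    @property
    def feature_names(self) -> list[str]:
        return FEATURE_SUBSETS[self.feature_subset]

    def stage_models(self, route: str) -> list[tuple[str, PLSModel]]:
        chain = {
            "raw": [],
            "AD": [("AD", self.ad)],
            "compost": [("compost", self.compost)],
            "AD+compost": [("AD", self.ad), ("compost", self.compost)],
        }
        if route not in chain:
            raise ValueError(f"unknown route {route!r}; expected one of {ROUTES}")
        return chain[route] + [("soil", self.soil)]

    def predict(
        self,
        features: np.ndarray,
        route: str,
        hrt_days: float | None = None,
        dc_days: float | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        return couple_predict(self, features, route, hrt_days, dc_days)


def couple_predict(
    model: CoupledModel,
    features: np.ndarray,
    route: str,
    hrt_days: float | None = None,
    dc_days: float | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Predict C_nm for a raw waste along a management route.

    The waste's feature vector is pushed through each stage model in turn
    (with the stage duration appended for the AD and composting stages),
    the predicted profile re-closed between stages, and the soil model
    applied last.  Returns the predicted C_nm (%), clipped to [0, 100]
    with a warning if the raw prediction fell outside, plus the
    intermediate re-closed profiles keyed by stage.
    """
    durations = {"AD": hrt_days, "compost": dc_days}
    current = np.asarray(features, dtype=float)
    if current.shape != (len(model.feature_names),):
        raise ValueError(
            f"expected {len(model.feature_names)} features for subset "
            f"{model.feature_subset!r}, got shape {current.shape}"
        )
    intermediates: dict[str, np.ndarray] = {}
    for stage, sub in model.stage_models(route):
        if stage == "soil":
            cnm = float(sub.predict(current)[0, 0])
            break
        d = durations[stage]
        if d is None:
            raise ValueError(f"route {route!r} requires a duration for stage {stage!r}")
        pred = sub.predict(np.append(current, d))[0]
        current, _ = reclose_profile(pred, model.feature_names)
        intermediates[stage] = current
    else:  # pragma: no cover - soil stage always terminates the chain
        raise RuntimeError("route did not terminate in the soil stage")
    if not (0.0 <= cnm <= 100.0):
        warnings.warn(
            f"predicted C_nm {cnm:.1f}% outside [0, 100]; clipped", stacklevel=2
        )
        cnm = float(np.clip(cnm, 0.0, 100.0))
    return cnm, intermediates


def fit_coupled(
    dataset: StudyDataset,
    holdout_families: tuple[str, ...] = (),
    exclude_ids: tuple[str, ...] = (),
    n_components: dict[str, int] | int = 3,
    feature_subset: str = "all",
    n_cv_groups: int = 7,
) -> CoupledModel:
    """Fit the three sub-models on the study data and wire them together."""
    if isinstance(n_components, int):
        n_components = {s: n_components for s in ("AD", "compost", "soil")}
    subs = {}
    for stage in ("AD", "compost", "soil"):
        spec = SubModelSpec(
            stage=stage,
            n_components=n_components[stage],
            n_cv_groups=n_cv_groups,
            feature_subset=feature_subset,
            exclude_ids=tuple(exclude_ids),
        )
        subs[stage] = fit_submodel(dataset, spec, tuple(holdout_families))
    model = CoupledModel(
        ad=subs["AD"],
        compost=subs["compost"],
        soil=subs["soil"],
        feature_subset=feature_subset,
        holdout_families=tuple(holdout_families),
    )
    assert_no_leakage(model, holdout_families)
    return model


def assert_no_leakage(model: CoupledModel, holdout_families: tuple[str, ...]) -> None:
    """Raise if any holdout-family sample appears in a sub-model's training set."""
    holdout = set(holdout_families)
    for stage, sub in (("AD", model.ad), ("compost", model.compost), ("soil", model.soil)):
        ids = getattr(sub, "training_ids", [])
        leaked = sorted(sid for sid in ids if parse_family(sid) in holdout)
        if leaked:
            raise ValueError(f"holdout leakage into {stage} training set: {leaked}")


# ---------------------------------------------------------------------------
# validation & ablation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Observed vs predicted C_nm for held-out samples."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["sample_id", "route", "observed_cnm", "predicted_cnm", "abs_error"],
        )

    @property
    def rmse(self) -> float:
        errs = [r["abs_error"] for r in self.rows if r["abs_error"] is not None]
        if not errs:
            return float("nan")
        return float(np.sqrt(np.mean(np.square(errs))))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def validate_holdout(
    dataset: StudyDataset,
    model: CoupledModel,
    holdout_families: tuple[str, ...],
) -> ValidationReport:
    """Predict C_nm for every holdout-family sample from its raw waste only.

    Each holdout sample's route and stage durations are reconstructed from
    the pairing structure; the prediction starts from the *raw waste's*
    features in all cases, so the report measures the full chained
    pipeline.  Samples without a measured C_nm (never incubated) get a
    prediction with an empty observed column.  Raises if any holdout sample
    leaked into a training set.
    """
    assert_no_leakage(model, holdout_families)
    idx = _subset_indices(model.feature_subset)
    holdout = set(holdout_families)
    report = ValidationReport()
    for sid in sorted(dataset.samples):
        if parse_family(sid) not in holdout:
            continue
        root, route, hrt, dc = dataset.route_of(sid)
        if route == "raw" and sid not in dataset.cnm:
            # un-incubated raw material: prediction only, flagged by the
            # empty observed column
            pass
        waste = dataset.samples[root]
        pred, _ = couple_predict(model, waste.features[idx], route, hrt, dc)
        obs = dataset.cnm.get(sid)
        report.rows.append(
            {
                "sample_id": sid,
                "route": route,
                "observed_cnm": obs,
                "predicted_cnm": pred,
                "abs_error": abs(pred - obs) if obs is not None else None,
            }
        )
    return report


def ablation_run(
    dataset: StudyDataset,
    holdout_families: tuple[str, ...],
    exclude_ids: tuple[str, ...] = (),
    n_components: dict[str, int] | int = 3,
    subsets: tuple[str, ...] = ("all", "accessibility", "complexity"),
    n_cv_groups: int = 7,
) -> dict[str, ValidationReport]:
    """Re-run the coupled pipeline on reduced feature sets.

    Builds one coupled model per feature subset on the *same* training /
    holdout split and validates each on the holdout families, so the
    reports are directly comparable sample by sample.  The canonical
    subsets are the full 34 variables, carbon content + 5 accessibility
    variables (6), and carbon content + 28 complexity variables (29).
    """
    reports = {}
    for subset in subsets:
        model = fit_coupled(
            dataset,
            holdout_families=holdout_families,
            exclude_ids=exclude_ids,
            n_components=n_components,
            feature_subset=subset,
            n_cv_groups=n_cv_groups,
        )
        reports[subset] = validate_holdout(dataset, model, holdout_families)
    return reports
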