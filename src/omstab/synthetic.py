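"""Synthetic study-shaped data with the structure the analysis assumes.

The generator emulates the statistical shape of a multi-waste treatment
study: several groups of wastes with distinct composition profiles,
treatment operators (anaerobic digestion, composting) that move carbon from
accessible to refractory fractions and fluorescence mass from protein-like
zones (I–III) to humified zones (IV–VII) — the right-to-upper-left drift
seen in score plots of real material — and a linear stability response
C_nm with Gaussian measurement noise.

Compositional blocks are drawn from Dirichlet distributions around group
mean profiles, so every generated record satisfies the closure invariants
exactly by construction (no negative-clipping artifacts).  Treatment
transfers stay within the simplex, hence closure is preserved exactly along
a treatment chain.

Default effect sizes and dispersions are calibration choices (the magnitude
of shifts a treatment study of this kind typically shows), not estimates
from any particular dataset; see the methods note.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .characterize import (
    FEATURE_NAMES,
    FRACTIONS,
    N_FEATURES,
    SampleRecord,
    ac_slice,
    pf_slice,
)
from .dataset import StudyDataset, TreatmentPair

__all__ = [
    "GeneratorParams",
    "generate_wastes",
    "apply_treatment",
    "true_cnm",
    "generate_dataset",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _pf_mean(labile_share: float) -> np.ndarray:
    """7-zone mean composition from the share of zones I–III."""
    s = float(np.clip(labile_share, 0.05, 0.90))
    labile = s * np.array([0.40, 0.35, 0.25])
    humic = (1 - s) * np.array([0.30, 0.30, 0.25, 0.15])
    return np.concatenate([labile, humic])


# per-fraction offset of the labile fluorescence share: the soluble fraction
# carries more protein-like material than the poorly extractable one
_FRACTION_LABILE_OFFSET = {"SPOM": 0.08, "REOM": 0.03, "SEOM": -0.03, "PEOM": -0.08}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic study generator.

    Rates are per day and act multiplicatively: a transfer rate *r* over a
    duration *t* retains a fraction ``(1−r)**t`` of the labile pool.
    ``cnm_beta`` acts on features standardized against a fixed reference
    scale derived from the group means, so its entries are in C_nm
    percentage points per reference standard deviation.
    """

    n_wastes: int = 31
    n_groups: int = 5
    # group mean composition: the five default groups sit along a single
    # lability gradient (fresh, carbon-rich, accessible material down to
    # stabilized, refractory material), the dominant axis real multi-waste
    # collections show
    group_om_tc: tuple[float, ...] = (420.0, 330.0, 390.0, 300.0, 360.0)
    group_ac_means: tuple[tuple[float, ...], ...] = (
        (0.2340, 0.2400, 0.2060, 0.1500, 0.1700),
        (0.1995, 0.2100, 0.1955, 0.1725, 0.2225),
        (0.1650, 0.1800, 0.1850, 0.1950, 0.2750),
        (0.1305, 0.1500, 0.1745, 0.2175, 0.3275),
        (0.0960, 0.1200, 0.1640, 0.2400, 0.3800),
    )
    # the fluorescence gradient is deliberately not collinear with the
    # carbon-accessibility gradient: real wastes (e.g. sludges) can be
    # chemically accessible yet carry a complex soluble-OM signature, and
    # the stability signal draws on both blocks
    group_pf_labile_share: tuple[float, ...] = (0.50, 0.62, 0.38, 0.56, 0.44)
    # within-group dispersion
    ac_concentration: float = 2500.0
    pf_concentration: float = 2200.0
    om_tc_sigma: float = 0.05  # lognormal sd on OM_TC
    # anaerobic digestion effect rates (per day)
    ad_ac_rate: float = 0.010
    ad_pf_rate: float = 0.008
    ad_tc_rate: float = 0.004
    # composting effect rates (per day)
    compost_ac_rate: float = 0.009
    compost_pf_rate: float = 0.008
    compost_tc_rate: float = 0.005
    # split of transferred accessible carbon between PEOM and NEOM
    transfer_to_peom: float = 0.4
    # treatment reproducibility noise (0 → deterministic operator)
    treatment_noise: float = 1.0
    treatment_ac_concentration: float = 5000.0
    treatment_pf_concentration: float = 4000.0
    treatment_om_tc_sigma: float = 0.015
    # stability response
    cnm_beta0: float = 58.0
    cnm_beta: dict[str, float] = field(default_factory=lambda: _default_beta())
    cnm_sigma: float = 2.0
    # study shape
    hrt_cycle: tuple[float, ...] = (20.0, 21.0, 28.0, 29.0, 50.0, 56.0, 70.0, 75.0)
    dc_cycle: tuple[float, ...] = (14.0, 28.0, 42.0, 50.0, 56.0, 60.0, 70.0, 77.0, 84.0)

    def __post_init__(self) -> None:
        if self.n_wastes < 1:
            raise ValueError("n_wastes must be >= 1")
        if not (1 <= self.n_groups <= len(self.group_ac_means)):
            raise ValueError("n_groups exceeds the number of group mean profiles")
        for rate_name in (
            "ad_ac_rate",
            "ad_pf_rate",
            "compost_ac_rate",
            "compost_pf_rate",
        ):
            r = getattr(self, rate_name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{rate_name} must be in [0, 1)")
        for g, m in enumerate(self.group_ac_means[: self.n_groups]):
            if abs(sum(m) - 1.0) > 1e-9 or min(m) <= 0:
                raise ValueError(f"group_ac_means[{g}] must be a positive composition summing to 1")
        if self.cnm_sigma < 0:
            raise ValueError("cnm_sigma must be >= 0")
        if not (0.0 <= self.transfer_to_peom <= 1.0):
            raise ValueError("transfer_to_peom must be in [0, 1]")

    # ------------------------------------------------------------------
    def group_mean_features(self, g: int) -> np.ndarray:
        """Mean 34-vector of group g (AC and Pf in %, OM_TC in mg C/g DM)."""
        parts = [np.array([self.group_om_tc[g % len(self.group_om_tc)]])]
        parts.append(np.asarray(self.group_ac_means[g]) * 100.0)
        s = self.group_pf_labile_share[g % len(self.group_pf_labile_share)]
        for f in FRACTIONS:
            parts.append(_pf_mean(s + _FRACTION_LABILE_OFFSET[f]) * 100.0)
        return np.concatenate(parts)

    def reference_scale(self) -> tuple[np.ndarray, np.ndarray]:
        """Fixed standardization reference for the C_nm response model.

        The mean is the average of the group mean profiles; the scale is a
        fixed plausible spread per variable type (so the response model is a
        deterministic function of the parameters, not of a dataset).
        """
        means = np.mean(
            [self.group_mean_features(g) for g in range(self.n_groups)], axis=0
        )
        sds = np.empty(N_FEATURES)
        sds[0] = 40.0  # OM_TC, mg C/g DM
        sds[ac_slice()] = 4.0  # AC, %
        sds[6:] = 2.5  # Pf, %
        return means, sds

    def beta_vector(self) -> np.ndarray:
        beta = np.zeros(N_FEATURES)
        for name, b in self.cnm_beta.items():
            beta[FEATURE_NAMES.index(name)] = b
        return beta


def _default_beta() -> dict[str, float]:
    """Stability loads positively on refractory carbon and humified zones."""
    beta = {
        "OM_TC": -0.25,
        "SPOM_AC": -0.9,
        "REOM_AC": -0.65,
        "SEOM_AC": -0.25,
        "PEOM_AC": 0.5,
        "NEOM_AC": 1.25,
    }
    for f in FRACTIONS:
        for z in ("I", "II", "III"):
            beta[f"{f}_Pf_{z}"] = -0.18
        for z in ("IV", "V", "VI", "VII"):
            beta[f"{f}_Pf_{z}"] = 0.13
    return beta


# ---------------------------------------------------------------------------


def generate_wastes(params: GeneratorParams, seed=None) -> list[SampleRecord]:
    """Draw raw wastes around their group mean profiles.

    OM_TC is lognormal, the AC block and each Pf block are Dirichlet draws
    around the group mean composition, so closure holds exactly for every
    record.  Groups are assigned round-robin.
    """
    rng = _rng(seed)
    records = []
    for i in range(params.n_wastes):
        g = i % params.n_groups
        om_tc = params.group_om_tc[g % len(params.group_om_tc)] * float(
            rng.lognormal(0.0, params.om_tc_sigma)
        )
        ac = rng.dirichlet(
            np.asarray(params.group_ac_means[g]) * params.ac_concentration
        )
        parts = [np.array([om_tc]), ac * 100.0]
        s = params.group_pf_labile_share[g % len(params.group_pf_labile_share)]
        for f in FRACTIONS:
            mean = _pf_mean(s + _FRACTION_LABILE_OFFSET[f])
            parts.append(rng.dirichlet(mean * params.pf_concentration) * 100.0)
        rec = SampleRecord(
            sample_id=f"W{i + 1:02d}",
            features=np.concatenate(parts),
            group_label=f"G{g + 1}",
            route="raw",
        )
        records.append(rec)
    return records


def _shift_composition(comp: np.ndarray, labile_idx, sink_idx, rate: float,
                       duration: float, sink_weights: np.ndarray | None = None) -> np.ndarray:
    """Move mass from labile to sink entries of a composition, within-simplex.

    Retains ``(1−rate)**duration`` of each labile entry; the transferred
    mass is distributed over the sinks with the given weights (default:
    proportional to current sink shares).
    """
    out = comp.astype(float).copy()
    retain = (1.0 - rate) ** duration
    moved = out[labile_idx].sum() * (1.0 - retain)
    out[labile_idx] *= retain
    sinks = out[sink_idx]
    if sink_weights is None:
        total = sinks.sum()
        weights = sinks / total if total > 0 else np.full(len(sinks), 1.0 / len(sinks))
    else:
        weights = np.asarray(sink_weights, dtype=float)
        weights = weights / weights.sum()
    out[sink_idx] = sinks + moved * weights
    return out


def apply_treatment(
    record: SampleRecord,
    kind: str,
    duration_days: float,
    params: GeneratorParams,
    seed=None,
    output_id: str | None = None,
) -> SampleRecord:
    """Transform a sample through anaerobic digestion or composting.

    Deterministic core: exponential transfer of accessible carbon
    (SPOM+REOM+SEOM AC) into PEOM/NEOM, of protein-like fluorescence
    (zones I–III) into zones IV–VII in every fraction, and first-order
    decay of OM_TC.  With ``treatment_noise > 0`` the shifted composition
    becomes the mean of a Dirichlet redraw (process reproducibility noise);
    at zero noise and zero duration the operator is the identity.
    """
    if duration_days < 0:
        raise ValueError("duration_days must be >= 0")
    if kind == "AD":
        r_ac, r_pf, r_tc = params.ad_ac_rate, params.ad_pf_rate, params.ad_tc_rate
    elif kind == "compost":
        r_ac, r_pf, r_tc = (
            params.compost_ac_rate,
            params.compost_pf_rate,
            params.compost_tc_rate,
        )
    else:
        raise ValueError(f"unknown treatment kind {kind!r}")
    rng = _rng(seed)

    ac = record.features[ac_slice()] / 100.0
    ac = _shift_composition(
        ac,
        labile_idx=np.arange(0, 3),
        sink_idx=np.arange(3, 5),
        rate=r_ac,
        duration=duration_days,
        sink_weights=np.array([params.transfer_to_peom, 1.0 - params.transfer_to_peom]),
    )
    # humified fluorescence appears with a characteristic zone signature,
    # independent of where the labile signal started
    humic_signature = np.array([0.30, 0.30, 0.25, 0.15])
    pf_blocks = []
    for f in FRACTIONS:
        pf = record.features[pf_slice(f)] / 100.0
        pf_blocks.append(
            _shift_composition(
                pf,
                labile_idx=np.arange(0, 3),
                sink_idx=np.arange(3, 7),
                rate=r_pf,
                duration=duration_days,
                sink_weights=humic_signature,
            )
        )
    om_tc = record.features[0] * float(np.exp(-r_tc * duration_days))

    noise = params.treatment_noise
    if noise > 0:
        ac = rng.dirichlet(np.maximum(ac, 1e-12) * params.treatment_ac_concentration / noise)
        pf_blocks = [
            rng.dirichlet(np.maximum(pf, 1e-12) * params.treatment_pf_concentration / noise)
            for pf in pf_blocks
        ]
        om_tc *= float(rng.lognormal(0.0, params.treatment_om_tc_sigma * noise))

    features = np.concatenate(
        [np.array([om_tc]), ac * 100.0] + [pf * 100.0 for pf in pf_blocks]
    )
    route = {"AD": "AD", "compost": "compost"}[kind]
    if record.route == "AD" and kind == "compost":
        route = "AD+compost"
    return SampleRecord(
        sample_id=output_id or f"{record.sample_id}-{'D' if kind == 'AD' else 'C'}",
        features=features,
        group_label=record.group_label,
        route=route,
        hrt_days=duration_days if kind == "AD" else record.hrt_days,
        dc_days=duration_days if kind == "compost" else None,
    )


def true_cnm(record: SampleRecord, params: GeneratorParams, seed=None) -> float:
    """Ground-truth stability response of a record.

    ``C_nm = clip(β₀ + βᵀ z + ε, 0, 100)`` with z the features standardized
    against the fixed reference scale and ε ~ N(0, σ²).
    """
    rng = _rng(seed)
    ref_mean, ref_sd = params.reference_scale()
    z = (record.features - ref_mean) / ref_sd
    eps = float(rng.normal(0.0, params.cnm_sigma)) if params.cnm_sigma > 0 else 0.0
    return float(np.clip(params.cnm_beta0 + params.beta_vector() @ z + eps, 0.0, 100.0))


def generate_dataset(params: GeneratorParams | None = None, seed=None) -> StudyDataset:
    """Generate a full study-shaped dataset.

    Shape (at the defaults): 31 wastes in 5 groups; a solid digestate for
    three wastes out of four (HRT cycled through the configured values); a
    compost for two wastes out of three (DC cycled likewise); a compost of
    digestate for the digestates of every fifth waste; measured C_nm for
    all samples except every seventh waste (the analogue of material that
    is not allowed to be spread raw, hence never incubated).  Families share
    the waste's id prefix, so holdout splitting by family is exact.
    """
    params = params or GeneratorParams()
    rng = _rng(seed)
    ds = StudyDataset()
    wastes = generate_wastes(params, rng)
    for i, w in enumerate(wastes):
        measured = (i % 7) != 6
        ds.add(w, cnm=true_cnm(w, params, rng) if measured else None)

    digestates: dict[int, SampleRecord] = {}
    k = 0
    for i, w in enumerate(wastes):
        if i % 4 == 3:
            continue
        hrt = params.hrt_cycle[k % len(params.hrt_cycle)]
        k += 1
        d = apply_treatment(w, "AD", hrt, params, rng, output_id=f"{w.sample_id}-D")
        ds.add(d, cnm=true_cnm(d, params, rng))
        ds.ad_pairs.append(TreatmentPair(w.sample_id, d.sample_id, hrt))
        digestates[i] = d

    k = 0
    for i, w in enumerate(wastes):
        if i % 3 == 2:
            continue
        dc = params.dc_cycle[k % len(params.dc_cycle)]
        k += 1
        c = apply_treatment(w, "compost", dc, params, rng, output_id=f"{w.sample_id}-C")
        ds.add(c, cnm=true_cnm(c, params, rng))
        ds.compost_pairs.append(TreatmentPair(w.sample_id, c.sample_id, dc))

    k = 0
    for i, d in digestates.items():
        if i % 5 != 0:
            continue
        dc = params.dc_cycle[(k + 3) % len(params.dc_cycle)]
        k += 1
        dc_rec = apply_treatment(
            d, "compost", dc, params, rng, output_id=f"{d.sample_id}-C"
        )
        ds.add(dc_rec, cnm=true_cnm(dc_rec, params, rng))
        ds.compost_pairs.append(TreatmentPair(d.sample_id, dc_rec.sample_id, dc))

    ds.validate_links()
    return ds
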