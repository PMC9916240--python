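"""Organic-matter characterization.

Turns raw laboratory measurements into the 34 featuring variables used by
every model in the package:

* ``OM_TC`` — total carbon of the powder sample (mg C g⁻¹ DM);
* five *accessibility* variables — the apportionment of carbon (AC, % of
  OM_TC) among the sequential-extraction fractions SPOM, REOM, SEOM, PEOM
  and the non-extractable residue NEOM;
* 28 *complexity* variables — the fluorescence proportions (Pf, %) of
  seven excitation–emission zones (I–VII) in each of the four extractable
  fractions, obtained by regional integration of the fraction's
  excitation–emission matrix (EEM).

It also computes the stability response: the non-mineralized carbon C_nm
(% of added carbon not respired as CO₂ during a soil incubation).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZONE_LABELS",
    "FRACTIONS",
    "AC_NAMES",
    "FEATURE_NAMES",
    "N_FEATURES",
    "EEM",
    "Zone",
    "ZoneSet",
    "ScatterMask",
    "FluorescenceProfile",
    "FractionProfile",
    "SampleRecord",
    "IncubationSeries",
    "integrate_eem_zones",
    "normalize_zone_volumes",
    "fluorescence_proportions",
    "apportion_carbon",
    "net_co2",
    "compute_cnm",
    "assemble_features",
    "ac_slice",
    "pf_slice",
]

ZONE_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII")
FRACTIONS = ("SPOM", "REOM", "SEOM", "PEOM")
AC_NAMES = ("SPOM_AC", "REOM_AC", "SEOM_AC", "PEOM_AC", "NEOM_AC")
FEATURE_NAMES: tuple[str, ...] = (
    ("OM_TC",)
    + AC_NAMES
    + tuple(f"{f}_Pf_{z}" for f in FRACTIONS for z in ZONE_LABELS)
)
N_FEATURES = len(FEATURE_NAMES)  # 34

#: slack allowed on the AC closure (sum of the five AC values, %) before a
#: sample is flagged as suspicious
AC_CLOSURE_BAND = (90.0, 110.0)


def ac_slice() -> slice:
    """Index slice of the 5 accessibility variables in a feature vector."""
    return slice(1, 6)


def pf_slice(fraction: str) -> slice:
    """Index slice of one fraction's 7-zone Pf block in a feature vector."""
    k = FRACTIONS.index(fraction)
    return slice(6 + 7 * k, 13 + 7 * k)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EEM:
    """Excitation–emission fluorescence matrix of one supernatant.

    ``intensity`` has one row per excitation wavelength and one column per
    emission wavelength (arbitrary units, U.A.).  ``toc_sample`` is the TOC
    concentration (mg L⁻¹) of the analysed supernatant, used to normalize
    zone volumes.
    """

    ex_wavelengths: np.ndarray
    em_wavelengths: np.ndarray
    intensity: np.ndarray
    toc_sample: float | None = None

    def __post_init__(self) -> None:
        self.ex_wavelengths = np.asarray(self.ex_wavelengths, dtype=float)
        self.em_wavelengths = np.asarray(self.em_wavelengths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        for name, ax in (("ex", self.ex_wavelengths), ("em", self.em_wavelengths)):
            if ax.ndim != 1 or ax.size < 2:
                raise ValueError(f"{name} wavelength axis must be 1-D with >= 2 points")
            if not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} wavelengths must be strictly increasing")
        if self.intensity.shape != (self.ex_wavelengths.size, self.em_wavelengths.size):
            raise ValueError(
                f"intensity grid {self.intensity.shape} does not match axes "
                f"({self.ex_wavelengths.size}, {self.em_wavelengths.size})"
            )


@dataclass(frozen=True)
class Zone:
    """One rectangular excitation–emission integration zone."""

    label: str
    ex_min: float
    ex_max: float
    em_min: float
    em_max: float

    def __post_init__(self) -> None:
        if not (self.ex_max > self.ex_min and self.em_max > self.em_min):
            raise ValueError(f"zone {self.label!r} has a degenerate Ex/Em range")

    @property
    def area(self) -> float:
        """Zone area S_i in nm²."""
        return (self.ex_max - self.ex_min) * (self.em_max - self.em_min)


@dataclass
class ZoneSet:
    """An ordered collection of integration zones (default: seven, I–VII)."""

    zones: list[Zone]

    def __post_init__(self) -> None:
        labels = [z.label for z in self.zones]
        if len(set(labels)) != len(labels):
            raise ValueError("zone labels must be unique")
        if not self.zones:
            raise ValueError("zone set is empty")

    @property
    def labels(self) -> list[str]:
        return [z.label for z in self.zones]

    @property
    def areas(self) -> np.ndarray:
        return np.array([z.area for z in self.zones])

    def __len__(self) -> int:
        return len(self.zones)


@dataclass(frozen=True)
class ScatterMask:
    """Optional Rayleigh/Raman scatter mask, off by default.

    Cells with ``|em - order·ex| <= width`` are zeroed before integration
    for each configured scatter order.
    """

    first_order_width: float = 0.0
    second_order_width: float = 0.0

    def mask(self, ex: np.ndarray, em: np.ndarray) -> np.ndarray:
        """Boolean grid, True where intensity must be zeroed."""
        exg, emg = np.meshgrid(ex, em, indexing="ij")
        m = np.zeros(exg.shape, dtype=bool)
        if self.first_order_width > 0:
            m |= np.abs(emg - exg) <= self.first_order_width
        if self.second_order_width > 0:
            m |= np.abs(emg - 2.0 * exg) <= self.second_order_width
        return m


@dataclass
class FluorescenceProfile:
    """TOC-normalized zone volumes (Vf) and proportions (Pf, %) of a fraction."""

    fraction_label: str
    vf: np.ndarray
    pf: np.ndarray

    def __post_init__(self) -> None:
        self.vf = np.asarray(self.vf, dtype=float)
        self.pf = np.asarray(self.pf, dtype=float)
        if self.fraction_label not in FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction_label!r}")
        if np.any(self.pf < -1e-12):
            raise ValueError("Pf entries must be non-negative")
        if np.any(self.vf > 0) and abs(self.pf.sum() - 100.0) > 1e-9:
            raise ValueError("Pf must sum to 100%")


@dataclass
class FractionProfile:
    """Carbon bookkeeping of one sample across the five extraction fractions."""

    om_tc: float
    toc_by_fraction: dict[str, float]  # SPOM/REOM/SEOM/PEOM, mg C g-1 DM
    tc_residue: float  # NEOM, mg C g-1 DM
    ac: np.ndarray = field(default=None)  # type: ignore[assignment]
    closure: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ac is None:
            self.ac, self.closure = apportion_carbon(
                self.om_tc, self.toc_by_fraction, self.tc_residue
            )


@dataclass
class SampleRecord:
    """One sample: identity, treatment metadata and its 34 featuring variables."""

    sample_id: str
    features: np.ndarray
    group_label: str | None = None
    route: str = "raw"  # raw | AD | compost | AD+compost
    hrt_days: float | None = None
    dc_days: float | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (N_FEATURES,):
            raise ValueError(
                f"sample {self.sample_id!r}: expected {N_FEATURES} features, "
                f"got shape {self.features.shape}"
            )

    def validate(self, pf_tol: float = 1e-6) -> list[str]:
        """Check closure invariants; returns human-readable warnings.

        The AC block is allowed to close anywhere inside ``AC_CLOSURE_BAND``
        (measurement recoveries below/above 100% are routine); each 7-zone
        Pf block must sum to 100 within ``pf_tol``.
        """
        issues: list[str] = []
        ac_sum = float(self.features[ac_slice()].sum())
        lo, hi = AC_CLOSURE_BAND
        if not (lo <= ac_sum <= hi):
            issues.append(
                f"sample {self.sample_id!r}: AC closure {ac_sum:.1f}% outside [{lo}, {hi}]"
            )
        for f in FRACTIONS:
            s = float(self.features[pf_slice(f)].sum())
            if abs(s - 100.0) > pf_tol:
                issues.append(
                    f"sample {self.sample_id!r}: {f} Pf block sums to {s:.4f}%"
                )
        if np.any(self.features < -1e-9):
            issues.append(f"sample {self.sample_id!r}: negative feature value")
        return issues

    def feature(self, name: str) -> float:
        return float(self.features[FEATURE_NAMES.index(name)])


@dataclass
class IncubationSeries:
    """Cumulative CO₂-C trapped during a soil incubation, amended vs control.

    All series are cumulative (mg C g⁻¹ DM of sample equivalent) on a shared
    strictly increasing day grid; ``tc_added`` is the carbon added with the
    amendment.
    """

    days: np.ndarray
    co2_amended: np.ndarray
    co2_control: np.ndarray
    tc_added: float

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.co2_amended = np.asarray(self.co2_amended, dtype=float)
        self.co2_control = np.asarray(self.co2_control, dtype=float)
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("sampling days must be strictly increasing")
        for name, s in (("amended", self.co2_amended), ("control", self.co2_control)):
            if s.shape != self.days.shape:
                raise ValueError(f"{name} series length does not match day grid")
            if np.any(np.diff(s) < -1e-9):
                raise ValueError(f"cumulative {name} series must be non-decreasing")


# ---------------------------------------------------------------------------
# fluorescence regional integration
# ---------------------------------------------------------------------------


def _cell_widths(axis: np.ndarray) -> np.ndarray:
    # rectangle-rule cell widths; central spacing inside, one-sided at edges
    return np.gradient(axis)


def integrate_eem_zones(
    eem: EEM,
    zones: ZoneSet,
    scatter_mask: ScatterMask | None = None,
) -> np.ndarray:
    """Raw fluorescence volume of each zone (U.A.·nm²), rectangle rule.

    Each grid point is treated as the centre of a cell of area Δex × Δem;
    a cell belongs to zone *i* when its centre lies inside the zone's
    rectangle (boundaries inclusive). Scatter cells, if a mask is given,
    are zeroed before integration.
    """
    ex, em = eem.ex_wavelengths, eem.em_wavelengths
    intensity = eem.intensity
    if scatter_mask is not None:
        intensity = np.where(scatter_mask.mask(ex, em), 0.0, intensity)
    dex = _cell_widths(ex)
    dem = _cell_widths(em)
    cell_area = np.outer(dex, dem)
    # grid coverage extends half a cell beyond the outermost centres
    ex_lo, ex_hi = ex[0] - dex[0] / 2, ex[-1] + dex[-1] / 2
    em_lo, em_hi = em[0] - dem[0] / 2, em[-1] + dem[-1] / 2

    volumes = np.empty(len(zones))
    for i, z in enumerate(zones.zones):
        if z.ex_min < ex_lo - 1e-9 or z.ex_max > ex_hi + 1e-9 or \
           z.em_min < em_lo - 1e-9 or z.em_max > em_hi + 1e-9:
            raise ValueError(
                f"zone {z.label!r} [{z.ex_min}-{z.ex_max}] x [{z.em_min}-{z.em_max}] nm "
                "lies outside the EEM wavelength coverage"
            )
        in_ex = (ex >= z.ex_min) & (ex <= z.ex_max)
        in_em = (em >= z.em_min) & (em <= z.em_max)
        if not (in_ex.any() and in_em.any()):
            raise ValueError(f"zone {z.label!r} contains no grid cells")
        sub = np.ix_(in_ex, in_em)
        volumes[i] = float(np.sum(intensity[sub] * cell_area[sub]))
    return volumes


def normalize_zone_volumes(
    raw_volumes: np.ndarray, toc_sample: float, zones: ZoneSet
) -> np.ndarray:
    """TOC- and area-normalized zone volumes.

    Vf_i = Vf_raw_i / TOC_sample × 1 / (S_i / ΣS_i)

    dividing by the supernatant TOC concentration removes the trivial
    dependence on how much carbon was extracted, and the relative-area
    weight removes the dependence on how large each zone's rectangle is.
    """
    raw = np.asarray(raw_volumes, dtype=float)
    if toc_sample is None or toc_sample <= 0:
        raise ValueError("toc_sample must be > 0 for normalization")
    areas = zones.areas
    if np.any(areas <= 0):
        raise ValueError("every zone area S_i must be > 0")
    if raw.shape != areas.shape:
        raise ValueError("raw volume count does not match the zone set")
    rel_area = areas / areas.sum()
    return raw / toc_sample / rel_area


def fluorescence_proportions(vf: np.ndarray) -> np.ndarray:
    """Percentage share of each zone: Pf_i = Vf_i / ΣVf × 100."""
    vf = np.asarray(vf, dtype=float)
    if np.any(vf < 0):
        raise ValueError("normalized volumes must be non-negative")
    total = vf.sum()
    if total <= 0:
        raise ValueError("all zone volumes are zero; proportions undefined")
    return vf / total * 100.0


def fluorescence_profile(
    fraction_label: str,
    eem: EEM,
    zones: ZoneSet,
    scatter_mask: ScatterMask | None = None,
) -> FluorescenceProfile:
    """Full chain EEM → raw volumes → Vf → Pf for one fraction supernatant."""
    raw = integrate_eem_zones(eem, zones, scatter_mask)
    vf = normalize_zone_volumes(raw, eem.toc_sample, zones)
    pf = fluorescence_proportions(vf)
    return FluorescenceProfile(fraction_label=fraction_label, vf=vf, pf=pf)


# ---------------------------------------------------------------------------
# carbon apportionment & stability statistic
# ---------------------------------------------------------------------------


def apportion_carbon(
    om_tc: float,
    toc_by_fraction: dict[str, float],
    tc_residue: float,
    residue_by_difference: bool = False,
) -> tuple[np.ndarray, float]:
    """Apportionment of carbon (AC, %) across the five fractions.

    AC_f = carbon of fraction f / OM_TC × 100, with the four supernatant
    TOCs for SPOM..PEOM and the measured residue TC for NEOM.  Returns the
    five AC values in canonical order plus the closure (their sum, %): a
    closure far from 100% flags a carbon-balance problem in the extraction.

    With ``residue_by_difference`` the NEOM carbon is instead inferred as
    OM_TC minus the sum of the extractable fractions (closure then 100 by
    construction).
    """
    if om_tc is None or om_tc <= 0:
        raise ValueError("om_tc must be > 0")
    try:
        frac = np.array([toc_by_fraction[f] for f in FRACTIONS], dtype=float)
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"missing fraction {e.args[0]!r} in toc_by_fraction") from e
    if residue_by_difference:
        tc_residue = max(om_tc - frac.sum(), 0.0)
    if np.any(frac < 0) or tc_residue < 0:
        raise ValueError("fraction carbon contents must be non-negative")
    carbon = np.append(frac, tc_residue)
    ac = carbon / om_tc * 100.0
    closure = float(ac.sum())
    lo, hi = AC_CLOSURE_BAND
    if not (lo <= closure <= hi):
        warnings.warn(
            f"AC closure {closure:.1f}% outside [{lo}, {hi}]%", stacklevel=2
        )
    return ac, closure


def net_co2(series: IncubationSeries) -> np.ndarray:
    """Net cumulative CO₂-C curve: amended minus control, elementwise.

    Negative values (control respiring more than the amended soil) are kept
    and reported with a warning — the underlying assumption is that any
    priming effect is either absent or comparable across substrates, so
    sign information must not be silently discarded.
    """
    net = series.co2_amended - series.co2_control
    if np.any(net < 0):
        warnings.warn(
            "net CO2 production is negative at some sampling days "
            "(control above amended); values kept unclipped",
            stacklevel=2,
        )
    return net


def compute_cnm(net_final: float, tc_added: float) -> float:
    """Non-mineralized carbon C_nm (%) at the end of the incubation.

    C_nm = (TC_added − net CO₂-C released) / TC_added × 100.
    """
    if tc_added is None or tc_added <= 0:
        raise ValueError("tc_added must be > 0")
    return (tc_added - net_final) / tc_added * 100.0


def cnm_from_series(series: IncubationSeries) -> float:
    """C_nm computed at the last incubation day present in the series."""
    net = net_co2(series)
    return compute_cnm(float(net[-1]), series.tc_added)


def assemble_features(
    fraction_profile: FractionProfile,
    fluorescence: dict[str, FluorescenceProfile],
) -> np.ndarray:
    """Assemble the 34-variable vector (OM_TC, 5 AC, 4 × 7 Pf)."""
    missing = [f for f in FRACTIONS if f not in fluorescence]
    if missing:
        raise ValueError(f"missing fluorescence profiles for fractions {missing}")
    parts = [np.array([fraction_profile.om_tc]), np.asarray(fraction_profile.ac)]
    for f in FRACTIONS:
        prof = fluorescence[f]
        if prof.pf.size != len(ZONE_LABELS):
            raise ValueError(
                f"fraction {f}: expected {len(ZONE_LABELS)} Pf values, got {prof.pf.size}"
            )
        parts.append(prof.pf)
    return np.concatenate(parts)
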