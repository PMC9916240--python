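"""Readers and writers for the package's tabular formats.

All files are UTF-8, comma-separated, dot-decimal CSV with a header row;
units are fixed by schema (mg C g⁻¹ DM for carbon contents, % for AC/Pf
and C_nm, days for durations, nm for wavelengths).  Schema violations
raise :class:`SchemaError` naming the offending row/column.  A missing
C_nm is encoded as an empty cell (e.g. material never incubated).

Schemas
-------
feature table
    ``sample_id, group, route, hrt_days, dc_days, cnm,`` then the 34
    feature columns in canonical order (``OM_TC``, the 5 ``*_AC``, the 28
    ``*_Pf_*``).
pair table
    ``kind (AD|compost), input_id, output_id, duration_days``.
measurement table
    one row per sample × fraction: ``sample_id, fraction
    (SPOM|REOM|SEOM|PEOM|NEOM|TOTAL), carbon_mg_per_gDM,
    toc_supernatant_mg_per_L``.
EEM matrix
    first row: emission wavelengths (nm); first column: excitation
    wavelengths (nm); body: intensities (U.A.).
incubation table
    ``sample_id, day, co2_amended, co2_control, tc_added`` (cumulative
    CO₂-C, mg C g⁻¹ DM).
zone table
    YAML (``zones: [{label, ex_min, ex_max, em_min, em_max}, ...]``) or
    CSV with the same columns.
"""
from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .characterize import (
    FEATURE_NAMES,
    FRACTIONS,
    EEM,
    FractionProfile,
    IncubationSeries,
    SampleRecord,
    Zone,
    ZoneSet,
)
from .dataset import StudyDataset, TreatmentPair

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "RunConfig",
    "default_zones",
    "read_zones",
    "read_eem",
    "read_measurements",
    "read_incubation",
    "read_feature_table",
    "write_feature_table",
    "read_pair_table",
    "write_pair_table",
    "read_study",
    "write_study",
]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# zones & EEM
# ---------------------------------------------------------------------------


def default_zones() -> ZoneSet:
    """The package's default 7-zone table (see data/default_zones.yaml)."""
    ref = importlib.resources.files("omstab") / "data" / "default_zones.yaml"
    return _zones_from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


def _zones_from_mapping(doc: dict) -> ZoneSet:
    try:
        zones = [
            Zone(
                label=str(z["label"]),
                ex_min=float(z["ex_min"]),
                ex_max=float(z["ex_max"]),
                em_min=float(z["em_min"]),
                em_max=float(z["em_max"]),
            )
            for z in doc["zones"]
        ]
    except (KeyError, TypeError) as e:
        raise SchemaError(f"zone table: malformed entry ({e})") from e
    return ZoneSet(zones)


def read_zones(path) -> ZoneSet:
    """Zone table from YAML or CSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        return _zones_from_mapping(yaml.safe_load(path.read_text(encoding="utf-8")))
    df = pd.read_csv(path)
    _require_columns(df, ["label", "ex_min", "ex_max", "em_min", "em_max"], path)
    return _zones_from_mapping({"zones": df.to_dict("records")})


def read_eem(path, toc_sample: float | None = None) -> EEM:
    """EEM matrix CSV: first row emission nm, first column excitation nm."""
    df = pd.read_csv(path, index_col=0)
    try:
        em = df.columns.to_numpy(dtype=float)
        ex = df.index.to_numpy(dtype=float)
        intensity = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise SchemaError(f"{path}: non-numeric wavelength or intensity ({e})") from e
    return EEM(ex_wavelengths=ex, em_wavelengths=em, intensity=intensity,
               toc_sample=toc_sample)


# ---------------------------------------------------------------------------
# measurement / incubation tables
# ---------------------------------------------------------------------------

_MEAS_COLS = ["sample_id", "fraction", "carbon_mg_per_gDM", "toc_supernatant_mg_per_L"]
_VALID_FRACTIONS = set(FRACTIONS) | {"NEOM", "TOTAL"}


def read_measurements(path) -> dict[str, FractionProfile]:
    """Per-fraction carbon table → one :class:`FractionProfile` per sample."""
    df = pd.read_csv(path)
    _require_columns(df, _MEAS_COLS, path)
    dup = df.duplicated(subset=["sample_id", "fraction"])
    if dup.any():
        rows = (df[dup].index + 2).tolist()  # 1-based incl. header
        raise SchemaError(f"{path}: duplicate sample_id+fraction at row(s) {rows}")
    bad = ~df["fraction"].isin(_VALID_FRACTIONS)
    if bad.any():
        raise SchemaError(
            f"{path}: unknown fraction {df.loc[bad, 'fraction'].iloc[0]!r} "
            f"at row {int(df.index[bad][0]) + 2}"
        )
    profiles: dict[str, FractionProfile] = {}
    for sid, sub in df.groupby("sample_id", sort=True):
        by_frac = dict(zip(sub["fraction"], sub["carbon_mg_per_gDM"]))
        missing = [f for f in (*FRACTIONS, "NEOM", "TOTAL") if f not in by_frac]
        if missing:
            raise SchemaError(f"{path}: sample {sid!r} missing fraction row(s) {missing}")
        try:
            profiles[str(sid)] = FractionProfile(
                om_tc=float(by_frac["TOTAL"]),
                toc_by_fraction={f: float(by_frac[f]) for f in FRACTIONS},
                tc_residue=float(by_frac["NEOM"]),
            )
        except ValueError as e:
            raise SchemaError(f"{path}: sample {sid!r}: {e}") from e
    return profiles


def read_incubation(path) -> dict[str, IncubationSeries]:
    """Incubation CO₂ table → one series per sample."""
    df = pd.read_csv(path)
    _require_columns(
        df, ["sample_id", "day", "co2_amended", "co2_control", "tc_added"], path
    )
    out: dict[str, IncubationSeries] = {}
    for sid, sub in df.groupby("sample_id", sort=True):
        sub = sub.sort_values("day")
        tc = sub["tc_added"].unique()
        if len(tc) != 1:
            raise SchemaError(f"{path}: sample {sid!r} has inconsistent tc_added")
        try:
            out[str(sid)] = IncubationSeries(
                days=sub["day"].to_numpy(float),
                co2_amended=sub["co2_amended"].to_numpy(float),
                co2_control=sub["co2_control"].to_numpy(float),
                tc_added=float(tc[0]),
            )
        except ValueError as e:
            raise SchemaError(f"{path}: sample {sid!r}: {e}") from e
    return out


# ---------------------------------------------------------------------------
# feature & pair tables (the schemas the synthetic generator emits)
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "group", "route", "hrt_days", "dc_days", "cnm"]


def write_feature_table(dataset: StudyDataset, path) -> None:
    rows = []
    for sid in sorted(dataset.samples):
        r = dataset.samples[sid]
        row = {
            "sample_id": r.sample_id,
            "group": r.group_label or "",
            "route": r.route,
            "hrt_days": r.hrt_days,
            "dc_days": r.dc_days,
            "cnm": dataset.cnm.get(sid),
        }
        row.update(dict(zip(FEATURE_NAMES, r.features)))
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLS + list(FEATURE_NAMES)).to_csv(
        path, index=False
    )


def read_feature_table(path) -> StudyDataset:
    # round_trip parsing so write -> read -> write is byte-identical
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["sample_id", "route"] + list(FEATURE_NAMES), path)
    ds = StudyDataset()
    for i, row in df.iterrows():
        try:
            features = row[list(FEATURE_NAMES)].to_numpy(dtype=float)
        except (TypeError, ValueError) as e:
            raise SchemaError(f"{path}: row {i + 2}: non-numeric feature ({e})") from e
        if np.isnan(features).any():
            j = list(FEATURE_NAMES)[int(np.nonzero(np.isnan(features))[0][0])]
            raise SchemaError(f"{path}: row {i + 2}: missing value in column {j!r}")
        rec = SampleRecord(
            sample_id=str(row["sample_id"]),
            features=features,
            group_label=str(row["group"]) if "group" in df.columns and pd.notna(row.get("group")) and row.get("group") != "" else None,
            route=str(row["route"]),
            hrt_days=float(row["hrt_days"]) if pd.notna(row.get("hrt_days")) else None,
            dc_days=float(row["dc_days"]) if pd.notna(row.get("dc_days")) else None,
        )
        cnm = row.get("cnm")
        ds.add(rec, cnm=float(cnm) if pd.notna(cnm) else None)
        for issue in rec.validate(pf_tol=1e-6):
            logger.warning(issue)
    return ds


def write_pair_table(dataset: StudyDataset, path) -> None:
    rows = [
        {"kind": kind, "input_id": p.input_id, "output_id": p.output_id,
         "duration_days": p.duration_days}
        for kind, pairs in (("AD", dataset.ad_pairs), ("compost", dataset.compost_pairs))
        for p in pairs
    ]
    pd.DataFrame(rows, columns=["kind", "input_id", "output_id", "duration_days"]).to_csv(
        path, index=False
    )


def read_pair_table(path, dataset: StudyDataset) -> StudyDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["kind", "input_id", "output_id", "duration_days"], path)
    for i, row in df.iterrows():
        pair = TreatmentPair(
            input_id=str(row["input_id"]),
            output_id=str(row["output_id"]),
            duration_days=float(row["duration_days"]),
        )
        if row["kind"] == "AD":
            dataset.ad_pairs.append(pair)
        elif row["kind"] == "compost":
            dataset.compost_pairs.append(pair)
        else:
            raise SchemaError(f"{path}: row {i + 2}: unknown pair kind {row['kind']!r}")
    dataset.validate_links()
    return dataset


def write_study(dataset: StudyDataset, directory) -> None:
    """Write a study as ``samples.csv`` + ``pairs.csv`` in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_feature_table(dataset, directory / "samples.csv")
    write_pair_table(dataset, directory / "pairs.csv")


def read_study(directory) -> StudyDataset:
    directory = Path(directory)
    ds = read_feature_table(directory / "samples.csv")
    return read_pair_table(directory / "pairs.csv", ds)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One analysis run, loadable from YAML and echoed into every output."""

    dataset_dir: str
    out_dir: str = "out"
    zone_table: str | None = None
    seed: int = 0
    n_components: dict = field(
        default_factory=lambda: {"AD": 3, "compost": 3, "soil": 3}
    )
    cv_groups: int = 7
    exclude_ids: list[str] = field(default_factory=list)
    holdout_families: list[str] = field(default_factory=list)
    feature_subset: str = "all"

    @classmethod
    def load(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(doc) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        cfg = cls(**doc)
        for p in (cfg.dataset_dir, cfg.zone_table):
            if p is not None and not Path(p).exists():
                raise SchemaError(f"{path}: referenced path does not exist: {p}")
        return cfg

    def to_dict(self) -> dict:
        return {
            "dataset_dir": self.dataset_dir,
            "out_dir": self.out_dir,
            "zone_table": self.zone_table,
            "seed": self.seed,
            "n_components": dict(self.n_components),
            "cv_groups": self.cv_groups,
            "exclude_ids": list(self.exclude_ids),
            "holdout_families": list(self.holdout_families),
            "feature_subset": self.feature_subset,
        }
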