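"""Harmonize technique-specific sub-ROI measurements onto a common master-ROI set.

Morphometry pipelines parcellate the cortex with different atlases, so
comparing them region-by-region first requires collapsing each technique's
sub-regions onto one shared set of master ROIs.  The rules are the
conventional ones for these measure kinds:

* **volume** — constituent volumes (left + right hemisphere, and any
  sub-parcels) are summed, then divided by the subject's total intracranial
  volume (TIV) to remove head-size effects;
* **thickness** — constituent thicknesses are averaged weighted by each
  constituent's surface area (a surface-area-weighted mean is the thickness
  of the merged patch), and are *not* TIV-adjusted, since cortical thickness
  does not scale with head size.

The packaged default map (28 master ROIs, two atlas schemes plus an
all-volume variant of the surface scheme) is a reconstruction from
conventional Desikan/AAL correspondences; supply your own
:class:`ROIMap` CSV to override it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateInputError, MappingError

__all__ = [
    "ROIMap",
    "MeasurementTable",
    "combine_thickness",
    "combine_volume",
    "normalize_tiv",
    "harmonize",
    "default_roi_map",
]

MAP_COLUMNS = ["master_roi", "technique", "sub_roi", "hemisphere", "measure_kind"]


@dataclass(frozen=True)
class ROIMap:
    """Mapping from technique-specific sub-ROIs to master ROIs.

    ``entries`` has columns ``master_roi, technique, sub_roi, hemisphere,
    measure_kind``; within a technique every (sub_roi, hemisphere) belongs to
    exactly one master ROI and every master ROI has a single measure kind.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ConfigError(f"ROIMap entries missing columns: {missing}")
        dup = self.entries.duplicated(["technique", "sub_roi", "hemisphere"])
        if dup.any():
            bad = self.entries.loc[dup, ["technique", "sub_roi", "hemisphere"]]
            raise ConfigError(
                "sub-ROI mapped to more than one master ROI: "
                + ", ".join(map(str, bad.itertuples(index=False, name=None)))
            )
        kinds = self.entries.groupby(["technique", "master_roi"])["measure_kind"].nunique()
        if (kinds > 1).any():
            bad = kinds[kinds > 1].index.tolist()
            raise ConfigError(f"master ROI with mixed measure_kind within a technique: {bad}")
        bad_kind = set(self.entries["measure_kind"]) - {"thickness", "volume"}
        if bad_kind:
            raise ConfigError(f"unknown measure_kind values: {sorted(bad_kind)}")

    @classmethod
    def from_csv(cls, path) -> "ROIMap":
        return cls(pd.read_csv(path))

    def techniques(self) -> list[str]:
        return list(dict.fromkeys(self.entries["technique"]))

    def for_technique(self, technique: str) -> pd.DataFrame:
        sub = self.entries[self.entries["technique"] == technique]
        if sub.empty:
            raise MappingError(f"technique {technique!r} not present in ROI map")
        return sub

    def master_rois(self, technique: str | None = None) -> list[str]:
        ent = self.entries if technique is None else self.for_technique(technique)
        return list(dict.fromkeys(ent["master_roi"]))


def default_roi_map() -> ROIMap:
    """The packaged 28-master-ROI map (reconstructed atlas correspondence key)."""
    ref = importlib.resources.files("roiconcord.datasets") / "master_roi_map.csv"
    with importlib.resources.as_file(ref) as path:
        return ROIMap.from_csv(path)


@dataclass
class MeasurementTable:
    """Subjects x measurement-columns matrix for one technique.

    ``values`` is indexed by subject_id.  ``columns`` describes each column:
    ``sub_roi``, ``hemisphere``, ``kind`` (thickness | volume | area).
    Column names follow ``<sub_roi>_<hemisphere>_<kind>``.
    """

    technique: str
    values: pd.DataFrame
    columns: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.columns is None:
            self.columns = parse_column_names(self.values.columns)
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataError(f"non-finite values in measurement table {self.technique!r}")
        if (self.values.to_numpy(dtype=float) <= 0).any():
            raise DataError(
                f"non-positive measurement in table {self.technique!r}; thickness, "
                "volume and area must be strictly positive"
            )

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, technique: str) -> "MeasurementTable":
        values = pd.read_csv(path, index_col="subject_id")
        return cls(technique=technique, values=values)


def parse_column_names(names) -> pd.DataFrame:
    """Split ``<sub_roi>_<hemisphere>_<kind>`` column names into metadata."""
    rows = []
    for name in names:
        parts = str(name).rsplit("_", 2)
        if len(parts) != 3 or parts[1] not in ("left", "right") or parts[2] not in (
            "thickness",
            "volume",
            "area",
        ):
            raise DataError(
                f"cannot parse measurement column {name!r}; expected "
                "'<sub_roi>_<left|right>_<thickness|volume|area>'"
            )
        rows.append({"column": name, "sub_roi": parts[0], "hemisphere": parts[1], "kind": parts[2]})
    return pd.DataFrame(rows).set_index("column")


def combine_thickness(thicknesses, areas):
    """Surface-area-weighted mean thickness of k constituent patches.

    Generalizes the two-hemisphere rule ``(area_L*thick_L + area_R*thick_R) /
    (area_L + area_R)`` to any number of constituents.  Accepts 1-D vectors
    (one subject) or 2-D arrays (subjects x constituents); reduces the last
    axis.
    """
    thick = np.asarray(thicknesses, dtype=float)
    area = np.asarray(areas, dtype=float)
    if thick.shape != area.shape:
        raise DataError(f"thickness shape {thick.shape} != area shape {area.shape}")
    if thick.size == 0:
        raise DegenerateInputError("empty thickness input")
    if (area < 0).any():
        raise DataError("negative surface area")
    total = area.sum(axis=-1)
    if np.any(total <= 0):
        raise DegenerateInputError("zero total surface area")
    return (thick * area).sum(axis=-1) / total


def combine_volume(volumes):
    """Sum of constituent volumes (last axis)."""
    vol = np.asarray(volumes, dtype=float)
    if vol.size == 0:
        raise DegenerateInputError("empty volume input")
    return vol.sum(axis=-1)


def normalize_tiv(volume, tiv):
    """Divide a volume by total intracranial volume (head-size normalization)."""
    vol = np.asarray(volume, dtype=float)
    t = np.asarray(tiv, dtype=float)
    if np.any(t <= 0):
        raise DataError("TIV must be strictly positive")
    return vol / t


def harmonize(table: MeasurementTable, roi_map: ROIMap, tiv: pd.Series) -> MeasurementTable:
    """Collapse a sub-ROI table onto master ROIs: sum+TIV-normalize volumes,
    area-weight thicknesses.

    ``tiv`` is this technique's per-subject total intracranial volume (mm3),
    indexed by subject_id.  Output is one column per master ROI named
    ``<master_roi>``; thickness masters stay in mm, volume masters become
    dimensionless volume/TIV ratios.
    """
    entries = roi_map.for_technique(table.technique)
    tiv = tiv.reindex(table.subject_ids)
    if tiv.isna().any():
        missing = list(tiv.index[tiv.isna()][:5])
        raise DataError(f"TIV missing for subjects {missing} in table {table.technique!r}")

    out = {}
    missing_cols: list[str] = []
    for master in dict.fromkeys(entries["master_roi"]):
        ent = entries[entries["master_roi"] == master]
        kind = ent["measure_kind"].iloc[0]
        cols = [f"{s}_{h}_{kind}" for s, h in zip(ent["sub_roi"], ent["hemisphere"])]
        absent = [c for c in cols if c not in table.values.columns]
        if absent:
            missing_cols.extend(absent)
            continue
        block = table.values[cols].to_numpy(dtype=float)
        if kind == "volume":
            out[master] = normalize_tiv(combine_volume(block), tiv.to_numpy())
        else:
            area_cols = [f"{s}_{h}_area" for s, h in zip(ent["sub_roi"], ent["hemisphere"])]
            absent_area = [c for c in area_cols if c not in table.values.columns]
            if absent_area:
                raise MappingError(
                    f"master ROI {master!r}: missing surface-area columns {absent_area}"
                )
            areas = table.values[area_cols].to_numpy(dtype=float)
            out[master] = combine_thickness(block, areas)
    if missing_cols:
        raise MappingError(f"measurement columns missing for table {table.technique!r}: {missing_cols}")

    values = pd.DataFrame(out, index=table.subject_ids)
    kinds = entries.drop_duplicates("master_roi").set_index("master_roi")["measure_kind"]
    columns = pd.DataFrame(
        {
            "sub_roi": values.columns,
            "hemisphere": "both",
            "kind": kinds.reindex(values.columns).to_numpy(),
        },
        index=pd.Index(values.columns, name="column"),
    )
    return MeasurementTable(technique=table.technique, values=values, columns=columns)
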