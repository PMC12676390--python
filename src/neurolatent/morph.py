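"""FreeSurfer-style anatomical-stats parsing and the morphometric feature block.

Nine sensorimotor/language Brodmann areas (BA1, BA2, BA3a, BA3b, BA4a, BA4p,
BA6, BA44, BA45) x four metrics (surface area, gray volume, mean thickness,
thickness SD) give the canonical 36-column table. No intracranial-volume
correction is applied. The pairwise screening conventionally uses only
{area, vol, thick_avg} (27 columns); the latent model uses all 36.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MorphRegion",
    "DEFAULT_REGIONS",
    "MORPH_METRICS",
    "SCREENING_METRICS",
    "MissingRegionError",
    "parse_anat_stats",
    "build_morph_features",
    "morph_feature_names",
    "screening_columns",
    "validate_features",
    "write_feature_table",
    "read_feature_table",
]

DEFAULT_REGIONS = ("BA1", "BA2", "BA3a", "BA3b", "BA4a", "BA4p", "BA6", "BA44", "BA45")
MORPH_METRICS = ("area", "vol", "thick_avg", "thick_sd")
SCREENING_METRICS = ("area", "vol", "thick_avg")

# FreeSurfer anatomical-stats column -> our metric name
_COLUMN_MAP = {
    "SurfArea": "area",
    "GrayVol": "vol",
    "ThickAvg": "thick_avg",
    "ThickStd": "thick_sd",
}


class MissingRegionError(ValueError):
    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"requested regions missing from stats file: {', '.join(missing)}")


@dataclass(frozen=True)
class MorphRegion:
    label: str
    area: float
    vol: float
    thick_avg: float
    thick_sd: float

    def __post_init__(self):
        for m in MORPH_METRICS:
            if getattr(self, m) < 0:
                raise ValueError(f"{self.label}: {m} must be nonnegative")
        if not (0 < self.thick_avg < 10):
            raise ValueError(f"{self.label}: mean thickness {self.thick_avg} mm outside (0, 10)")


def parse_anat_stats(path: str | Path, regions: tuple[str, ...] = DEFAULT_REGIONS) -> list[MorphRegion]:
    """Parse a FreeSurfer anatomical-stats table into the requested regions.

    Comment lines start with '#'; the '# ColHeaders' line names the whitespace
    delimited data columns (StructName, SurfArea, GrayVol, ThickAvg, ThickStd
    are required). Region labels match with or without an '_exvivo' suffix;
    extra rows are ignored.
    """
    text = Path(path).read_text()
    headers: list[str] | None = None
    rows: list[list[str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("ColHeaders"):
                headers = body.split()[1:]
            continue
        rows.append(line.split())
    if headers is None:
        raise ValueError(f"{path}: no '# ColHeaders' line; not an anatomical-stats table")
    required = ["StructName", *_COLUMN_MAP]
    missing_cols = [c for c in required if c not in headers]
    if missing_cols:
        raise ValueError(f"{path}: malformed header, missing columns {missing_cols}")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    col = {name: headers.index(name) for name in required}
    by_label: dict[str, MorphRegion] = {}
    for parts in rows:
        if len(parts) != len(headers):
            raise ValueError(f"{path}: row with {len(parts)} fields, expected {len(headers)}")
        label = parts[col["StructName"]].removesuffix("_exvivo")
        if label not in regions:
            continue
        by_label[label] = MorphRegion(
            label=label,
            area=float(parts[col["SurfArea"]]),
            vol=float(parts[col["GrayVol"]]),
            thick_avg=float(parts[col["ThickAvg"]]),
            thick_sd=float(parts[col["ThickStd"]]),
        )
    missing = [r for r in regions if r not in by_label]
    if missing:
        raise MissingRegionError(missing)
    return [by_label[r] for r in regions]


def morph_feature_names(
    regions: tuple[str, ...] = DEFAULT_REGIONS, metrics: tuple[str, ...] = MORPH_METRICS
) -> list[str]:
    """Canonical column order ``<region>.<metric>``."""
    return [f"{r}.{m}" for r in regions for m in metrics]


def screening_columns(columns=None) -> list[str]:
    """The 27-column {area, vol, thick_avg} subset used by the pairwise screen."""
    names = [f"{r}.{m}" for r in DEFAULT_REGIONS for m in SCREENING_METRICS]
    if columns is not None:
        names = [c for c in names if c in set(columns)]
    return names


def _region_series(regions: list[MorphRegion]) -> pd.Series:
    vals = {f"{r.label}.{m}": getattr(r, m) for r in regions for m in MORPH_METRICS}
    return pd.Series(vals, dtype=float)


def build_morph_features(
    subjects: dict[str, list[MorphRegion] | tuple[list[MorphRegion], list[MorphRegion]]],
    regions: tuple[str, ...] = DEFAULT_REGIONS,
    hemispheres: str = "average",
) -> pd.DataFrame:
    """Canonical subjects x 36 table; hemisphere pairs are averaged by default.

    Values pass through without ICV scaling. Subjects must share the same
    region set; a tuple of two parsed lists is treated as (left, right).
    """
    rows = {}
    expected = set(morph_feature_names(regions))
    for subject, parsed in subjects.items():
        if isinstance(parsed, tuple):
            if hemispheres == "left":
                series = _region_series(parsed[0])
            elif hemispheres == "right":
                series = _region_series(parsed[1])
            else:
                series = pd.concat(
                    [_region_series(parsed[0]), _region_series(parsed[1])], axis=1
                ).mean(axis=1)
        else:
            series = _region_series(parsed)
        if set(series.index) != expected:
            raise ValueError(f"subject {subject}: inconsistent region set")
        rows[subject] = series
    table = pd.DataFrame(rows).T[morph_feature_names(regions)]
    table.index.name = "subject"
    return table


def validate_features(table: pd.DataFrame) -> dict:
    """Report zero-variance and missing-value columns (kept, but flagged)."""
    zero_var = [c for c in table.columns if table[c].std(skipna=True) == 0 or table[c].count() <= 1]
    with_missing = [c for c in table.columns if table[c].isna().any()]
    return {"zero_variance": zero_var, "missing": with_missing, "n_subjects": len(table)}


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
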