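"""Data model and I/O for administrative radiotherapy treatment records.

A record set is a :class:`pandas.DataFrame` with one row per daily treatment
fraction. The canonical columns are listed in :data:`CANONICAL_COLUMNS`;
``patient_id`` and ``treat_date`` are required, everything else may be
missing on a per-cell basis (missingness is the norm in these data, and the
classifier cascade is the strategy for dealing with it — see
:mod:`radrole.cascade`).

Controlled vocabularies
-----------------------
Disease sites are 3-digit ICD-9 codes (140-208 for malignant neoplasms)
grouped into site groups by anatomic region; irradiated body-regions are
verbatim descriptions coded into body-region groups. Both grouping maps are
shipped as editable CSV files under ``radrole/data`` and loaded with
:func:`load_grouping_maps`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CURATIVE = "C"
PALLIATIVE = "P"

#: canonical column order for a record set
CANONICAL_COLUMNS = [
    "patient_id",
    "cancer_id",
    "centre",
    "treat_date",
    "fraction_size",
    "body_region_group",
    "site_group",
    "technique",
    "intent_raw",
]

REQUIRED_COLUMNS = ["patient_id", "treat_date"]

#: classification variables usable by the tree inducer
CLASSIFICATION_VARIABLES = [
    "fraction_size",
    "site_group",
    "body_region_group",
    "days_from_first",
]

#: sentinel returned for ICD-9 codes outside every configured site group
UNGROUPED = "ungrouped"

#: default vocabulary mapping recorded intent strings to the binary flag
DEFAULT_INTENT_VOCAB = {
    "curative": CURATIVE,
    "radical": CURATIVE,
    "adjuvant": CURATIVE,
    "palliative": PALLIATIVE,
}


class ConfigurationError(ValueError):
    """A schema/configuration problem (e.g. a required column is absent)."""


class RecordParseError(ValueError):
    """A required field failed to parse; carries the offending row indices."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(f"{message} (rows: {rows})")
        self.rows = rows


# ---------------------------------------------------------------------------
# grouping maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupingMaps:
    """Controlled vocabularies for site and body-region grouping.

    ``site_map`` maps each site-group label to a frozenset of 3-digit ICD-9
    codes (pairwise disjoint across groups); ``body_region_map`` maps
    lower-cased verbatim region descriptions to body-region-group labels.
    """

    site_map: dict[str, frozenset[int]]
    body_region_map: dict[str, str]
    _code_index: dict[int, str] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        index: dict[int, str] = {}
        for group, codes in self.site_map.items():
            for code in codes:
                if code in index:
                    raise ConfigurationError(
                        f"ICD-9 code {code} assigned to both {index[code]!r} and {group!r}"
                    )
                index[code] = group
        object.__setattr__(self, "_code_index", index)

    @property
    def site_groups(self) -> list[str]:
        return list(self.site_map)

    @property
    def body_region_groups(self) -> list[str]:
        return sorted(set(self.body_region_map.values()))


def _parse_code_ranges(spec: str) -> frozenset[int]:
    codes: set[int] = set()
    spec = spec.strip()
    if not spec:
        return frozenset()
    for part in spec.split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-")
            codes.update(range(int(lo), int(hi) + 1))
        else:
            codes.add(int(part))
    return frozenset(codes)


def _data_path(name: str) -> Path:
    return Path(resources.files("radrole").joinpath("data", name))


def load_grouping_maps(
    site_path: str | Path | None = None,
    body_region_path: str | Path | None = None,
) -> GroupingMaps:
    """Load the site and body-region grouping maps (packaged defaults)."""
    site_df = pd.read_csv(site_path or _data_path("site_groups.csv"), keep_default_na=False)
    site_map = {
        row.site_group: _parse_code_ranges(str(row.icd9_codes))
        for row in site_df.itertuples()
    }
    region_df = pd.read_csv(
        body_region_path or _data_path("body_region_synonyms.csv"), keep_default_na=False
    )
    body_region_map = {
        str(row.verbatim).strip().lower(): row.body_region_group
        for row in region_df.itertuples()
    }
    return GroupingMaps(site_map=site_map, body_region_map=body_region_map)


def group_disease_site(icd9_code, maps: GroupingMaps | None = None) -> str:
    """Map an ICD-9 primary-site code to its site-group label.

    Sub-codes (e.g. ``1628`` or ``"162.8"``) truncate to their 3-digit
    parent. Codes outside every configured group return :data:`UNGROUPED`.
    """
    if maps is None:
        maps = load_grouping_maps()
    code = str(icd9_code).strip().split(".")[0]
    code = int(float(code))
    while code > 999:
        code //= 10
    return maps._code_index.get(code, UNGROUPED)


# ---------------------------------------------------------------------------
# intent handling
# ---------------------------------------------------------------------------

_warned_intents: set[str] = set()


def binarize_intent(intent_raw, mapping: dict[str, str] | None = None):
    """Collapse a recorded intent string to the binary flag C/P.

    Unmapped values become missing (``None``) with a logged warning; missing
    input passes through.
    """
    if mapping is None:
        mapping = DEFAULT_INTENT_VOCAB
    if intent_raw is None or (isinstance(intent_raw, float) and np.isnan(intent_raw)):
        return None
    key = str(intent_raw).strip().lower()
    if not key:
        return None
    if key in (CURATIVE.lower(), PALLIATIVE.lower(), CURATIVE, PALLIATIVE):
        return key.upper()
    mapped = {k.strip().lower(): v for k, v in mapping.items()}.get(key)
    if mapped is None:
        if key not in _warned_intents:
            logger.warning("unmapped intent value %r -> missing", intent_raw)
            _warned_intents.add(key)
        return None
    if mapped not in (CURATIVE, PALLIATIVE):
        raise ConfigurationError(f"intent mapping must target C/P, got {mapped!r}")
    return mapped


def binarize_intent_column(series: pd.Series, mapping=None) -> pd.Series:
    out = series.map(lambda v: binarize_intent(v, mapping))
    return out.astype(object).where(out.notna(), None)


# ---------------------------------------------------------------------------
# treatment-date arithmetic
# ---------------------------------------------------------------------------


def compute_days_from_first(records: pd.DataFrame) -> pd.DataFrame:
    """Attach ``days_from_first``: whole days since the first treatment for
    the same cancer (grouping key ``cancer_id``, falling back to
    ``patient_id``). Rows with a missing date get a missing value; result is
    independent of row order.
    """
    df = records.copy()
    if len(df) == 0:
        df["days_from_first"] = pd.Series(dtype=float)
        return df
    key = "cancer_id" if "cancer_id" in df.columns else "patient_id"
    dates = pd.to_datetime(df["treat_date"])
    first = dates.groupby(df[key]).transform("min")
    df["days_from_first"] = (dates - first).dt.days.astype(float)
    return df


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def _load_schema(schema_config) -> dict[str, str]:
    if schema_config is None:
        return {}
    if isinstance(schema_config, dict):
        return dict(schema_config)
    path = Path(schema_config)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return dict(yaml.safe_load(text))
    return dict(json.loads(text))


def read_records(path, schema_config=None) -> pd.DataFrame:
    """Read a record set from CSV.

    ``schema_config`` maps canonical column names to the file's column names
    (dict, or path to a JSON/YAML file). Unparseable optional fields become
    missing; an unparseable required date raises :class:`RecordParseError`
    with the offending row indices; a missing required column raises
    :class:`ConfigurationError` naming it.
    """
    schema = _load_schema(schema_config)
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    out = pd.DataFrame(index=raw.index)
    consumed = []
    for canon in CANONICAL_COLUMNS:
        source = schema.get(canon, canon)
        if source in raw.columns:
            out[canon] = raw[source]
            consumed.append(source)
        elif canon in REQUIRED_COLUMNS:
            raise ConfigurationError(
                f"required column {canon!r} (mapped from {source!r}) not found in {path}"
            )
        else:
            out[canon] = None
    # passthrough columns (identifiers, annotations) are preserved verbatim
    for col in raw.columns:
        if col not in consumed and col not in out.columns:
            out[col] = raw[col]
    dates = pd.to_datetime(out["treat_date"], errors="coerce", format="ISO8601")
    bad = out.index[dates.isna() & out["treat_date"].notna()].tolist()
    missing_date = out.index[out["treat_date"].isna()].tolist()
    if bad or missing_date:
        raise RecordParseError("unparseable or missing treat_date", bad + missing_date)
    out["treat_date"] = dates.dt.normalize()
    fs = pd.to_numeric(out["fraction_size"], errors="coerce")
    nonpos = fs <= 0
    if nonpos.any():
        logger.warning("%d non-positive fraction_size values set to missing", int(nonpos.sum()))
    out["fraction_size"] = fs.where(~nonpos)
    if out["cancer_id"].isna().all():
        out["cancer_id"] = out["patient_id"]
    for col in ("body_region_group", "site_group", "technique", "intent_raw", "centre"):
        out[col] = out[col].astype(object).where(out[col].notna(), None)
    return out


def write_records(records: pd.DataFrame, path) -> None:
    """Write a record set to CSV (ISO dates, empty cells for missing)."""
    df = records.copy()
    if "treat_date" in df.columns:
        df["treat_date"] = pd.to_datetime(df["treat_date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def prepare_records(
    records: pd.DataFrame,
    maps: GroupingMaps | None = None,
    intent_mapping: dict[str, str] | None = None,
    icd9_column: str | None = None,
) -> pd.DataFrame:
    """Derive the classification variables on a raw record set.

    Adds ``intent_flag`` (binary C/P or missing) and ``days_from_first``;
    fills ``site_group`` from an ICD-9 column if one is named and the group
    is absent; maps verbatim body-region descriptions through the grouping
    map when they are not already group labels.
    """
    df = records.copy()
    if maps is None:
        maps = load_grouping_maps()
    if icd9_column and icd9_column in df.columns:
        need = df["site_group"].isna() if "site_group" in df.columns else pd.Series(True, index=df.index)
        codes = df.loc[need & df[icd9_column].notna(), icd9_column]
        df.loc[codes.index, "site_group"] = codes.map(lambda c: group_disease_site(c, maps))
    if "body_region_group" in df.columns:
        known = set(maps.body_region_map.values())

        def _map_region(v):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            if v in known:
                return v
            return maps.body_region_map.get(str(v).strip().lower())

        df["body_region_group"] = df["body_region_group"].map(_map_region)
    df["intent_flag"] = binarize_intent_column(df["intent_raw"], intent_mapping)
    df = compute_days_from_first(df)
    return df


# ---------------------------------------------------------------------------
# reference profile of the classification variables
# ---------------------------------------------------------------------------


def table1_profile() -> pd.DataFrame:
    """Printed curative/palliative profile of the classification variables
    in the Ontario 2005-2008 reference analysis (counts and printed integer
    percentages per body-region and site group). Shipped as package data;
    used for generator defaults and worked-example checks.
    """
    return pd.read_csv(_data_path("table1_profile.csv"))


def recompute_profile_percentages(profile: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute integer percentages from the profile's printed count pairs."""
    df = (profile if profile is not None else table1_profile()).copy()
    total = df["n_curative"] + df["n_palliative"]
    df["computed_pct_curative"] = (100.0 * df["n_curative"] / total).round().astype(int)
    df["computed_pct_palliative"] = (100.0 * df["n_palliative"] / total).round().astype(int)
    return df
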