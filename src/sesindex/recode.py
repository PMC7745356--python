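"""Dichotomization of raw housing/asset survey responses.

Every candidate item is recoded to 0/1 with 1 indicating the higher-SES
state (the household has the item / the improved condition). Three item
types are supported: ``categorical`` (explicit category -> {0,1} map),
``count`` (threshold rule on a nonnegative count, e.g. rooms >= 2), and
``binary`` (yes/no style raw values). Raw missing values stay missing;
unmapped categories are rejected, never coerced.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dataset import ResponseDataset

DEFAULT_MAP_RESOURCE = "default_recode_map.yaml"

_BINARY_TRUE = {"1", "yes", "y", "true"}
_BINARY_FALSE = {"0", "no", "n", "false"}
_COUNT_OPS = {
    "ge": lambda x, v: x >= v,
    "gt": lambda x, v: x > v,
    "le": lambda x, v: x <= v,
    "lt": lambda x, v: x < v,
}


class RecodeMapError(ValueError):
    """Raised when a recode map fails schema validation."""


class RecodeError(ValueError):
    """Raised when raw data contain values the map cannot resolve."""


@dataclass
class RecodeItem:
    name: str
    source: str
    type: str
    mapping: dict[str, int] = field(default_factory=dict)
    rule: dict | None = None


@dataclass
class RecodeMap:
    """Validated collection of per-item dichotomization rules."""

    items: dict[str, RecodeItem]

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_names(self) -> list[str]:
        return list(self.items)


def _validate_item(name: str, spec: dict) -> RecodeItem:
    if not isinstance(spec, dict) or "type" not in spec:
        raise RecodeMapError(f"item {name!r}: entry must declare a type")
    kind = spec["type"]
    source = spec.get("source", name)
    if kind == "categorical":
        mapping = spec.get("map")
        if not mapping:
            raise RecodeMapError(f"item {name!r}: categorical item needs a 'map'")
        for cat, val in mapping.items():
            if val not in (0, 1):
                raise RecodeMapError(
                    f"item {name!r}: category {cat!r} maps to {val!r}, expected 0 or 1"
                )
        return RecodeItem(name, source, kind, {str(k): int(v) for k, v in mapping.items()})
    if kind == "count":
        rule = spec.get("rule")
        if not rule or rule.get("op") not in _COUNT_OPS or "value" not in rule:
            raise RecodeMapError(
                f"item {name!r}: count item needs rule {{op: ge|gt|le|lt, value: n}}"
            )
        return RecodeItem(name, source, kind, rule=dict(rule))
    if kind == "binary":
        return RecodeItem(name, source, kind)
    raise RecodeMapError(f"item {name!r}: unknown type {kind!r}")


def _map_from_mapping(raw: dict) -> RecodeMap:
    if not raw or "items" not in raw or not raw["items"]:
        raise RecodeMapError("recode map is empty or lacks an 'items' section")
    return RecodeMap({name: _validate_item(name, spec) for name, spec in raw["items"].items()})


def load_recode_map(path) -> RecodeMap:
    """Load and validate a recode map from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise RecodeMapError(f"recode map file {path!r} is empty")
    return _map_from_mapping(raw)


def default_recode_map() -> RecodeMap:
    """The packaged map covering the 16 candidate index items."""
    ref = importlib.resources.files("sesindex") / "data" / DEFAULT_MAP_RESOURCE
    return _map_from_mapping(yaml.safe_load(ref.read_text()))


def _recode_column(raw: pd.Series, item: RecodeItem) -> pd.Series:
    out = pd.Series(np.nan, index=raw.index, dtype=float)
    observed = raw.notna()
    if item.type == "count":
        values = pd.to_numeric(raw[observed], errors="coerce")
        if values.isna().any():
            bad = raw[observed][values.isna()]
            raise RecodeError(
                f"item {item.name!r}: non-numeric count value {bad.iloc[0]!r} "
                f"at row {bad.index[0]}"
            )
        op = _COUNT_OPS[item.rule["op"]]
        out[observed] = op(values, item.rule["value"]).astype(float)
        return out

    if item.type == "binary" and pd.api.types.is_numeric_dtype(raw):
        values = raw[observed].astype(float)
        bad = ~values.isin([0.0, 1.0])
        if bad.any():
            raise RecodeError(
                f"item {item.name!r}: unmapped value {values[bad].iloc[0]!r} "
                f"at row {values[bad].index[0]}"
            )
        out[observed] = values
        return out

    text = raw[observed].astype(str).str.strip()
    if item.type == "binary":
        lowered = text.str.lower()
        ones = lowered.isin(_BINARY_TRUE)
        zeros = lowered.isin(_BINARY_FALSE)
        unknown = ~(ones | zeros)
        if unknown.any():
            bad = text[unknown]
            raise RecodeError(
                f"item {item.name!r}: unmapped value {bad.iloc[0]!r} at row {bad.index[0]}"
            )
        out[observed] = ones.astype(float)
        return out

    mapped = text.map(item.mapping)
    if mapped.isna().any():
        bad = text[mapped.isna()]
        raise RecodeError(
            f"item {item.name!r}: unmapped category {bad.iloc[0]!r} at row {bad.index[0]}"
        )
    out[observed] = mapped.astype(float)
    return out


def dichotomize(raw: pd.DataFrame, recode_map: RecodeMap) -> ResponseDataset:
    """Recode a raw response table into a binary :class:`ResponseDataset`.

    Only map items whose source column is present are produced; missing
    raw values propagate as missing. Carries through ``id``, ``site``,
    and any covariate columns unchanged.
    """
    produced = {}
    for name, item in recode_map.items.items():
        if item.source not in raw.columns:
            continue
        produced[name] = _recode_column(raw[item.source], item)
    if not produced:
        raise RecodeError("no map item has a source column in the raw table")
    frame = pd.DataFrame(produced)
    for col in ("id", "site", "education_type", "education_years_band",
                "antenatal_care", "facility_delivery", "theta"):
        if col in raw.columns:
            frame[col] = raw[col].to_numpy()
    if "site" not in frame.columns:
        frame["site"] = "all"
    return ResponseDataset(frame, list(produced))
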