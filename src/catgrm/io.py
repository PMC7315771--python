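"""File formats and preprocessing.

Item banks travel as CSV (columns ``item_id, model, n_categories, a,
b1..bK`` with trailing blanks for items with fewer categories) or as an
equivalent JSON document. Response matrices are wide CSV: one row per
person, first column the person id, one column per item, ``NA``/empty for
missing, plus optional demographic columns (region, gender, age, health)
used for DIF grouping.

Also houses the survey preprocessing filters: the paired lie-detection
consistency screen and listwise deletion.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import ItemBank, ItemParameters

#: response-matrix columns treated as demographics rather than items
DEFAULT_GROUP_COLS = ("region", "gender", "age", "health", "group")

__all__ = [
    "ResponseMatrix",
    "RunConfig",
    "read_item_bank",
    "write_item_bank",
    "load_packaged_bank",
    "read_responses",
    "write_responses",
    "lie_pair_filter",
    "listwise_delete",
]


class ResponseMatrix:
    """Persons x items ordinal response codes with an explicit missing mask.

    ``codes`` is a float array with NaN marking missing responses;
    observed entries are nonnegative integers. Optional ``groups`` holds
    per-person demographic columns (same row order).
    """

    def __init__(self, codes, item_ids: Sequence[str], person_ids=None,
                 groups: pd.DataFrame | None = None):
        codes = np.asarray(codes, dtype=float)
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D persons x items array")
        if codes.shape[1] != len(item_ids):
            raise ValueError("item_ids length does not match codes columns")
        obs = ~np.isnan(codes)
        if np.any(codes[obs] < 0) or np.any(codes[obs] != np.round(codes[obs])):
            raise ValueError("observed codes must be nonnegative integers")
        self.codes = codes
        self.item_ids = [str(i) for i in item_ids]
        if person_ids is None:
            person_ids = [str(i) for i in range(codes.shape[0])]
        if len(person_ids) != codes.shape[0]:
            raise ValueError("person_ids length does not match codes rows")
        self.person_ids = [str(p) for p in person_ids]
        if groups is not None:
            groups = groups.reset_index(drop=True)
            if len(groups) != codes.shape[0]:
                raise ValueError("groups rows do not match codes rows")
        self.groups = groups

    # -- shape ------------------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.codes.shape[0]

    @property
    def n_items(self) -> int:
        return self.codes.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the response is missing."""
        return np.isnan(self.codes)

    def column(self, item_id: str) -> np.ndarray:
        return self.codes[:, self.item_ids.index(item_id)]

    # -- derived matrices -------------------------------------------------
    def subset_items(self, item_ids: Iterable[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(self.codes[:, idx], [self.item_ids[i] for i in idx],
                              self.person_ids, self.groups)

    def subset_persons(self, row_idx) -> "ResponseMatrix":
        row_idx = np.asarray(row_idx)
        groups = self.groups.iloc[row_idx] if self.groups is not None else None
        return ResponseMatrix(self.codes[row_idx], self.item_ids,
                              [self.person_ids[i] for i in row_idx], groups)

    def validate_against(self, bank: ItemBank) -> None:
        """Raise if any observed code exceeds the item's category range."""
        for j, iid in enumerate(self.item_ids):
            if iid not in bank.ids:
                continue
            m = bank.get(iid).n_categories
            col = self.codes[:, j]
            bad = np.where(~np.isnan(col) & (col >= m))[0]
            if bad.size:
                raise ValueError(
                    f"person {self.person_ids[bad[0]]!r}, item {iid!r}: "
                    f"code {int(col[bad[0]])} >= n_categories {m}"
                )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=self.item_ids)
        df.insert(0, "person_id", self.person_ids)
        if self.groups is not None:
            for c in self.groups.columns:
                df[c] = self.groups[c].to_numpy()
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, item_ids: Sequence[str] | None = None,
                   group_cols: Sequence[str] | None = None) -> "ResponseMatrix":
        df = df.copy()
        if "person_id" in df.columns:
            person_ids = df.pop("person_id").astype(str).tolist()
        else:
            person_ids = [str(i) for i in range(len(df))]
        if group_cols is None:
            group_cols = [c for c in df.columns if str(c).lower() in DEFAULT_GROUP_COLS]
        if item_ids is None:
            item_ids = [c for c in df.columns if c not in group_cols]
        groups = df[list(group_cols)] if group_cols else None
        codes = df[list(item_ids)].to_numpy(dtype=float)
        return cls(codes, [str(c) for c in item_ids], person_ids, groups)


# ---------------------------------------------------------------------------
# item-bank CSV / JSON
# ---------------------------------------------------------------------------

def _bank_from_records(records, source: str) -> ItemBank:
    items = []
    for row_no, rec in enumerate(records, start=2):  # header is row 1
        model = str(rec["model"]).upper()
        m = int(rec["n_categories"])
        b = np.asarray(rec["b"], dtype=float)
        a = rec["a"]
        try:
            items.append(ItemParameters(str(rec["item_id"]), model, m, a, b))
        except ValueError as exc:
            raise ValueError(f"{source}, row {row_no}: {exc}") from exc
    return ItemBank(items)


def read_item_bank(path) -> ItemBank:
    """Read a bank from CSV or JSON (chosen by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        records = [
            {"item_id": it["item_id"], "model": it["model"],
             "n_categories": it["n_categories"], "a": it["a"], "b": it["b"]}
            for it in doc["items"]
        ]
        return _bank_from_records(records, str(path))
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        bcols = [c for c in reader.fieldnames if c.startswith("b")]
        for rec in reader:
            b = [float(rec[c]) for c in bcols if rec.get(c) not in (None, "", "NA")]
            records.append(
                {"item_id": rec["item_id"], "model": rec["model"],
                 "n_categories": rec["n_categories"], "a": float(rec["a"]), "b": b}
            )
    return _bank_from_records(records, str(path))


def write_item_bank(bank: ItemBank, path) -> None:
    """Write a bank as CSV (GRM/GPCM) or JSON (any model, by suffix).

    Floats are written with shortest round-trip ``repr`` so a
    write-then-read cycle reproduces the parameters bit-exactly.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {"items": [
            {"item_id": it.item_id, "model": it.model, "n_categories": it.n_categories,
             "a": np.asarray(it.a).tolist(), "b": it.b.tolist()}
            for it in bank
        ]}
        path.write_text(json.dumps(doc, indent=1))
        return
    if not all(it.model in ("GRM", "GPCM") for it in bank):
        raise ValueError("CSV bank format supports GRM/GPCM only; use .json for NRM")
    maxk = int(bank.n_categories.max()) - 1
    bcols = [f"b{k + 1}" for k in range(maxk)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["item_id", "model", "n_categories", "a", *bcols])
        for it in bank:
            bs = [repr(float(x)) for x in it.b] + [""] * (maxk - it.b.size)
            w.writerow([it.item_id, it.model, it.n_categories, repr(float(it.a)), *bs])


def load_packaged_bank() -> ItemBank:
    """The packaged 68-item calibrated GRM bank (mixed 3/4/5-category items)."""
    from importlib.resources import files

    return read_item_bank(files("catgrm.data").joinpath("bank_68.csv"))


# ---------------------------------------------------------------------------
# response CSV
# ---------------------------------------------------------------------------

def read_responses(path, bank: ItemBank | None = None,
                   group_cols: Sequence[str] | None = None,
                   one_based: bool = False) -> ResponseMatrix:
    """Read a wide response CSV; validates codes against ``bank`` if given.

    ``one_based=True`` shifts Likert data coded 1..m down to the internal
    0-based convention.
    """
    df = pd.read_csv(path, dtype={0: str})
    first = df.columns[0]
    if first.lower() in ("person_id", "id", "person"):
        df = df.rename(columns={first: "person_id"})
    item_ids = bank.ids if bank is not None else None
    rm = ResponseMatrix.from_frame(df, item_ids=item_ids, group_cols=group_cols)
    if one_based:
        codes = rm.codes - 1.0
        if np.nanmin(codes) < 0:
            raise ValueError("one_based=True but a code of 0 is present")
        rm = ResponseMatrix(codes, rm.item_ids, rm.person_ids, rm.groups)
    if bank is not None:
        rm.validate_against(bank)
    return rm


def write_responses(rm: ResponseMatrix, path) -> None:
    df = rm.to_frame()
    icols = rm.item_ids
    df[icols] = df[icols].astype("Int64")  # keeps NA, drops the ".0" noise
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing filters
# ---------------------------------------------------------------------------

def lie_pair_filter(rm: ResponseMatrix,
                    pairs: Sequence[tuple[str, str]]) -> tuple[ResponseMatrix, list[str]]:
    """Remove persons who gave the same raw answer to an item and its
    reversed lie-detection twin, for at least one pair."""
    drop = np.zeros(rm.n_persons, dtype=bool)
    for item, twin in pairs:
        x = rm.column(item)
        y = rm.column(twin)
        drop |= (~np.isnan(x)) & (~np.isnan(y)) & (x == y)
    removed = [p for p, d in zip(rm.person_ids, drop) if d]
    return rm.subset_persons(np.where(~drop)[0]), removed


def listwise_delete(rm: ResponseMatrix,
                    on: Sequence[str] | None = None) -> ResponseMatrix:
    """Drop every person with a missing value in the named columns
    (item ids and/or group columns); default: all items and all groups."""
    if on is None:
        miss = rm.mask.any(axis=1)
        if rm.groups is not None:
            miss |= rm.groups.isna().any(axis=1).to_numpy()
    else:
        miss = np.zeros(rm.n_persons, dtype=bool)
        for col in on:
            if col in rm.item_ids:
                miss |= np.isnan(rm.column(col))
            elif rm.groups is not None and col in rm.groups.columns:
                miss |= rm.groups[col].isna().to_numpy()
            else:
                raise KeyError(f"unknown column {col!r}")
    kept = rm.subset_persons(np.where(~miss)[0])
    if kept.n_persons == 0:
        warnings.warn("listwise deletion removed every person", RuntimeWarning, stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline thresholds and seeds in one place."""

    model: str = "GRM"
    loading_min: float = 0.30
    ratio_min: float = 3.0
    variance_min_pct: float = 20.0
    sx2_alpha: float = 0.05
    dif_threshold: float = 0.02
    min_discrimination: float = 0.8
    se_thresholds: tuple = (0.3, 0.4, 0.5)
    max_items: int = 20
    n_quadrature: int = 81
    theta_bounds: tuple = (-4.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loading_min", "ratio_min", "variance_min_pct", "sx2_alpha",
                     "dif_threshold", "min_discrimination"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        for name in ("se_thresholds", "theta_bounds"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["se_thresholds"] = list(self.se_thresholds)
        doc["theta_bounds"] = list(self.theta_bounds)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    def hash(self) -> str:
        """Stable digest embedded in every output artifact."""
        doc = asdict(self)
        doc["se_thresholds"] = list(self.se_thresholds)
        doc["theta_bounds"] = list(self.theta_bounds)
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
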