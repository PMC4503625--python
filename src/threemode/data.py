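"""Labelled three-way data cubes and long-format table input/output.

The central container is :class:`ThreeWayDataset`: an I x J x K array of
repeated questionnaire item scores indexed by persons (mode 1), symptom
items (mode 2) and assessment time points (mode 3), together with a
boolean observation mask.  Long-format tables (one row per person x time
x item) are the on-disk interchange format; cubes round-trip through
them losslessly, including the mask.

The module also implements the cohort-style sample-selection filter:
persons are retained only if they "provided" a minimum number of
assessment time points, where a time point counts as provided when at
least a configurable fraction of its items was answered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    EmptySelectionError,
    ParseError,
    ValidationError,
)

DEFAULT_SCHEMA: dict[str, str] = {
    "person": "person_id",
    "time": "time",
    "item": "item",
    "value": "value",
}


@dataclass
class ThreeWayDataset:
    """A persons x items x time-points score cube with observation mask.

    Attributes
    ----------
    values : ndarray, shape (I, J, K)
        Item scores; entries where ``mask`` is False are meaningless and
        must never be consumed.
    mask : ndarray of bool, shape (I, J, K)
        True where the cell was observed.
    person_ids, item_labels : list of str
    time_labels : ndarray of float
        Numeric assessment times, strictly increasing (e.g. months).
    time_unit : str
    """

    values: np.ndarray
    mask: np.ndarray
    person_ids: list[str]
    item_labels: list[str]
    time_labels: np.ndarray
    time_unit: str = "months"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.time_labels = np.asarray(self.time_labels, dtype=float)
        self.person_ids = [str(p) for p in self.person_ids]
        self.item_labels = [str(j) for j in self.item_labels]
        if self.values.ndim != 3:
            raise ValidationError("values must be a 3-way array")
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask shapes differ")
        i, j, k = self.values.shape
        if len(self.person_ids) != i or len(self.item_labels) != j:
            raise ValidationError("label vector lengths do not match dims")
        if len(self.time_labels) != k:
            raise ValidationError("time label length does not match dims")
        if k > 1 and not np.all(np.diff(self.time_labels) > 0):
            raise ValidationError("time labels must be strictly increasing")

    # -- basic introspection ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]

    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def missing_fraction(self) -> float:
        return float(1.0 - self.mask.mean())

    def copy(self) -> "ThreeWayDataset":
        return ThreeWayDataset(
            self.values.copy(),
            self.mask.copy(),
            list(self.person_ids),
            list(self.item_labels),
            self.time_labels.copy(),
            self.time_unit,
        )

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "ThreeWayDataset":
        """Return a copy sharing labels but with new values (and optional mask)."""
        return ThreeWayDataset(
            np.asarray(values, dtype=float),
            self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
            list(self.person_ids),
            list(self.item_labels),
            self.time_labels.copy(),
            self.time_unit,
        )


@dataclass
class SelectionReport:
    """Outcome of the minimum-time-points sample filter."""

    n_before: int
    n_after: int
    min_timepoints: int
    timepoint_rule: float
    per_person_observed_timepoints: dict[str, int] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            "sample selection report",
            f"  persons before: {self.n_before}",
            f"  persons after:  {self.n_after}",
            f"  rule: >= {self.min_timepoints} time points with >= "
            f"{self.timepoint_rule:.0%} of items answered",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# long-format table IO
# ---------------------------------------------------------------------------

def read_long_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    item_order: Sequence[str] | None = None,
    time_unit: str = "months",
) -> ThreeWayDataset:
    """Assemble a :class:`ThreeWayDataset` from a long-format CSV.

    Parameters
    ----------
    path : path to a UTF-8 CSV with a header row.
    schema : mapping with keys ``person``, ``time``, ``item``, ``value``
        giving the corresponding column names; defaults to
        ``person_id, time, item, value``.
    item_order : optional explicit questionnaire item order; items not
        listed raise, items listed but absent from the table raise.

    Missing cells may be encoded as absent rows, empty value fields or
    the literal ``NA``; all three produce a masked cell.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for role, col in schema.items():
        if col not in df.columns:
            raise ValidationError(f"column {col!r} (role {role}) missing from table")

    person_col, time_col, item_col, value_col = (
        schema["person"], schema["time"], schema["item"], schema["value"],
    )
    dup = df.duplicated(subset=[person_col, time_col, item_col])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DuplicateRecordError(
            f"duplicate (person,time,item) record at data row {row}"
        )

    raw_vals = df[value_col].str.strip()
    observed = (~raw_vals.isin(["", "NA", "NaN", "nan"])).to_numpy()
    # parse via float() for exact (1-ulp-free) round trips
    numeric = np.full(len(raw_vals), np.nan)
    for pos, (text, ok) in enumerate(zip(raw_vals.to_numpy(), observed)):
        if ok:
            try:
                numeric[pos] = float(text)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {text!r} at data row {pos}"
                ) from None

    persons = list(dict.fromkeys(df[person_col]))  # first appearance order
    times = np.asarray(sorted({float(t) for t in df[time_col]}), dtype=float)
    if item_order is not None:
        items = [str(x) for x in item_order]
        extra = set(df[item_col]) - set(items)
        if extra:
            raise ValidationError(f"items not in item_order: {sorted(extra)}")
    else:
        items = list(dict.fromkeys(df[item_col]))

    p_idx = {p: i for i, p in enumerate(persons)}
    j_idx = {s: j for j, s in enumerate(items)}
    k_idx = {t: k for k, t in enumerate(times)}

    shape = (len(persons), len(items), len(times))
    values = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    ii = df[person_col].map(p_idx).to_numpy()
    jj = df[item_col].map(j_idx).to_numpy()
    kk = np.asarray([k_idx[float(t)] for t in df[time_col]])
    values[ii[observed], jj[observed], kk[observed]] = numeric[observed]
    mask[ii[observed], jj[observed], kk[observed]] = True
    return ThreeWayDataset(values, mask, persons, items, times, time_unit)


def write_long_table(dataset: ThreeWayDataset, path: str | Path) -> None:
    """Write a cube as a long-format CSV (masked cells get an empty field)."""
    i_n, j_n, k_n = dataset.shape
    ii, jj, kk = np.unravel_index(np.arange(i_n * j_n * k_n), (i_n, j_n, k_n))
    vals = dataset.values[ii, jj, kk]
    obs = dataset.mask[ii, jj, kk]
    out = pd.DataFrame(
        {
            "person_id": np.asarray(dataset.person_ids, dtype=object)[ii],
            "time": dataset.time_labels[kk],
            "item": np.asarray(dataset.item_labels, dtype=object)[jj],
            "value": [repr(float(v)) if o else "" for v, o in zip(vals, obs)],
        }
    )
    out.to_csv(path, index=False)


def write_wide_tables(dataset: ThreeWayDataset, directory: str | Path) -> list[Path]:
    """Export one persons-x-items CSV per time point, for eyeballing."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, t in enumerate(dataset.time_labels):
        frame = pd.DataFrame(
            np.where(dataset.mask[:, :, k], dataset.values[:, :, k], np.nan),
            index=dataset.person_ids,
            columns=dataset.item_labels,
        )
        p = directory / f"wide_t{t:g}.csv"
        frame.to_csv(p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# sample selection
# ---------------------------------------------------------------------------

def select_sample(
    dataset: ThreeWayDataset,
    min_timepoints: int = 5,
    timepoint_rule: float = 0.5,
) -> tuple[ThreeWayDataset, SelectionReport]:
    """Drop persons who provided fewer than ``min_timepoints`` assessments.

    A time point counts as provided for a person iff the fraction of
    that person's observed items at that time is at least
    ``timepoint_rule`` (default 0.5; use 1.0 for a strict reading).
    Values of retained persons are never altered.
    """
    k_n = dataset.n_times
    if not 1 <= min_timepoints <= k_n:
        raise ValidationError("min_timepoints must be in [1, K]")
    if not 0 < timepoint_rule <= 1:
        raise ValidationError("timepoint_rule must be in (0, 1]")

    frac_items = dataset.mask.mean(axis=1)  # I x K observed-item fraction
    provided = (frac_items >= timepoint_rule).sum(axis=1)
    keep = provided >= min_timepoints
    if not keep.any():
        raise EmptySelectionError("selection filter removed every person")

    report = SelectionReport(
        n_before=dataset.n_persons,
        n_after=int(keep.sum()),
        min_timepoints=min_timepoints,
        timepoint_rule=timepoint_rule,
        per_person_observed_timepoints={
            p: int(c) for p, c in zip(dataset.person_ids, provided)
        },
    )
    selected = ThreeWayDataset(
        dataset.values[keep],
        dataset.mask[keep],
        [p for p, k in zip(dataset.person_ids, keep) if k],
        list(dataset.item_labels),
        dataset.time_labels.copy(),
        dataset.time_unit,
    )
    return selected, report
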