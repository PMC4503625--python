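"""Invertible preprocessing: person-mode centering and symptom-mode scaling.

Centering across the person mode subtracts, for every (item, time)
pair, the mean over persons — the "general trend", i.e. the average
item-score trajectory shared by the whole sample.  What remains is the
qualitative heterogeneity around that trend, which is what the Tucker3
decomposition models.

Normalization within the symptom mode then rescales each item's
I x K slab to root-mean-square 1 (slab SS = I*K), so that every item
contributes equally to the least-squares fit regardless of its raw
variance.  Both steps are recorded in a :class:`PreprocessingState`
and are exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ThreeWayDataset
from .errors import DegenerateItemError, IncompleteInputError, ValidationError


@dataclass
class PreprocessingState:
    """General trend M (J x K) and per-item scales s (length J, all > 0)."""

    trend: np.ndarray
    scales: np.ndarray
    conventions: dict = field(default_factory=lambda: {
        "centering": "across persons (fiber means per item x time)",
        "normalization": "within symptom mode, slab root-mean-square = 1",
    })

    def __post_init__(self) -> None:
        self.trend = np.asarray(self.trend, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if self.trend.ndim != 2 or self.scales.ndim != 1:
            raise ValidationError("trend must be J x K, scales length J")
        if self.trend.shape[0] != self.scales.shape[0]:
            raise ValidationError("trend and scales disagree on item count")
        if np.any(self.scales <= 0):
            raise ValidationError("scales must be strictly positive")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.trend).to_csv(directory / "trend.csv", index=False)
        pd.DataFrame({"scale": self.scales}).to_csv(
            directory / "scales.csv", index=False
        )

    @classmethod
    def load(cls, directory: str | Path) -> "PreprocessingState":
        directory = Path(directory)
        trend = pd.read_csv(directory / "trend.csv").to_numpy()
        scales = pd.read_csv(directory / "scales.csv")["scale"].to_numpy()
        return cls(trend, scales)


def center_across_persons(
    dataset: ThreeWayDataset,
) -> tuple[ThreeWayDataset, np.ndarray]:
    """Remove the general trend: subtract the per-(item,time) person mean.

    Requires a complete cube (run after imputation).  Returns the
    centered dataset and the J x K trend matrix M.
    """
    if not dataset.is_complete():
        raise IncompleteInputError("centering requires a complete cube; impute first")
    trend = dataset.values.mean(axis=0)
    return dataset.with_values(dataset.values - trend[None, :, :]), trend


def normalize_within_symptom(
    dataset: ThreeWayDataset,
) -> tuple[ThreeWayDataset, np.ndarray]:
    """Scale every item slab to root-mean-square 1 (slab SS = I*K).

    Returns the normalized dataset and the length-J scale vector s,
    where s_j is the RMS of item j's slab before scaling.
    """
    if not dataset.is_complete():
        raise IncompleteInputError("normalization requires a complete cube")
    ss = np.sum(dataset.values**2, axis=(0, 2))
    if np.any(ss == 0):
        j = int(np.flatnonzero(ss == 0)[0])
        raise DegenerateItemError(
            f"item {dataset.item_labels[j]!r} has a zero-variance slab"
        )
    i_n, _, k_n = dataset.shape
    scales = np.sqrt(ss / (i_n * k_n))
    return dataset.with_values(dataset.values / scales[None, :, None]), scales


def preprocess(
    dataset: ThreeWayDataset,
) -> tuple[ThreeWayDataset, PreprocessingState]:
    """Center across persons then normalize within symptom mode."""
    centered, trend = center_across_persons(dataset)
    normalized, scales = normalize_within_symptom(centered)
    return normalized, PreprocessingState(trend=trend, scales=scales)


def inverse_transform(
    cube: np.ndarray, state: PreprocessingState
) -> np.ndarray:
    """Undo preprocessing: multiply by s_j and add back the trend."""
    cube = np.asarray(cube, dtype=float)
    if cube.shape[1:] != state.trend.shape:
        raise ValidationError("cube shape does not match preprocessing state")
    return cube * state.scales[None, :, None] + state.trend[None, :, :]
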