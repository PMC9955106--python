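"""Core data container: a continuous marker with a binary condition label.

Every analysis in this package consumes a :class:`MarkerDataset` — one row
per subject, one continuous measurement (e.g. the systemic
immune-inflammation index, SII) and one {0, 1} condition indicator
(1 = condition present, e.g. no-reflow after primary PCI). Higher marker
values are assumed to indicate the condition; that orientation is fixed
throughout the package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical on-disk column order for cohort CSV files
CSV_COLUMNS = ("subject_id", "marker", "value", "condition")


class SingleClassError(ValueError):
    """Raised when an operation needs both classes but one is absent."""


@dataclasses.dataclass(frozen=True)
class MarkerDataset:
    """Continuous marker values paired with binary condition labels.

    Parameters
    ----------
    values
        Marker measurements, one per subject (marker units).
    labels
        Condition indicators in {0, 1}; 1 means the condition is present.
    marker_name
        Free-text marker identifier, e.g. ``"SII"``.
    """

    values: np.ndarray
    labels: np.ndarray
    marker_name: str = "marker"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=np.int64)
        if values.ndim != 1 or labels.ndim != 1:
            raise ValueError("values and labels must be one-dimensional")
        if values.shape != labels.shape:
            raise ValueError(
                f"length mismatch: {values.size} values vs {labels.size} labels"
            )
        if values.size == 0:
            raise ValueError("dataset is empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("marker values must be finite (no missing values)")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_groups(
        cls,
        non_diseased: np.ndarray,
        diseased: np.ndarray,
        marker_name: str = "marker",
    ) -> "MarkerDataset":
        """Build a dataset from the two class samples (non-diseased first)."""
        non_diseased = np.asarray(non_diseased, dtype=float)
        diseased = np.asarray(diseased, dtype=float)
        values = np.concatenate([non_diseased, diseased])
        labels = np.concatenate(
            [np.zeros(non_diseased.size, dtype=np.int64),
             np.ones(diseased.size, dtype=np.int64)]
        )
        return cls(values=values, labels=labels, marker_name=marker_name)

    # -- basic views -------------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return self.n - self.n_pos

    @property
    def pos_values(self) -> np.ndarray:
        """Marker values of subjects with the condition."""
        return self.values[self.labels == 1]

    @property
    def neg_values(self) -> np.ndarray:
        """Marker values of subjects without the condition."""
        return self.values[self.labels == 0]

    def require_both_classes(self) -> None:
        if self.n_pos == 0:
            raise SingleClassError("no subjects with the condition (label 1)")
        if self.n_neg == 0:
            raise SingleClassError("no subjects without the condition (label 0)")

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": np.arange(1, self.n + 1),
                "marker": self.marker_name,
                "value": self.values,
                "condition": self.labels,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, marker_name: str | None = None) -> "MarkerDataset":
        """Read the cohort CSV dialect (``subject_id,marker,value,condition``).

        If the file holds several markers, ``marker_name`` selects one;
        otherwise the file must contain a single marker.
        """
        frame = pd.read_csv(path)
        missing = set(CSV_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"cohort CSV is missing columns: {sorted(missing)}")
        if marker_name is not None:
            frame = frame[frame["marker"] == marker_name]
            if frame.empty:
                raise ValueError(f"no rows for marker {marker_name!r}")
        else:
            names = frame["marker"].unique()
            if len(names) != 1:
                raise ValueError(
                    f"file contains markers {sorted(names)}; pass marker_name"
                )
            marker_name = str(names[0])
        return cls(
            values=frame["value"].to_numpy(dtype=float),
            labels=frame["condition"].to_numpy(),
            marker_name=str(marker_name),
        )
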