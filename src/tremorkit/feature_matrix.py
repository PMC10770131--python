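"""Participants-by-features container with per-column group annotations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix"]


@dataclass
class FeatureMatrix:
    """Feature values plus the column metadata needed for grouped importance.

    ``columns`` carries one row per feature column with fields:
    ``name`` (unique column name), ``channel`` (source channel label or
    ``questionnaire``), ``group`` (task category or symptom domain), and
    ``sensor`` (acceleration / rotation / questionnaire) used for
    input-source selection.
    """

    values: np.ndarray            # (n_subjects, n_features)
    subject_ids: list[str]
    columns: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count must match subject_ids")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count must match columns metadata")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_sensors(self, sensors: tuple[str, ...]) -> "FeatureMatrix":
        """Column subset restricted to the given sensors (order preserved)."""
        mask = self.columns["sensor"].isin(sensors).to_numpy()
        return FeatureMatrix(
            self.values[:, mask],
            list(self.subject_ids),
            self.columns.loc[mask].reset_index(drop=True),
        )
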