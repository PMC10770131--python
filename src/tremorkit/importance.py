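"""Grouped permutation importance over feature-column groups.

For each predefined group of input columns (questionnaire symptom domains,
smartwatch task categories) and each repeat, one shared random permutation
is applied jointly to all of the group's columns across test subjects — the
within-group joint structure is preserved — and the drop in balanced
accuracy relative to the unpermuted baseline is recorded.  The importance of
a group is the mean drop over repeats (and, when run per fold, over folds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score

from . import pdnms

__all__ = [
    "FeatureGrouping",
    "grouped_permutation_importance",
    "rank_groups",
    "default_pdnms_domains",
    "plot_importance",
]


def default_pdnms_domains() -> dict[str, list[int]]:
    """Default 30-item questionnaire grouping into nine symptom domains."""
    return {k: list(v) for k, v in pdnms.DEFAULT_DOMAINS.items()}


@dataclass
class FeatureGrouping:
    """Partition of feature-column indices into named groups."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=int) for k, v in self.groups.items()}
        for name, idx in self.groups.items():
            if idx.size == 0:
                raise ValueError(f"group {name!r} is empty")

    def validate_partition(self, n_columns: int) -> None:
        all_idx = np.concatenate(list(self.groups.values()))
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("groups overlap: a column appears in more than one group")
        if not np.array_equal(np.sort(all_idx), np.arange(n_columns)):
            raise ValueError(
                f"groups must partition all {n_columns} columns exactly"
            )

    @classmethod
    def from_column_groups(cls, group_labels) -> "FeatureGrouping":
        """Build a grouping from a per-column group-label sequence."""
        labels = np.asarray(group_labels)
        return cls({g: np.flatnonzero(labels == g) for g in pd.unique(labels)})


def grouped_permutation_importance(
    predict_fn,
    X: np.ndarray,
    y: np.ndarray,
    grouping: FeatureGrouping,
    n_repeats: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean balanced-accuracy drop per group when its columns are shuffled.

    ``predict_fn(X) -> labels`` must wrap a model fitted on data disjoint
    from ``X``.  Returns a DataFrame indexed by group with columns
    ``importance`` (mean drop), ``sd`` (over repeats), and ``n_repeats``.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    grouping.validate_partition(X.shape[1])
    rng = np.random.default_rng(seed)
    baseline = balanced_accuracy_score(y, predict_fn(X))

    rows = {}
    for name, cols in grouping.groups.items():
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            perm = rng.permutation(X.shape[0])
            Xp = X.copy()
            Xp[:, cols] = X[np.ix_(perm, cols)]  # one shared permutation per repeat
            drops[r] = baseline - balanced_accuracy_score(y, predict_fn(Xp))
        rows[name] = (drops.mean(), drops.std(ddof=0))
    df = pd.DataFrame(
        {
            "importance": [v[0] for v in rows.values()],
            "sd": [v[1] for v in rows.values()],
            "n_repeats": n_repeats,
        },
        index=list(rows.keys()),
    )
    df.index.name = "group"
    return df


def rank_groups(importances: pd.DataFrame) -> pd.DataFrame:
    """Groups sorted by descending mean importance; ties keep input order."""
    return importances.sort_values("importance", ascending=False, kind="stable")


def average_importances(per_fold: list[pd.DataFrame]) -> pd.DataFrame:
    """Average importance tables across test folds (matching group sets)."""
    combined = pd.concat(per_fold)
    out = combined.groupby(level=0, sort=False).agg(
        importance=("importance", "mean"), sd=("importance", "std")
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out


def plot_importance(importances: pd.DataFrame, path=None, top: int = 10):
    """Horizontal bar chart of the top groups by mean importance."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = rank_groups(importances).head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(ranked) + 1.5))
    ax.barh(ranked.index, ranked["importance"], xerr=ranked["sd"], color="#4878d0")
    ax.set_xlabel("balanced-accuracy drop")
    ax.set_title("Grouped permutation importance")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
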