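"""Autoscaling and correlation-based descriptor screening.

Autoscaling (column-wise standardization to zero mean and unit variance, sample
n-1 convention) gives every descriptor equal weight before PCA, HCA and the
latent-variable regressions.  Descriptor screening keeps only descriptors whose
Pearson correlation with the activity reaches a cutoff in absolute value
(default |r| >= 0.20); redundancy between descriptors is deliberately not used
as a criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import QSARDataError, QSARDataset

__all__ = [
    "AutoscaleModel",
    "CorrelationReport",
    "fit_autoscale",
    "correlation_matrix",
    "filter_by_activity_correlation",
]

#: Default |r(descriptor, activity)| threshold below which a descriptor is discarded.
DEFAULT_CORRELATION_CUTOFF = 0.20


@dataclass
class AutoscaleModel:
    """Per-column means and sample standard deviations of the training data."""

    column_names: list[str]
    means: np.ndarray
    stdevs: np.ndarray

    def transform(self, dataset_or_matrix) -> np.ndarray:
        """Column-wise z-scores ``(x - mean) / sd`` using the fitted statistics.

        Accepts a :class:`QSARDataset` (its columns must include the model's,
        in any superset/order) or a plain matrix already in model column order.
        New data is scaled with the training statistics — no re-fitting.
        """
        x = self._as_matrix(dataset_or_matrix)
        return (x - self.means) / self.stdevs

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        scaled = np.asarray(scaled, dtype=float)
        return scaled * self.stdevs + self.means

    def _as_matrix(self, dataset_or_matrix) -> np.ndarray:
        if isinstance(dataset_or_matrix, QSARDataset):
            missing = [
                c for c in self.column_names if c not in dataset_or_matrix.descriptor_names
            ]
            if missing:
                raise QSARDataError(f"dataset lacks model column(s) {missing}")
            return dataset_or_matrix.subset(self.column_names).matrix()
        x = np.asarray(dataset_or_matrix, dtype=float)
        if x.ndim == 1:
            x = x.reshape(1, -1)
        if x.shape[1] != len(self.column_names):
            raise QSARDataError(
                f"matrix has {x.shape[1]} columns, model expects {len(self.column_names)}"
            )
        return x


@dataclass
class CorrelationReport:
    """Pearson correlation structure of a dataset with activity."""

    descriptor_names: list[str]
    descriptor_pair_corr: np.ndarray  # m x m, symmetric, unit diagonal
    descriptor_activity_corr: np.ndarray  # length m

    def pair(self, a: str, b: str) -> float:
        i, j = self.descriptor_names.index(a), self.descriptor_names.index(b)
        return float(self.descriptor_pair_corr[i, j])

    def with_activity(self, name: str) -> float:
        return float(self.descriptor_activity_corr[self.descriptor_names.index(name)])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.descriptor_pair_corr,
            index=self.descriptor_names,
            columns=self.descriptor_names,
        )
        df["activity"] = self.descriptor_activity_corr
        return df


def _column_sds(x: np.ndarray, names: list[str]) -> np.ndarray:
    sds = x.std(axis=0, ddof=1)
    constant = [names[j] for j in np.nonzero(sds == 0.0)[0]]
    if constant:
        raise QSARDataError(f"constant (zero-variance) column(s): {constant}")
    return sds


def fit_autoscale(dataset: QSARDataset, include_activity: bool = False) -> AutoscaleModel:
    """Fit column means and sample (n-1) standard deviations.

    With ``include_activity`` the activity column is appended as the last
    model column.  Requires at least two compounds and no constant column.
    """
    if dataset.n_compounds < 2:
        raise QSARDataError("autoscaling requires at least 2 compounds")
    x = dataset.matrix()
    names = list(dataset.descriptor_names)
    if include_activity:
        x = np.column_stack([x, dataset.activity()])
        names = names + [dataset.activity_name]
    if not np.all(np.isfinite(x)):
        raise QSARDataError("non-finite values in data matrix")
    return AutoscaleModel(names, x.mean(axis=0), _column_sds(x, names))


def correlation_matrix(dataset: QSARDataset) -> CorrelationReport:
    """Pearson product-moment correlations among descriptors and with activity."""
    if dataset.n_compounds < 3:
        raise QSARDataError("correlations require at least 3 compounds")
    x = dataset.matrix()
    y = dataset.activity()
    names = list(dataset.descriptor_names)
    _column_sds(x, names)  # raises on zero-variance descriptor
    if y.std(ddof=1) == 0.0:
        raise QSARDataError(f"constant activity column {dataset.activity_name!r}")
    full = np.corrcoef(np.column_stack([x, y]), rowvar=False)
    return CorrelationReport(names, full[:-1, :-1], full[:-1, -1])


def filter_by_activity_correlation(
    dataset: QSARDataset, cutoff: float = DEFAULT_CORRELATION_CUTOFF
) -> tuple[QSARDataset, pd.DataFrame]:
    """Drop descriptors with |r(descriptor, activity)| below the cutoff.

    Ties at exactly the cutoff are kept (descriptors "under" the cutoff are
    discarded).  Returns the retained dataset and a report with one row per
    descriptor: ``descriptor, r_with_activity, retained``.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise QSARDataError(f"cutoff must lie in [0, 1], got {cutoff}")
    report = correlation_matrix(dataset)
    retained_mask = np.abs(report.descriptor_activity_corr) >= cutoff
    table = pd.DataFrame(
        {
            "descriptor": report.descriptor_names,
            "r_with_activity": report.descriptor_activity_corr,
            "retained": retained_mask,
        }
    )
    kept = [d for d, keep in zip(report.descriptor_names, retained_mask) if keep]
    return dataset.subset(kept), table
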