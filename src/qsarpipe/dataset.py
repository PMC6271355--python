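"""Compound/descriptor data model, activity transformation and delimited-text I/O.

The central container is :class:`QSARDataset`: a rectangular compound-by-descriptor
matrix with an optional activity column.  Activity is expressed as logRA, the
base-10 logarithm of relative activity

    logRA = log10(IC50 of the reference compound / IC50 of the analog),

so that positive values mark analogs more potent than the reference (here
artemisinin, IC50 = 97 uM against the HepG2 hepatocellular carcinoma line).

Two fixtures ship with the package: the 21-compound artemisinin training set
(four descriptors: ALOGPS_logs, Mor29m, IC5, GAP_energy, plus IC50 and logRA)
and the 8-compound test set of untested derivatives.  Fixture values are stored
as decimal strings in CSV data files and parsed on load, so the in-memory values
are exactly the printed ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PotencyClass",
    "CompoundRecord",
    "QSARDataset",
    "QSARDataError",
    "REFERENCE_IC50_UM",
    "compute_log_ra",
    "classify_potency",
    "load_dataset",
    "save_dataset",
    "builtin_fixture",
]

#: IC50 of the reference compound (artemisinin) against HepG2, in uM.
#: Used by the fixtures; other reference compounds can be supplied in config.
REFERENCE_IC50_UM = 97.0

_FIXTURE_FILES = {
    "training": "artemisinin_training.csv",
    "test": "artemisinin_test.csv",
}

_ID_COLUMN = "compound_id"
_IC50_COLUMN = "IC50"


class QSARDataError(ValueError):
    """Invalid input data: non-positive concentration, ragged table, duplicate id..."""


class PotencyClass(str, Enum):
    MORE_POTENT = "more_potent"
    LESS_POTENT = "less_potent"
    UNKNOWN = "unknown"


def compute_log_ra(ic50_reference: float, ic50_analog: float) -> tuple[float, float]:
    """Relative activity RA = IC50_ref / IC50_analog and its base-10 log.

    Both concentrations must be strictly positive and finite (same units,
    conventionally uM).  Returns ``(ra, log_ra)``.
    """
    for label, value in (("ic50_reference", ic50_reference), ("ic50_analog", ic50_analog)):
        if not math.isfinite(value) or value <= 0:
            raise QSARDataError(
                f"{label} must be a strictly positive finite concentration, got {value!r}"
            )
    ra = ic50_reference / ic50_analog
    return ra, math.log10(ra)


def classify_potency(log_ra: float) -> PotencyClass:
    """Classify an analog relative to the reference: logRA > 0 is more potent.

    Exactly zero (the reference itself) counts as less potent.
    """
    if not math.isfinite(log_ra):
        raise QSARDataError(f"log_ra must be finite, got {log_ra!r}")
    return PotencyClass.MORE_POTENT if log_ra > 0.0 else PotencyClass.LESS_POTENT


@dataclass
class CompoundRecord:
    """One compound: id, descriptor values, and optional activity annotations."""

    compound_id: str
    descriptor_values: dict[str, float]
    ic50: float | None = None
    log_ra: float | None = None
    potency_class: PotencyClass = PotencyClass.UNKNOWN

    def __post_init__(self) -> None:
        for name, value in self.descriptor_values.items():
            if value is None or not math.isfinite(value):
                raise QSARDataError(
                    f"compound {self.compound_id!r}: descriptor {name!r} is missing/non-finite"
                )
        if self.ic50 is not None and (not math.isfinite(self.ic50) or self.ic50 <= 0):
            raise QSARDataError(
                f"compound {self.compound_id!r}: IC50 must be positive, got {self.ic50!r}"
            )
        if self.log_ra is not None and self.potency_class is PotencyClass.UNKNOWN:
            self.potency_class = classify_potency(self.log_ra)


@dataclass
class QSARDataset:
    """Rectangular compound x descriptor matrix with optional activity.

    ``descriptor_names`` fixes the column order; every compound must carry a
    value for every descriptor.  The activity column (default name "logRA") is
    present when every compound has ``log_ra`` set.
    """

    descriptor_names: list[str]
    compounds: list[CompoundRecord]
    activity_name: str = "logRA"
    reference_ic50: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise QSARDataError("duplicate descriptor names")
        ids = [c.compound_id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise QSARDataError(f"duplicate compound ids: {dupes}")
        for c in self.compounds:
            missing = [d for d in self.descriptor_names if d not in c.descriptor_values]
            if missing:
                raise QSARDataError(
                    f"compound {c.compound_id!r} lacks descriptor(s) {missing}"
                )

    # -- shape and views ---------------------------------------------------

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    @property
    def compound_ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    @property
    def has_activity(self) -> bool:
        return bool(self.compounds) and all(c.log_ra is not None for c in self.compounds)

    def matrix(self) -> np.ndarray:
        """The n x m descriptor matrix as a float array (row order preserved)."""
        return np.array(
            [[c.descriptor_values[d] for d in self.descriptor_names] for c in self.compounds],
            dtype=float,
        )

    def activity(self) -> np.ndarray:
        if not self.has_activity:
            raise QSARDataError("dataset has no complete activity column")
        return np.array([c.log_ra for c in self.compounds], dtype=float)

    def potency_classes(self) -> list[PotencyClass]:
        return [c.potency_class for c in self.compounds]

    def subset(self, descriptor_names: Sequence[str]) -> "QSARDataset":
        """A copy restricted to the given descriptors (order as given)."""
        missing = [d for d in descriptor_names if d not in self.descriptor_names]
        if missing:
            raise QSARDataError(f"unknown descriptor(s): {missing}")
        compounds = [
            CompoundRecord(
                compound_id=c.compound_id,
                descriptor_values={d: c.descriptor_values[d] for d in descriptor_names},
                ic50=c.ic50,
                log_ra=c.log_ra,
                potency_class=c.potency_class,
            )
            for c in self.compounds
        ]
        return QSARDataset(
            list(descriptor_names), compounds, self.activity_name, self.reference_ic50
        )

    def select_rows(self, indices: Iterable[int]) -> "QSARDataset":
        compounds = [self.compounds[i] for i in indices]
        return QSARDataset(
            list(self.descriptor_names),
            [
                CompoundRecord(
                    c.compound_id, dict(c.descriptor_values), c.ic50, c.log_ra, c.potency_class
                )
                for c in compounds
            ],
            self.activity_name,
            self.reference_ic50,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix(), columns=self.descriptor_names)
        df.insert(0, _ID_COLUMN, self.compound_ids)
        if any(c.ic50 is not None for c in self.compounds):
            df[_IC50_COLUMN] = [c.ic50 for c in self.compounds]
        if self.has_activity:
            df[self.activity_name] = self.activity()
        return df


# -- delimited-text I/O ----------------------------------------------------


def load_dataset(path: str | Path, activity_name: str = "logRA") -> QSARDataset:
    """Read a CSV with header ``compound_id,<descriptor...>[,IC50][,logRA]``.

    Row order is preserved; parsing is locale-independent (dot decimal).
    Ragged rows, duplicate ids or non-numeric cells raise :class:`QSARDataError`
    with the offending position.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise QSARDataError(f"{path}: cannot parse delimited text: {exc}") from exc
    return _dataset_from_strings(df, activity_name, origin=str(path))


def _dataset_from_strings(df: pd.DataFrame, activity_name: str, origin: str) -> QSARDataset:
    if _ID_COLUMN not in df.columns:
        raise QSARDataError(f"{origin}: missing {_ID_COLUMN!r} header column")
    descriptor_names = [
        c for c in df.columns if c not in (_ID_COLUMN, _IC50_COLUMN, activity_name)
    ]
    if not descriptor_names:
        raise QSARDataError(f"{origin}: no descriptor columns found")

    def parse_cell(row: int, col: str, text: str, optional: bool = False) -> float | None:
        text = text.strip()
        if text == "":
            if optional:
                return None
            raise QSARDataError(f"{origin}: empty cell at row {row + 2}, column {col!r}")
        try:
            # tolerate the unicode minus used in typeset tables
            return float(text.replace("−", "-"))
        except ValueError:
            raise QSARDataError(
                f"{origin}: non-numeric cell {text!r} at row {row + 2}, column {col!r}"
            ) from None

    compounds = []
    for i, row in enumerate(df.itertuples(index=False)):
        record = dict(zip(df.columns, row))
        values = {d: parse_cell(i, d, record[d]) for d in descriptor_names}
        ic50 = (
            parse_cell(i, _IC50_COLUMN, record[_IC50_COLUMN], optional=True)
            if _IC50_COLUMN in df.columns
            else None
        )
        log_ra = (
            parse_cell(i, activity_name, record[activity_name], optional=True)
            if activity_name in df.columns
            else None
        )
        compounds.append(
            CompoundRecord(str(record[_ID_COLUMN]).strip(), values, ic50, log_ra)
        )
    return QSARDataset(descriptor_names, compounds, activity_name)


def save_dataset(dataset: QSARDataset, path: str | Path) -> None:
    """Write the dataset as CSV; values round-trip as decimal strings."""
    df = dataset.to_dataframe()
    df.to_csv(path, index=False)


def builtin_fixture(name: str, reference_ic50: float = REFERENCE_IC50_UM) -> QSARDataset:
    """The packaged artemisinin tables: ``"training"`` (21 x 4, with IC50 and
    logRA) or ``"test"`` (8 x 4, activity unknown)."""
    if name not in _FIXTURE_FILES:
        raise QSARDataError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}"
        )
    source = resources.files("qsarpipe.data").joinpath(_FIXTURE_FILES[name])
    with resources.as_file(source) as path:
        dataset = load_dataset(path)
    dataset.reference_ic50 = reference_ic50
    return dataset
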