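"""Shared containers for the multi-omic SGA phenotyping pipeline.

The pipeline moves four kinds of objects between stages: per-domain
patient x feature tables (:class:`FeatureBlock`), patient x patient
similarity matrices (plain ``numpy`` arrays, see :mod:`sgasnf.snf`),
cluster assignments (:class:`ClusterAssignment`) and per-patient outcome
tables (:class:`OutcomeTable`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Data domains used to characterise the cohort, in canonical order.
DOMAINS = (
    "clinical",
    "ultrasound",
    "cord_metabolomics",
    "maternal_metabolomics",
)

#: Binary outcome columns of an OutcomeTable, in canonical order.
BINARY_OUTCOMES = ("preeclampsia", "stillbirth", "apo", "abnormal_bnp")


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its valid range."""


class ImputationError(ValueError):
    """Raised when a feature cannot be imputed (e.g. fully missing)."""


@dataclass
class FeatureBlock:
    """One data domain's patients x features matrix.

    Missing cells are NaN in ``values``; ``mask`` is True where observed.
    """

    values: pd.DataFrame
    domain: str

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2 or self.values.shape[1] < 1:
            raise ValueError(
                f"FeatureBlock needs >=2 patients and >=1 feature, "
                f"got shape {self.values.shape}"
            )
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError(f"infinite values in domain {self.domain!r}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is observed."""
        return ~self.values.isna().to_numpy()

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def copy(self) -> "FeatureBlock":
        return FeatureBlock(self.values.copy(), self.domain)


@dataclass
class OutcomeTable:
    """Per-patient binary outcomes plus diagnosis-to-delivery interval.

    ``data`` has the binary outcome columns of :data:`BINARY_OUTCOMES`
    (0/1), an ``interval_weeks`` column (time from diagnosis to delivery)
    and an ``event`` indicator (1 = delivered during follow-up).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("interval_weeks", "event"):
            if col not in self.data.columns:
                raise ValueError(f"OutcomeTable missing column {col!r}")
        if (self.data["interval_weeks"].to_numpy() <= 0).any():
            raise ValueError("interval_weeks must be strictly positive")
        ev = self.data["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def n_patients(self) -> int:
        return self.data.shape[0]

    def binary(self, outcome: str) -> np.ndarray:
        return self.data[outcome].to_numpy(dtype=int)

    def copy(self) -> "OutcomeTable":
        return OutcomeTable(self.data.copy())


@dataclass
class ClusterAssignment:
    """Per-patient integer phenotype labels in 1..k."""

    labels: np.ndarray
    k: int
    source: str = "fused"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if uniq.min() < 1 or uniq.max() > self.k:
            raise ValueError(f"labels must lie in 1..{self.k}, got {uniq}")

    @property
    def n_patients(self) -> int:
        return self.labels.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        """Per-cluster counts, indexed by label-1; sums to n."""
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


@dataclass
class ContingencyTable:
    """TP/FP/TN/FN counts for a binary classification vs a binary outcome."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MultiOmicCohort:
    """A cohort: aligned feature blocks, outcomes and hidden true labels.

    ``true_labels`` is generator ground truth (1..n_clusters) and must not
    be consulted by pipeline stages; it exists for evaluation only.
    ``complete_blocks`` retains pre-missingness values so that imputation
    accuracy can be measured against the withheld truth.
    """

    patient_ids: list[str]
    blocks: dict[str, FeatureBlock]
    outcomes: OutcomeTable
    true_labels: Optional[np.ndarray] = None
    complete_blocks: Optional[dict[str, FeatureBlock]] = None

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        for dom, block in self.blocks.items():
            if block.n_patients != n:
                raise ValueError(
                    f"block {dom!r} has {block.n_patients} patients, expected {n}"
                )
        if self.outcomes.n_patients != n:
            raise ValueError("outcome table size mismatch")
        if self.true_labels is not None and len(self.true_labels) != n:
            raise ValueError("true_labels size mismatch")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def subset(self, idx: Sequence[int]) -> "MultiOmicCohort":
        """Row-subset every table consistently (used by train/test splits)."""
        idx = np.asarray(idx, dtype=int)
        blocks = {
            d: FeatureBlock(b.values.iloc[idx].reset_index(drop=True), d)
            for d, b in self.blocks.items()
        }
        complete = None
        if self.complete_blocks is not None:
            complete = {
                d: FeatureBlock(b.values.iloc[idx].reset_index(drop=True), d)
                for d, b in self.complete_blocks.items()
            }
        return MultiOmicCohort(
            patient_ids=[self.patient_ids[i] for i in idx],
            blocks=blocks,
            outcomes=OutcomeTable(self.outcomes.data.iloc[idx].reset_index(drop=True)),
            true_labels=None if self.true_labels is None else self.true_labels[idx],
            complete_blocks=complete,
        )
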