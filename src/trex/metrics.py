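"""Hamming-distance grading metrics.

The Hamming distance between two segmentations of the same scan is the
proportion of pixels labeled differently — one minus the pixel accuracy.
It is computed either across all four compartments at once (the 4-way
label comparison, scope ``ALL``) or per compartment on the binary
membership maps.  The denominator is always the total pixel count H·W,
also for per-compartment scopes, so the per-compartment distances of a
pair sum to exactly twice the overall distance (each differing pixel
flips exactly two binary maps).

Distances are stored as fractions in [0, 1]; percent formatting belongs
to reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .labelmaps import CompartmentCode, CompartmentLabelMap, GradingEnsemble

__all__ = [
    "Scope",
    "DistanceTable",
    "MeanDistanceMatrix",
    "hamming",
    "compartment_hamming",
    "build_distance_table",
    "mean_distance_matrix",
    "fraction_model_closer",
]


class Scope(str, Enum):
    """Comparison scope: the 4-way label comparison or one binary compartment."""

    ALL = "all"
    VITREOUS = "vitreous"
    RETINA = "retina"
    CHOROID = "choroid"
    SCLERA = "sclera"

    @property
    def code(self) -> CompartmentCode | None:
        """The compartment code for per-compartment scopes, None for ALL."""
        if self is Scope.ALL:
            return None
        return CompartmentCode[self.name]


COMPARTMENT_SCOPES = (Scope.VITREOUS, Scope.RETINA, Scope.CHOROID, Scope.SCLERA)


def _check_shapes(a: CompartmentLabelMap, b: CompartmentLabelMap) -> None:
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")


def hamming(a: CompartmentLabelMap, b: CompartmentLabelMap) -> float:
    """Fraction of pixels labeled differently (4-way comparison)."""
    _check_shapes(a, b)
    return float(np.count_nonzero(a.labels != b.labels)) / a.labels.size


def compartment_hamming(
    a: CompartmentLabelMap, b: CompartmentLabelMap, code: CompartmentCode
) -> float:
    """Hamming distance between the binary membership maps of one compartment.

    The denominator remains the total pixel count, regardless of how large
    the compartment is.
    """
    _check_shapes(a, b)
    return float(np.count_nonzero(a.binary(code) != b.binary(code))) / a.labels.size


def _scoped_distance(a: CompartmentLabelMap, b: CompartmentLabelMap, scope: Scope) -> float:
    code = scope.code
    if code is None:
        return hamming(a, b)
    return compartment_hamming(a, b, code)


_TABLE_COLUMNS = ["scan_id", "grading_a", "grading_b", "scope", "distance"]


@dataclass
class DistanceTable:
    """Per-scan, per-pair, per-scope Hamming distances.

    Each unordered pair is stored once; lookups are symmetric.  Backed by
    a pandas DataFrame with columns
    ``scan_id, grading_a, grading_b, scope, distance``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"distance table missing columns {missing}")
        d = self.frame["distance"]
        if ((d < 0) | (d > 1)).any():
            raise ValidationError("distances must lie in [0, 1]")
        if (self.frame["grading_a"] == self.frame["grading_b"]).any():
            raise ValidationError("self-pairs must not be stored")
        self.frame = self.frame[_TABLE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def scan_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["scan_id"]))

    @property
    def pairs(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for a, b in zip(self.frame["grading_a"], self.frame["grading_b"]):
            seen.setdefault((a, b), None)
        return list(seen)

    def select(
        self, scope: Scope, pair: tuple[str, str] | None = None
    ) -> pd.DataFrame:
        """Rows for one scope (and optionally one unordered pair)."""
        sub = self.frame[self.frame["scope"] == scope.value]
        if pair is not None:
            a, b = pair
            mask = ((sub["grading_a"] == a) & (sub["grading_b"] == b)) | (
                (sub["grading_a"] == b) & (sub["grading_b"] == a)
            )
            sub = sub[mask]
        return sub

    def distance(self, scan_id: str, a: str, b: str, scope: Scope) -> float:
        sub = self.select(scope, (a, b))
        sub = sub[sub["scan_id"] == scan_id]
        if len(sub) != 1:
            raise ValidationError(
                f"expected exactly one record for (scan {scan_id!r}, pair "
                f"({a!r}, {b!r}), scope {scope.value}); found {len(sub)}"
            )
        return float(sub["distance"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceTable":
        return cls(pd.read_csv(path, dtype={"scan_id": str}))


@dataclass
class MeanDistanceMatrix:
    """Mean pairwise Hamming distances over a common scan set.

    Symmetric with zero diagonal; satisfies the triangle inequality because
    it is an average of per-scan metrics.
    """

    ids: list[str]
    values: np.ndarray
    scope: Scope
    n_scans: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if values.shape != (k, k):
            raise ValidationError(f"expected a {k}x{k} matrix, got {values.shape}")
        if not np.allclose(values, values.T):
            raise ValidationError("mean distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValidationError("mean distance matrix must have a zero diagonal")
        if (values < 0).any():
            raise ValidationError("mean distances must be non-negative")
        self.values = values

    def entry(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def as_percent(self) -> np.ndarray:
        return self.values * 100.0

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        values = self.as_percent() if percent else self.values
        return pd.DataFrame(values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path, percent: bool = False) -> None:
        self.to_frame(percent=percent).to_csv(path, index_label="grading_id")

    @classmethod
    def from_csv(cls, path: str | Path, scope: Scope, n_scans: int) -> "MeanDistanceMatrix":
        frame = pd.read_csv(path, index_col="grading_id")
        return cls(list(frame.columns), frame.to_numpy(), scope, n_scans)


def build_distance_table(
    ensemble: GradingEnsemble,
    pairs: Sequence[tuple[str, str]] | None = None,
    scopes: Sequence[Scope] | None = None,
) -> DistanceTable:
    """Compute one distance record per (scan, pair, scope).

    Default pairs are all unordered pairs of the ensemble's gradings in
    registration order (graders first, model last); default scopes are
    ALL plus the four compartments.
    """
    ids = ensemble.grading_ids
    if pairs is None:
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    if scopes is None:
        scopes = [Scope.ALL, *COMPARTMENT_SCOPES]
    scan_ids = ensemble.scan_ids
    for a, b in pairs:
        ensemble.require_complete([a, b], scan_ids)
    records = []
    for scan_id in scan_ids:
        for a, b in pairs:
            ma = ensemble.get(scan_id, a)
            mb = ensemble.get(scan_id, b)
            for scope in scopes:
                records.append(
                    (scan_id, a, b, scope.value, _scoped_distance(ma, mb, scope))
                )
    return DistanceTable(pd.DataFrame(records, columns=_TABLE_COLUMNS))


def mean_distance_matrix(
    table: DistanceTable,
    scope: Scope,
    ids: Sequence[str] | None = None,
) -> MeanDistanceMatrix:
    """Average per-scan distances into a symmetric k x k matrix.

    Every pair must cover the same scan set; otherwise the averages would
    not be comparable and an error is raised.
    """
    sub = table.select(scope)
    if sub.empty:
        raise ValidationError(f"no records for scope {scope.value}")
    if ids is None:
        seen: dict[str, None] = {}
        for a, b in zip(sub["grading_a"], sub["grading_b"]):
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        ids = list(seen)
    ids = list(ids)
    k = len(ids)
    values = np.zeros((k, k))
    scan_sets: list[frozenset[str]] = []
    for i in range(k):
        for j in range(i + 1, k):
            pair_rows = table.select(scope, (ids[i], ids[j]))
            if pair_rows.empty:
                raise ValidationError(
                    f"no records for pair ({ids[i]!r}, {ids[j]!r}) at scope {scope.value}"
                )
            scan_sets.append(frozenset(pair_rows["scan_id"]))
            values[i, j] = values[j, i] = float(pair_rows["distance"].mean())
    if len(set(scan_sets)) > 1:
        raise ValidationError(
            "pairs cover unequal scan sets; means would not be comparable"
        )
    return MeanDistanceMatrix(ids, values, scope, n_scans=len(scan_sets[0]))


def _per_scan_means(
    table: DistanceTable,
    pairs: Iterable[tuple[str, str]],
    scope: Scope = Scope.ALL,
) -> pd.Series:
    """Per-scan mean distance over the given pairs (complete records required)."""
    pairs = list(pairs)
    frames = []
    for pair in pairs:
        rows = table.select(scope, pair)
        frames.append(rows.set_index("scan_id")["distance"])
    stacked = pd.concat(frames, axis=1)
    if stacked.isna().any().any():
        missing = stacked[stacked.isna().any(axis=1)].index.tolist()
        raise ValidationError(
            f"incomplete records for scans {missing} over pairs {pairs}"
        )
    return stacked.mean(axis=1)


def fraction_model_closer(
    table: DistanceTable,
    grader_ids: Sequence[str],
    model_id: str,
    scope: Scope = Scope.ALL,
) -> float:
    """Fraction of scans where the mean grader–model distance is strictly
    smaller than the mean inter-grader distance.

    Ties count as not-closer.
    """
    grader_ids = list(grader_ids)
    inter = [
        (grader_ids[i], grader_ids[j])
        for i in range(len(grader_ids))
        for j in range(i + 1, len(grader_ids))
    ]
    versus = [(g, model_id) for g in grader_ids]
    inter_means = _per_scan_means(table, inter, scope)
    model_means = _per_scan_means(table, versus, scope)
    if set(inter_means.index) != set(model_means.index):
        raise ValidationError("inter-grader and grader-model records cover different scans")
    model_means = model_means.reindex(inter_means.index)
    return float((model_means < inter_means).mean())
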