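"""Compartment label maps and boundary-line annotations.

A B-scan segmentation assigns every pixel to one of four anatomical
compartments — vitreous, retina, choroid, sclera — separated (top to
bottom) by three boundary lines: the internal limiting membrane (ILM),
the inner border of the choriocapillaris (CCi), and the choroid–sclera
interface (CSI).  This module provides the domain types for both the
pixel-wise representation (:class:`CompartmentLabelMap`) and the
line-wise representation (:class:`BoundarySet`), conversion between
them, and plain-file I/O (indexed PNG for maps, CSV for boundaries).

Conventions
-----------
Row 0 is the image top (vitreous side); indexing is 0-based.  A boundary
row belongs to the compartment *below* the line: a pixel at row ``r`` in
column ``c`` is vitreous iff ``r < ilm[c]``, retina iff
``ilm[c] <= r < cci[c]``, choroid iff ``cci[c] <= r < csi[c]``, and
sclera otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import FormatError, ValidationError

__all__ = [
    "CompartmentCode",
    "COMPARTMENT_PALETTE",
    "CompartmentLabelMap",
    "BoundarySet",
    "GradingEnsemble",
    "lines_to_labelmap",
    "labelmap_to_binary",
    "read_labelmap",
    "write_labelmap",
    "read_boundaries",
    "write_boundaries",
]


class CompartmentCode(IntEnum):
    """The four anatomical compartments of a retinal B-scan, top to bottom."""

    VITREOUS = 0
    RETINA = 1
    CHOROID = 2
    SCLERA = 3


#: Display palette (RGB) for label PNGs: vitreous orange, retina blue,
#: choroid yellow, sclera gray.  Visualization only — files store codes 0–3.
COMPARTMENT_PALETTE: dict[CompartmentCode, tuple[int, int, int]] = {
    CompartmentCode.VITREOUS: (235, 140, 35),
    CompartmentCode.RETINA: (45, 90, 200),
    CompartmentCode.CHOROID: (240, 210, 60),
    CompartmentCode.SCLERA: (150, 150, 150),
}

_VALID_CODES = frozenset(int(c) for c in CompartmentCode)


@dataclass(frozen=True)
class CompartmentLabelMap:
    """A 2D grid of compartment codes for one grading of one scan.

    Parameters
    ----------
    labels
        ``(H, W)`` array of integer codes in ``{0, 1, 2, 3}``.
    scan_id, grading_id
        Free-form identifiers (e.g. ``"scan007"``, ``"g2"`` or ``"cnn"``).
    """

    labels: np.ndarray
    scan_id: str = ""
    grading_id: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or labels.shape[0] < 1 or labels.shape[1] < 1:
            raise ValidationError(
                f"label grid must be 2D with positive shape, got {labels.shape}"
            )
        bad = np.setdiff1d(np.unique(labels), sorted(_VALID_CODES))
        if bad.size:
            raise ValidationError(
                f"invalid compartment codes {bad.tolist()}; expected values in 0..3"
            )
        object.__setattr__(self, "labels", labels.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def binary(self, code: CompartmentCode) -> np.ndarray:
        """Binary membership map for one compartment."""
        return labelmap_to_binary(self, code)


@dataclass(frozen=True)
class BoundarySet:
    """Per-column row positions of the ILM, CCi and CSI lines.

    Invariant: ``0 <= ilm[c] <= cci[c] <= csi[c]`` for every column; when a
    grid height is known, additionally ``csi[c] <= H``.  Boundaries may
    touch, producing a zero-height compartment.
    """

    ilm: np.ndarray
    cci: np.ndarray
    csi: np.ndarray

    def __post_init__(self) -> None:
        arrays = []
        for name in ("ilm", "cci", "csi"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.ndim != 1:
                raise ValidationError(f"{name} must be one-dimensional")
            arrays.append(arr)
            object.__setattr__(self, name, arr)
        if not (arrays[0].size == arrays[1].size == arrays[2].size):
            raise ValidationError(
                "boundary arrays have mismatched lengths: "
                f"ilm={arrays[0].size}, cci={arrays[1].size}, csi={arrays[2].size}"
            )
        self.validate()

    @property
    def width(self) -> int:
        return self.ilm.size

    def validate(self, height: int | None = None) -> None:
        """Check ordering (and optionally the grid height bound).

        Raises :class:`ValidationError` naming the first offending column.
        """
        for upper, lower, pair in (
            (self.ilm, self.cci, "ilm > cci"),
            (self.cci, self.csi, "cci > csi"),
        ):
            crossing = np.nonzero(upper > lower)[0]
            if crossing.size:
                c = int(crossing[0])
                raise ValidationError(
                    f"boundaries cross ({pair}) first at column {c}: "
                    f"{upper[c]:g} > {lower[c]:g}"
                )
        negative = np.nonzero(self.ilm < 0)[0]
        if negative.size:
            raise ValidationError(
                f"ilm below 0 first at column {int(negative[0])}"
            )
        if height is not None:
            over = np.nonzero(self.csi > height)[0]
            if over.size:
                c = int(over[0])
                raise ValidationError(
                    f"csi exceeds grid height {height} first at column {c}: "
                    f"{self.csi[c]:g}"
                )

    def as_array(self) -> np.ndarray:
        """``(3, W)`` stacked array in ILM, CCi, CSI order."""
        return np.stack([self.ilm, self.cci, self.csi])


def lines_to_labelmap(
    boundaries: BoundarySet,
    height: int,
    width: int,
    scan_id: str = "",
    grading_id: str = "",
) -> CompartmentLabelMap:
    """Rasterize three boundary lines into a four-compartment label map.

    Pixels between two lines are labeled as the compartment located
    between those lines; a boundary row itself belongs to the compartment
    below the line (vitreous lies strictly above the ILM).
    """
    if boundaries.width != width:
        raise ValidationError(
            f"boundary arrays have length {boundaries.width}, expected width {width}"
        )
    boundaries.validate(height=height)
    rows = np.arange(height, dtype=float)[:, None]
    labels = (
        (rows >= boundaries.ilm[None, :]).astype(np.uint8)
        + (rows >= boundaries.cci[None, :])
        + (rows >= boundaries.csi[None, :])
    )
    return CompartmentLabelMap(labels, scan_id=scan_id, grading_id=grading_id)


def labelmap_to_binary(m: CompartmentLabelMap, code: CompartmentCode) -> np.ndarray:
    """Binary membership map: 1 where the pixel belongs to ``code``."""
    return (m.labels == int(code)).astype(np.uint8)


def write_labelmap(m: CompartmentLabelMap, path: str | Path, palette: bool = False) -> None:
    """Write a label map as an 8-bit PNG storing codes 0–3.

    With ``palette=True`` the PNG is paletted with the display colors of
    :data:`COMPARTMENT_PALETTE`; pixel values (palette indices) are still
    the compartment codes, so the round trip is unaffected.
    """
    img = Image.fromarray(m.labels, mode="L")
    if palette:
        img = img.convert("P")
        flat = [0] * (256 * 3)
        for code, rgb in COMPARTMENT_PALETTE.items():
            flat[3 * int(code) : 3 * int(code) + 3] = list(rgb)
        img.putpalette(flat)
    img.save(path, format="PNG")


def read_labelmap(
    path: str | Path, scan_id: str = "", grading_id: str = ""
) -> CompartmentLabelMap:
    """Read a label map from an 8-bit grayscale or paletted PNG.

    Paletted PNGs are decoded by palette *index*, not by color, so any
    palette whose indices are the compartment codes round-trips exactly.
    """
    path = Path(path)
    if not scan_id:
        scan_id = path.stem
    with Image.open(path) as img:
        if img.format != "PNG":
            raise FormatError(f"{path}: expected a PNG file, got {img.format}")
        if img.mode not in ("L", "P"):
            raise FormatError(
                f"{path}: expected 8-bit grayscale or paletted PNG, got mode {img.mode}"
            )
        labels = np.asarray(img, dtype=np.uint8)
    bad = sorted(set(np.unique(labels).tolist()) - _VALID_CODES)
    if bad:
        raise FormatError(
            f"{path}: pixel values {bad} outside the compartment code set 0..3"
        )
    return CompartmentLabelMap(labels, scan_id=scan_id, grading_id=grading_id)


_BOUNDARY_COLUMNS = ["scan_id", "grading_id", "column", "ilm", "cci", "csi"]


def write_boundaries(
    records: Iterable[tuple[str, str, BoundarySet]], path: str | Path
) -> None:
    """Write ``(scan_id, grading_id, BoundarySet)`` records as CSV.

    One row per image column, header ``scan_id,grading_id,column,ilm,cci,csi``.
    """
    frames = []
    for scan_id, grading_id, b in records:
        frames.append(
            pd.DataFrame(
                {
                    "scan_id": scan_id,
                    "grading_id": grading_id,
                    "column": np.arange(b.width),
                    "ilm": b.ilm,
                    "cci": b.cci,
                    "csi": b.csi,
                }
            )
        )
    if not frames:
        raise ValidationError("no boundary records to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_boundaries(path: str | Path) -> list[tuple[str, str, BoundarySet]]:
    """Read boundary records from CSV (inverse of :func:`write_boundaries`).

    Each ``(scan_id, grading_id)`` group must cover columns ``0..W-1``
    without gaps; ordering invariants are validated per column.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    missing = [c for c in _BOUNDARY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out: list[tuple[str, str, BoundarySet]] = []
    for (scan_id, grading_id), group in frame.groupby(
        ["scan_id", "grading_id"], sort=False
    ):
        group = group.sort_values("column")
        cols = group["column"].to_numpy()
        expected = np.arange(cols.size)
        if not np.array_equal(cols, expected):
            raise ValidationError(
                f"{path}: ({scan_id}, {grading_id}) does not cover columns "
                f"0..{cols.size - 1} contiguously"
            )
        try:
            b = BoundarySet(
                group["ilm"].to_numpy(),
                group["cci"].to_numpy(),
                group["csi"].to_numpy(),
            )
        except ValidationError as exc:
            raise ValidationError(f"({scan_id}, {grading_id}): {exc}") from exc
        out.append((str(scan_id), str(grading_id), b))
    return out


@dataclass
class GradingEnsemble:
    """Label maps indexed by ``(scan_id, grading_id)`` for several graders
    and optionally one model, all on a common grid.

    Ensemble-level operations assume a complete block design: every
    grading present for every scan.
    """

    grader_ids: list[str]
    model_id: str | None = None
    maps: dict[tuple[str, str], CompartmentLabelMap] = field(default_factory=dict)

    @property
    def grading_ids(self) -> list[str]:
        """All grading identifiers: graders first, then the model."""
        ids = list(self.grader_ids)
        if self.model_id is not None:
            ids.append(self.model_id)
        return ids

    @property
    def scan_ids(self) -> list[str]:
        """Scan identifiers in insertion order."""
        seen: dict[str, None] = {}
        for scan_id, _ in self.maps:
            seen.setdefault(scan_id, None)
        return list(seen)

    @property
    def shape(self) -> tuple[int, int] | None:
        for m in self.maps.values():
            return m.shape
        return None

    def add(self, m: CompartmentLabelMap) -> None:
        key = (m.scan_id, m.grading_id)
        if key in self.maps:
            raise ValidationError(f"duplicate map for (scan, grading) = {key}")
        if m.grading_id not in self.grading_ids:
            raise ValidationError(
                f"unknown grading_id {m.grading_id!r}; "
                f"registered gradings: {self.grading_ids}"
            )
        shape = self.shape
        if shape is not None and m.shape != shape:
            raise ValidationError(
                f"map {key} has shape {m.shape}, ensemble grid is {shape}"
            )
        self.maps[key] = m

    def get(self, scan_id: str, grading_id: str) -> CompartmentLabelMap:
        try:
            return self.maps[(scan_id, grading_id)]
        except KeyError:
            raise ValidationError(
                f"missing map for (scan {scan_id!r}, grading {grading_id!r})"
            ) from None

    def require_complete(
        self,
        grading_ids: Sequence[str] | None = None,
        scan_ids: Sequence[str] | None = None,
    ) -> None:
        """Assert the complete block design over the given gradings/scans."""
        grading_ids = list(grading_ids) if grading_ids is not None else self.grading_ids
        scan_ids = list(scan_ids) if scan_ids is not None else self.scan_ids
        for scan_id in scan_ids:
            for grading_id in grading_ids:
                if (scan_id, grading_id) not in self.maps:
                    raise ValidationError(
                        f"incomplete ensemble: missing map for "
                        f"(scan {scan_id!r}, grading {grading_id!r})"
                    )

    def any_empty_compartment(self) -> bool:
        """True if any map lacks one of the four compartments entirely.

        The study's inclusion criteria require all four compartments to be
        visible on every scan; callers emit a warning when this is violated.
        """
        for m in self.maps.values():
            if np.unique(m.labels).size < 4:
                return True
        return False
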