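"""Reader/writer for the DLC landmark-table CSV dialect.

The dialect has three header rows — ``scorer``, ``bodyparts``, ``coords`` —
with an ``x``, ``y``, ``likelihood`` column triple per tracked point, and
one row per video frame indexed by frame number. In-memory tables use a
two-level column MultiIndex ``(bodyparts, coords)``; the scorer level is
added on write and stripped on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["RAW_LANDMARKS", "COORDS", "write_dlc_csv", "read_dlc_csv", "DLCFormatError"]

# The raw tracked point set: four pupil-rim corners per eye (averaged into a
# pupil center downstream), the four eye corners, and the upper-lip/philtrum
# point. 13 points -> 39 data columns.
RAW_LANDMARKS: tuple[str, ...] = (
    "left_pupil_corner_1",
    "left_pupil_corner_2",
    "left_pupil_corner_3",
    "left_pupil_corner_4",
    "right_pupil_corner_1",
    "right_pupil_corner_2",
    "right_pupil_corner_3",
    "right_pupil_corner_4",
    "left_lateral_corner",
    "left_medial_corner",
    "right_medial_corner",
    "right_lateral_corner",
    "lip_philtrum",
)

COORDS: tuple[str, ...] = ("x", "y", "likelihood")


class DLCFormatError(ValueError):
    """Raised when a file does not conform to the landmark-table dialect."""


def empty_table(landmarks: tuple[str, ...] = RAW_LANDMARKS) -> pd.DataFrame:
    columns = pd.MultiIndex.from_product(
        [landmarks, COORDS], names=["bodyparts", "coords"]
    )
    return pd.DataFrame(columns=columns, index=pd.Index([], name="frame", dtype=int))


def write_dlc_csv(table: pd.DataFrame, path: str | Path, scorer: str = "gazekit") -> None:
    """Write a landmark table with the three-row scorer/bodyparts/coords header."""
    if table.columns.nlevels != 2:
        raise DLCFormatError("table must have (bodyparts, coords) columns")
    out = table.copy()
    out.columns = pd.MultiIndex.from_tuples(
        [(scorer, bp, c) for bp, c in table.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    out.index.name = "frame"
    out.to_csv(path)


def read_dlc_csv(path: str | Path) -> pd.DataFrame:
    """Read a landmark table; returns (bodyparts, coords) columns, frame index."""
    try:
        table = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, IndexError) as exc:
        raise DLCFormatError(f"{path}: not a three-header-row landmark CSV: {exc}") from exc
    names = list(table.columns.names)
    if names != ["scorer", "bodyparts", "coords"]:
        raise DLCFormatError(
            f"{path}: header rows must be named scorer/bodyparts/coords, got {names}"
        )
    table.columns = table.columns.droplevel("scorer")
    for bodypart in table.columns.get_level_values("bodyparts").unique():
        coords = tuple(table[bodypart].columns)
        if coords != COORDS:
            raise DLCFormatError(
                f"{path}: bodypart {bodypart!r} has coords row {coords}, expected {COORDS}"
            )
    table.index = table.index.astype(int)
    table.index.name = "frame"
    return table.astype(float)
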