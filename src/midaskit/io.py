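"""Data model and I/O for equilibrium-dialysis metabolite-interaction screens.

A MIDAS-style screen dialyses a purified protein against pooled metabolite
standards and reads out, by flow-injection mass spectrometry (FIA-MS), how
much of each metabolite ends up on the protein side versus the metabolite
side of the membrane.  The on-disk exchange formats here are deliberately
plain: UTF-8, tab-separated, mandatory header row, ``.`` decimal separator.

Two tables travel through the pipeline:

* a *metabolite library* (``metabolite_id``, ``name``, ``mass_da``,
  ``pool_id``) describing the screening pools, and
* a *measurement table* (``protein_id``, ``metabolite_id``, ``chamber``,
  ``dialysis_rep``, ``tech_rep``, ``auc``) holding one area-under-the-curve
  value per FIA-MS injection.

Blank injections (``chamber == "blank"``) are accepted and stored but are
excluded from scoring by default; an optional blank-median subtraction is
available downstream behind a flag.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHAMBERS",
    "LIBRARY_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "MetaboliteEntry",
    "MetaboliteLibrary",
    "ScreenDesign",
    "IntensityTrace",
    "MeasurementTable",
    "integrate_trace",
    "read_library",
    "write_library",
    "read_measurements",
    "write_measurements",
]

#: Valid chamber tokens for one injection.
CHAMBERS = ("protein", "metabolite", "blank")

LIBRARY_COLUMNS = ["metabolite_id", "name", "mass_da", "pool_id"]
MEASUREMENT_COLUMNS = [
    "protein_id",
    "metabolite_id",
    "chamber",
    "dialysis_rep",
    "tech_rep",
    "auc",
]


@dataclasses.dataclass(frozen=True)
class MetaboliteEntry:
    """One metabolite standard in the screening library."""

    metabolite_id: str
    name: str = ""
    mass_da: float | None = None
    pool_id: int = 1


class MetaboliteLibrary:
    """A validated collection of :class:`MetaboliteEntry`.

    Invariants: ``metabolite_id`` is unique and every entry carries a pool
    assignment (``pool_id >= 1``).
    """

    def __init__(self, entries: Iterable[MetaboliteEntry]):
        entries = list(entries)
        seen: dict[str, int] = {}
        for i, e in enumerate(entries):
            if not e.metabolite_id:
                raise ValueError(f"entry {i}: empty metabolite_id")
            if e.metabolite_id in seen:
                raise ValueError(
                    f"duplicate metabolite_id {e.metabolite_id!r} "
                    f"(rows {seen[e.metabolite_id]} and {i})"
                )
            if e.pool_id is None or int(e.pool_id) < 1:
                raise ValueError(
                    f"entry {i} ({e.metabolite_id!r}): missing or invalid pool_id"
                )
            seen[e.metabolite_id] = i
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.metabolite_id for e in self.entries]

    @property
    def n_pools(self) -> int:
        return len({e.pool_id for e in self.entries})

    @property
    def pools(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for e in self.entries:
            out.setdefault(int(e.pool_id), []).append(e.metabolite_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite_id": [e.metabolite_id for e in self.entries],
                "name": [e.name for e in self.entries],
                "mass_da": [e.mass_da for e in self.entries],
                "pool_id": [int(e.pool_id) for e in self.entries],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MetaboliteLibrary":
        required = {"metabolite_id", "pool_id"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"library table missing columns: {sorted(missing)}")
        entries = []
        for i, row in enumerate(frame.itertuples(index=False)):
            pool = getattr(row, "pool_id")
            if pool is None or (isinstance(pool, float) and np.isnan(pool)):
                raise ValueError(f"row {i}: missing pool_id")
            mass = getattr(row, "mass_da", None)
            if mass is not None and isinstance(mass, float) and np.isnan(mass):
                mass = None
            entries.append(
                MetaboliteEntry(
                    metabolite_id=str(getattr(row, "metabolite_id")),
                    name=str(getattr(row, "name", "") or ""),
                    mass_da=mass,
                    pool_id=int(pool),
                )
            )
        return cls(entries)


@dataclasses.dataclass
class ScreenDesign:
    """Layout of one screening campaign.

    The reference design dialyses each target in triplicate against four
    metabolite pools at 50 µM per metabolite, supplemented with ThDP and
    MgCl2 cofactors, and injects each dialysate in technical triplicate.
    """

    protein_ids: Sequence[str]
    n_pools: int = 4
    pool_concentration_uM: float = 50.0
    n_dialysis_reps: int = 3
    n_tech_reps: int = 3
    cofactor_note: str = "1 mM ThDP, 1 mM MgCl2"

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        if not self.protein_ids:
            raise ValueError("design needs at least one protein")
        for field in ("n_pools", "n_dialysis_reps", "n_tech_reps"):
            if int(getattr(self, field)) < 1:
                raise ValueError(f"{field} must be >= 1")


@dataclasses.dataclass(frozen=True)
class IntensityTrace:
    """A raw injection trace: intensity versus time.

    Supports AUC computation when integrated areas are not supplied
    directly by the acquisition software.
    """

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("times and intensities must be 1-D and equal length")
        if len(t) < 2:
            raise ValueError("a trace needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("intensities must be nonnegative")


def integrate_trace(trace: IntensityTrace) -> float:
    """Trapezoidal area under an intensity trace (the injection AUC)."""
    return float(np.trapezoid(trace.intensities, trace.times))


class MeasurementTable:
    """Per-injection AUC table for a screen.

    Wraps a :class:`pandas.DataFrame` with columns
    ``protein_id, metabolite_id, chamber, dialysis_rep, tech_rep, auc`` and
    enforces the record invariants (nonnegative AUC, known chamber token,
    unique injection key).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(MEASUREMENT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"measurement table missing columns: {sorted(missing)}")
        frame = frame[MEASUREMENT_COLUMNS].copy()
        frame["protein_id"] = frame["protein_id"].astype(str)
        frame["metabolite_id"] = frame["metabolite_id"].astype(str)
        frame["chamber"] = frame["chamber"].astype(str)
        frame["dialysis_rep"] = frame["dialysis_rep"].astype(int)
        frame["tech_rep"] = frame["tech_rep"].astype(int)
        frame["auc"] = frame["auc"].astype(float)

        bad = ~frame["chamber"].isin(CHAMBERS)
        if bad.any():
            tok = frame.loc[bad, "chamber"].iloc[0]
            raise ValueError(f"unknown chamber token {tok!r}")
        if (frame["auc"] < 0).any():
            i = int(np.flatnonzero(frame["auc"].to_numpy() < 0)[0])
            raise ValueError(f"negative auc at row {i}")
        key = ["protein_id", "metabolite_id", "chamber", "dialysis_rep", "tech_rep"]
        dup = frame.duplicated(key)
        if dup.any():
            row = frame.loc[dup].iloc[0]
            raise ValueError(
                "duplicate injection record for "
                + "/".join(str(row[c]) for c in key)
            )
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    def completeness_report(
        self,
        design: ScreenDesign,
        library: MetaboliteLibrary,
        chambers: Sequence[str] = ("protein", "metabolite"),
    ) -> pd.DataFrame:
        """Missing (protein, metabolite, chamber, dialysis_rep, tech_rep) cells.

        Returns an empty frame when the screen is complete with respect to
        the design/library cross product.
        """
        expected = pd.MultiIndex.from_product(
            [
                list(design.protein_ids),
                library.ids,
                list(chambers),
                range(1, design.n_dialysis_reps + 1),
                range(1, design.n_tech_reps + 1),
            ],
            names=["protein_id", "metabolite_id", "chamber", "dialysis_rep", "tech_rep"],
        )
        have = pd.MultiIndex.from_frame(
            self.frame[
                ["protein_id", "metabolite_id", "chamber", "dialysis_rep", "tech_rep"]
            ]
        )
        missing = expected.difference(have)
        return missing.to_frame(index=False)


def read_library(path: str | Path) -> MetaboliteLibrary:
    """Read a metabolite library TSV (``metabolite_id``, ``pool_id`` required)."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"metabolite_id": str}, float_precision="round_trip"
    )
    return MetaboliteLibrary.from_frame(frame)


def write_library(library: MetaboliteLibrary, path: str | Path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


def read_measurements(
    path: str | Path, design: ScreenDesign | None = None
) -> MeasurementTable:
    """Read a per-injection AUC TSV and validate it against the record schema."""
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"protein_id": str, "metabolite_id": str, "chamber": str},
        float_precision="round_trip",
    )
    return MeasurementTable(frame)


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write a measurement TSV; float formatting round-trips bit-exactly."""
    table.frame.to_csv(path, sep="\t", index=False)
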