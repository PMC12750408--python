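"""Spectrum containers and wide-table I/O.

A :class:`Spectrum` pairs a strictly increasing Raman-shift grid (cm^-1)
with intensities and identity metadata.  Input files are wide delimited
tables: one ``ID`` column plus one numeric column per Raman shift, one row
per acquired spectrum.  Rows sharing an ID belong to one physical sample
(e.g. one hair sample measured at several spots).  The analysis window is
450-1650 cm^-1; the canonical grid used by every model is that window at
1 cm^-1 spacing (1201 features).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    CoverageError,
    DataError,
    GridRangeError,
    SchemaError,
    SpectrumParseError,
    UsageError,
)

#: Analysis window bounds, cm^-1.
TRIM_LOW = 450.0
TRIM_HIGH = 1650.0

#: Canonical feature grid: 450..1650 cm^-1 inclusive at 1 cm^-1 (1201 points).
CANONICAL_GRID: np.ndarray = np.arange(450.0, 1651.0, 1.0)
CANONICAL_GRID.setflags(write=False)


@dataclass
class Spectrum:
    """One spectrum: wavenumbers (cm^-1), intensities, and identity."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    spectrum_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise DataError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise DataError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise DataError("non-finite value in spectrum")
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise DataError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.wavenumbers = np.array(out.wavenumbers, dtype=float)
        out.intensities = np.array(out.intensities, dtype=float)
        return out


@dataclass
class SpectrumTable:
    """A collection of spectra, optionally on one shared grid."""

    spectra: list[Spectrum] = field(default_factory=list)
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)
            for s in self.spectra:
                if not np.array_equal(s.wavenumbers, self.grid):
                    raise AlignmentError(
                        f"spectrum {s.spectrum_id!r} is not on the table grid"
                    )
        ids = [s.spectrum_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise DataError("spectrum_ids must be unique within a table")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.sample_id)
        return list(seen)

    def by_sample(self) -> dict[str, list[Spectrum]]:
        out: dict[str, list[Spectrum]] = {}
        for s in self.spectra:
            out.setdefault(s.sample_id, []).append(s)
        return out

    def to_matrix(self) -> np.ndarray:
        """Stack intensities into an (n_spectra, n_points) matrix."""
        if self.grid is None:
            raise AlignmentError("table has no shared grid; resample first")
        return np.vstack([s.intensities for s in self.spectra])

    @classmethod
    def from_matrix(
        cls,
        X: np.ndarray,
        grid: np.ndarray,
        spectrum_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "SpectrumTable":
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        spectrum_ids = list(spectrum_ids) if spectrum_ids is not None else [
            f"S{i}" for i in range(n)
        ]
        sample_ids = list(sample_ids) if sample_ids is not None else spectrum_ids
        spectra = [
            Spectrum(np.asarray(grid, float), X[i], spectrum_ids[i], sample_ids[i])
            for i in range(n)
        ]
        return cls(spectra, grid=np.asarray(grid, float))


# ---------------------------------------------------------------------------
# reading / writing wide tables
# ---------------------------------------------------------------------------

def _open_source(source) -> pd.DataFrame:
    # header=None keeps duplicate column labels detectable (pandas would
    # otherwise silently mangle them); row 0 is restored as the header below.
    if isinstance(source, (str, Path)):
        raw = pd.read_csv(source, sep=None, engine="python", dtype=str,
                          header=None)
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        raw = pd.read_csv(source, sep=None, engine="python", dtype=str,
                          header=None)
    else:
        raise SchemaError(f"unsupported spectra source: {type(source)!r}")
    if raw.shape[0] < 1:
        raise SchemaError("empty spectra table")
    header = [str(c).strip() for c in raw.iloc[0]]
    df = raw.iloc[1:].reset_index(drop=True)
    df.columns = pd.Index(header)
    return df


def read_spectra_table(
    source,
    id_column: str = "ID",
    check_coverage: bool = True,
) -> SpectrumTable:
    """Read a wide delimited table of spectra.

    The header must contain ``id_column`` plus >=2 columns whose names parse
    as numeric wavenumbers.  The delimiter is auto-detected among
    comma/tab/semicolon.  Wavenumber columns are sorted ascending regardless
    of header order, rows sharing an ID become spectra of one sample, and
    with ``check_coverage`` the wavenumbers must span the 450-1650 cm^-1
    analysis window.
    """
    df = _open_source(source)
    if id_column not in df.columns:
        raise SchemaError(f"missing id column {id_column!r} in header")
    if list(df.columns).count(id_column) > 1:
        raise SchemaError(f"duplicate id column {id_column!r} in header")

    wn_cols: list[tuple[float, str]] = []
    for col in df.columns:
        if col == id_column:
            continue
        try:
            wn_cols.append((float(col), col))
        except ValueError as exc:
            raise SchemaError(f"non-numeric wavenumber header {col!r}") from exc
    if len(wn_cols) < 2:
        raise SchemaError("need at least two numeric wavenumber columns")
    wn_values = [w for w, _ in wn_cols]
    if len(set(wn_values)) != len(wn_values):
        raise SchemaError("duplicate wavenumber headers are not supported")
    wn_cols.sort(key=lambda t: t[0])
    wavenumbers = np.array([w for w, _ in wn_cols], dtype=float)
    ordered_cols = [c for _, c in wn_cols]

    if check_coverage and not (
        wavenumbers[0] <= TRIM_LOW and wavenumbers[-1] >= TRIM_HIGH
    ):
        raise CoverageError(
            f"wavenumber coverage {wavenumbers[0]:g}-{wavenumbers[-1]:g} cm^-1 "
            f"does not span the required {TRIM_LOW:g}-{TRIM_HIGH:g} cm^-1 window"
        )

    spectra: list[Spectrum] = []
    counts: dict[str, int] = {}
    for row_idx, row in df.iterrows():
        sample_id = str(row[id_column])
        values = np.empty(wavenumbers.size)
        for j, col in enumerate(ordered_cols):
            cell = row[col]
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError("missing cell")
                values[j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise SpectrumParseError(
                    f"row {row_idx} ({sample_id!r}), column {col!r}: "
                    f"cannot parse intensity {cell!r}"
                ) from exc
        k = counts.get(sample_id, 0)
        counts[sample_id] = k + 1
        spectra.append(
            Spectrum(wavenumbers, values, f"{sample_id}_{k}", sample_id)
        )
    return SpectrumTable(spectra, grid=wavenumbers)


def write_spectra_table(table: SpectrumTable, sink, id_column: str = "ID") -> None:
    """Write a shared-grid table in the wide input format (CSV)."""
    if table.grid is None:
        raise AlignmentError("cannot write a table without a shared grid")
    cols = [repr(float(w)) for w in table.grid]
    df = pd.DataFrame(
        [s.intensities for s in table.spectra], columns=cols
    )
    df.insert(0, id_column, [s.sample_id for s in table.spectra])
    df.to_csv(sink, index=False, float_format="%.12g")


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation of a spectrum onto ``grid`` (metadata kept).

    ``grid`` must lie inside the spectrum's support; extrapolation is
    refused because baseline-corrected intensities outside the measured
    window are not defined.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise GridRangeError("empty target grid")
    if grid[0] < s.wavenumbers[0] or grid[-1] > s.wavenumbers[-1]:
        raise GridRangeError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] extends beyond spectrum support "
            f"[{s.wavenumbers[0]:g}, {s.wavenumbers[-1]:g}]"
        )
    values = np.interp(grid, s.wavenumbers, s.intensities)
    return Spectrum(grid, values, s.spectrum_id, s.sample_id)


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

def _fmt_pct(x: float) -> str:
    return f"{100.0 * x:.0f}%"


def write_predictions(verdicts, sink, records=None) -> None:
    """Write the plain-text summary of per-sample verdicts.

    One block per sample: optional per-spectrum path lines (when the
    per-spectrum ``records`` are supplied) followed by the Phase I-III
    summary with support fractions.  Output is deterministic and
    byte-stable for identical inputs.

    ``verdicts`` is a collection of :class:`dyespy.pipeline.SampleVerdict`.
    """
    verdicts = list(verdicts)
    if not verdicts:
        raise UsageError("no verdicts to write")
    by_sample: dict[str, list] = {}
    if records is not None:
        for r in records:
            by_sample.setdefault(r.sample_id, []).append(r)

    lines: list[str] = ["=== DyeSPY classification summary ==="]
    for v in verdicts:
        lines.append("")
        lines.append(f"Sample {v.sample_id} ({v.n_spectra} spectra)")
        if v.n_spectra < 15:
            lines.append(
                "  warning: fewer than the recommended minimum of 15 spectra"
            )
        for r in by_sample.get(v.sample_id, []):
            mix = r.phase2_mixture_text
            lines.append(
                f"  {r.spectrum_id}: {r.phase1_label} -> {mix} -> {r.phase3_color}"
            )
        for phase_name, pv in (
            ("Phase I  (pathway)", v.phase1),
            ("Phase II (mixture)", v.phase2),
            ("Phase III (color)", v.phase3),
        ):
            dist = " / ".join(
                f"{lbl} {_fmt_pct(frac)}"
                for lbl, frac in sorted(
                    pv.distribution.items(), key=lambda t: (-t[1], t[0])
                )
            )
            head = "IC" if pv.ic else f"{pv.label} ({_fmt_pct(pv.support)} support)"
            lines.append(f"  {phase_name}: {head}   [{dist}]")
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


def write_prediction_csv(records: Iterable, sink) -> None:
    """Write per-spectrum predictions as CSV (deterministic)."""
    rows = [
        {
            "spectrum_id": r.spectrum_id,
            "sample_id": r.sample_id,
            "phase1": r.phase1_label,
            "phase1_score": f"{r.phase1_score:.6f}",
            "phase2_mixture": r.phase2_mixture_text,
            "phase3_color": r.phase3_color,
            "similarity": "" if r.phase3_similarity is None
            else f"{r.phase3_similarity:.6f}",
        }
        for r in records
    ]
    if not rows:
        raise UsageError("no prediction records to write")
    pd.DataFrame(rows).to_csv(sink, index=False)
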