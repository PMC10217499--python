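"""Wavenumber-indexed absorbance spectra and their tabular interchange formats.

The two containers here are the currency of the whole pipeline:

* :class:`Spectrum` — a single absorbance trace on a uniform wavenumber grid
  plus acquisition metadata (fish, postmortem day, fibre).
* :class:`SpectraSet` — an ordered collection of spectra sharing one grid,
  stored as an ``(n_spectra, n_points)`` matrix with a metadata DataFrame.

Interchange is plain CSV in two layouts. Long CSV (one row per
(spectrum, wavenumber) pair) is canonical; wide CSV (one column per
wavenumber) is provided for spreadsheet users.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraSet",
    "read_spectra",
    "write_spectra",
    "SpectraError",
    "FormatError",
    "GridMismatchError",
    "ParseError",
    "GridError",
]

#: relative tolerance on grid-step uniformity
GRID_RTOL = 1e-9

LONG_COLUMNS = ["spectrum_id", "fish_id", "day", "fibre_id", "wavenumber", "intensity"]
META_COLUMNS = ["spectrum_id", "fish_id", "day", "fibre_id"]


class SpectraError(ValueError):
    """Base class for spectra container and I/O errors."""


class FormatError(SpectraError):
    """A required column is missing or the file layout is not recognised."""


class GridMismatchError(SpectraError):
    """Member spectra do not share a common wavenumber grid."""

    def __init__(self, message: str, spectrum_ids: Sequence[str] = ()):
        super().__init__(message)
        self.spectrum_ids = list(spectrum_ids)


class ParseError(SpectraError):
    """A cell could not be parsed as a number."""


class GridError(SpectraError):
    """The wavenumber axis violates the uniform-grid invariant."""


def _validate_grid(wavenumbers: np.ndarray) -> np.ndarray:
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise GridError(f"wavenumber grid must be 1-D with >= 2 points, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise GridError("wavenumber grid contains non-finite values")
    if np.any(np.diff(w) <= 0):
        raise GridError("wavenumbers must be strictly increasing")
    steps = np.diff(w)
    mean_step = steps.mean()
    if np.max(np.abs(steps - mean_step)) > GRID_RTOL * abs(mean_step):
        raise GridError(
            "wavenumber grid is not uniform: max step deviation exceeds "
            f"{GRID_RTOL} relative (steps range {steps.min()}..{steps.max()})"
        )
    return w


@dataclass
class Spectrum:
    """One absorbance spectrum on a uniform, ascending wavenumber grid.

    Parameters
    ----------
    wavenumbers : array of float
        Wavenumber axis in cm^-1. Descending input is silently re-sorted
        (instrument exports vary); the stored grid is always ascending and
        must be uniform to within 1e-9 relative step tolerance.
    intensities : array of float
        Absorbance in arbitrary units, same length as the grid, all finite.
    meta : dict
        ``spectrum_id``, ``fish_id``, ``day`` (int, postmortem day),
        ``fibre_id``.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        x = np.asarray(self.intensities, dtype=float)
        if w.shape != x.shape:
            raise SpectraError(
                f"wavenumbers and intensities differ in length ({w.size} vs {x.size})"
            )
        if w.size >= 2 and np.all(np.diff(w) < 0):  # descending export
            w = w[::-1]
            x = x[::-1]
        self.wavenumbers = _validate_grid(w)
        if not np.all(np.isfinite(x)):
            raise SpectraError("intensities contain NaN or Inf")
        self.intensities = x
        self.meta = dict(self.meta)

    @property
    def spectrum_id(self) -> str:
        return str(self.meta.get("spectrum_id", ""))

    def replace_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float), dict(self.meta))

    def __len__(self) -> int:
        return self.wavenumbers.size


class SpectraSet:
    """An ordered collection of spectra on one shared wavenumber grid.

    Stored internally as a dense ``(n, p)`` intensity matrix plus a metadata
    DataFrame with columns ``spectrum_id, fish_id, day, fibre_id``. Days are
    coerced to integers; ``spectrum_id`` must be unique.
    """

    def __init__(self, grid: np.ndarray, intensities: np.ndarray, meta: pd.DataFrame):
        grid = _validate_grid(np.asarray(grid, float)) if len(np.atleast_1d(grid)) >= 2 else np.asarray(grid, float)
        intensities = np.asarray(intensities, dtype=float)
        if intensities.ndim != 2 or intensities.shape[1] != grid.size:
            raise SpectraError(
                f"intensity matrix shape {intensities.shape} does not match grid length {grid.size}"
            )
        if not np.all(np.isfinite(intensities)):
            raise SpectraError("intensity matrix contains NaN or Inf")
        meta = meta.reset_index(drop=True).copy()
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise FormatError(f"metadata missing required column(s): {', '.join(missing)}")
        if len(meta) != intensities.shape[0]:
            raise SpectraError("metadata row count does not match number of spectra")
        meta["day"] = meta["day"].astype(int)
        for c in ("spectrum_id", "fish_id", "fibre_id"):
            meta[c] = meta[c].astype(str)
        dup = meta["spectrum_id"][meta["spectrum_id"].duplicated()]
        if len(dup):
            raise SpectraError(f"duplicate spectrum_id(s): {sorted(set(dup))}")
        self.grid = grid
        self.intensities = intensities
        self.meta = meta

    # -- construction -----------------------------------------------------

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectraSet":
        if not spectra:
            raise SpectraError("cannot build a SpectraSet from zero spectra without a grid")
        grid = spectra[0].wavenumbers
        bad = [s.spectrum_id for s in spectra
               if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid)]
        if bad:
            raise GridMismatchError(
                f"spectra not on the common grid: {bad}", spectrum_ids=bad
            )
        X = np.vstack([s.intensities for s in spectra])
        meta = pd.DataFrame([{c: s.meta.get(c, "") for c in META_COLUMNS} for s in spectra])
        return cls(grid, X, meta)

    @classmethod
    def empty(cls, grid: np.ndarray) -> "SpectraSet":
        return cls(np.asarray(grid, float), np.empty((0, len(grid))),
                   pd.DataFrame(columns=META_COLUMNS))

    # -- access ------------------------------------------------------------

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        return Spectrum(self.grid.copy(), self.intensities[i].copy(),
                        {c: row[c] for c in META_COLUMNS})

    @property
    def labels(self) -> np.ndarray:
        """Postmortem day per spectrum."""
        return self.meta["day"].to_numpy()

    def select(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraSet(self.grid.copy(), self.intensities[idx],
                          self.meta.iloc[idx].reset_index(drop=True))

    def subset_days(self, days: Sequence[int]) -> "SpectraSet":
        return self.select(self.meta["day"].isin(list(days)).to_numpy())

    def with_intensities(self, X: np.ndarray, grid: np.ndarray | None = None) -> "SpectraSet":
        g = self.grid if grid is None else np.asarray(grid, float)
        return SpectraSet(g.copy(), np.asarray(X, float), self.meta.copy())

    # -- tabular conversion --------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        n, p = self.intensities.shape
        if n == 0:
            return pd.DataFrame(columns=LONG_COLUMNS)
        rep = self.meta.loc[self.meta.index.repeat(p)].reset_index(drop=True)
        rep["wavenumber"] = np.tile(self.grid, n)
        rep["intensity"] = self.intensities.ravel()
        return rep[LONG_COLUMNS]

    def to_wide_frame(self) -> pd.DataFrame:
        values = pd.DataFrame(self.intensities,
                              columns=[_format_wavenumber(w) for w in self.grid])
        return pd.concat([self.meta.reset_index(drop=True), values], axis=1)

    def plot_mean(self, ax=None, by_day: bool = True):
        """Plot mean spectrum (optionally one trace per postmortem day)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if by_day and len(self):
            for day in sorted(self.meta["day"].unique()):
                m = self.intensities[self.labels == day].mean(axis=0)
                ax.plot(self.grid, m, label=f"D{day}")
            ax.legend()
        elif len(self):
            ax.plot(self.grid, self.intensities.mean(axis=0))
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
        ax.set_ylabel("absorbance (a.u.)")
        return ax


def _format_wavenumber(w: float) -> str:
    # keep round grids readable ("900" not "900.0") while staying lossless
    return repr(float(w)).removesuffix(".0")


# ---------------------------------------------------------------------------
# file I/O


def read_spectra(path, format: str = "long_csv") -> SpectraSet:
    """Read a :class:`SpectraSet` from CSV.

    Parameters
    ----------
    path : path-like
    format : {"long_csv", "wide_csv"}
        Long CSV columns: ``spectrum_id, fish_id, day, fibre_id, wavenumber,
        intensity``. Wide CSV: the four metadata columns followed by one
        numerically named column per wavenumber.

    Raises
    ------
    FormatError
        A required column is missing (the message names it).
    GridMismatchError
        Spectra in a long CSV do not share one grid (offenders listed).
    ParseError
        A non-numeric intensity value (the message gives the row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "long_csv":
        return _read_long(path)
    if format == "wide_csv":
        return _read_wide(path)
    raise ValueError(f"unknown format {format!r}; expected 'long_csv' or 'wide_csv'")


def _read_long(path: Path) -> SpectraSet:
    df = pd.read_csv(path, dtype={"spectrum_id": str, "fish_id": str, "fibre_id": str},
                     float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"long CSV {path.name} missing column(s): {', '.join(missing)}")
    for col in ("wavenumber", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"non-numeric {col} at data row {bad[0] + 1} of {path.name}: {df[col].iloc[bad[0]]!r}"
            )
        df[col] = coerced
    if df["intensity"].isna().any():
        row = int(df.index[df["intensity"].isna()][0])
        raise ParseError(f"missing intensity at data row {row + 1} of {path.name}")
    if len(df) == 0:
        # header-only file: no grid can be inferred; empty set on empty grid
        return SpectraSet(np.array([0.0, 1.0]), np.empty((0, 2)),
                          pd.DataFrame(columns=META_COLUMNS))

    spectra = []
    grids = {}
    for sid, sub in df.groupby("spectrum_id", sort=False):
        sub = sub.sort_values("wavenumber")
        grids[sid] = sub["wavenumber"].to_numpy()
        first = sub.iloc[0]
        spectra.append(Spectrum(
            grids[sid], sub["intensity"].to_numpy(),
            {"spectrum_id": str(sid), "fish_id": str(first["fish_id"]),
             "day": int(first["day"]), "fibre_id": str(first["fibre_id"])},
        ))
    ref = spectra[0].wavenumbers
    bad = [s.spectrum_id for s in spectra if not np.array_equal(s.wavenumbers, ref)]
    if bad:
        raise GridMismatchError(
            f"inconsistent wavenumber grids across spectra in {path.name}; "
            f"offending spectrum_id(s): {bad}", spectrum_ids=bad)
    return SpectraSet.from_spectra(spectra)


def _read_wide(path: Path) -> SpectraSet:
    df = pd.read_csv(path, dtype={"spectrum_id": str, "fish_id": str, "fibre_id": str},
                     float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"wide CSV {path.name} missing column(s): {', '.join(missing)}")
    wave_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        grid = np.array([float(c) for c in wave_cols])
    except ValueError as e:
        raise FormatError(f"wide CSV {path.name} has a non-numeric wavenumber column: {e}")
    order = np.argsort(grid)
    grid = grid[order]
    wave_cols = [wave_cols[i] for i in order]
    if len(df) == 0:
        return SpectraSet(grid if grid.size >= 2 else np.array([0.0, 1.0]),
                          np.empty((0, max(grid.size, 2))),
                          pd.DataFrame(columns=META_COLUMNS))
    X = df[wave_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(X).any():
        i, j = np.argwhere(np.isnan(X))[0]
        raise ParseError(
            f"non-numeric intensity at data row {i + 1}, column {wave_cols[j]} of {path.name}"
        )
    return SpectraSet(grid, X, df[META_COLUMNS])


def write_spectra(spectra_set: SpectraSet, path, format: str = "long_csv") -> None:
    """Write a :class:`SpectraSet` to CSV, losslessly round-trippable.

    Intensities and wavenumbers are written with full float repr (17
    significant digits), so ``read_spectra(write_spectra(S)) == S`` exactly.
    """
    path = Path(path)
    if format == "long_csv":
        df = spectra_set.to_long_frame()
    elif format == "wide_csv":
        df = spectra_set.to_wide_frame()
    else:
        raise ValueError(f"unknown format {format!r}; expected 'long_csv' or 'wide_csv'")
    df.to_csv(path, index=False, float_format="%.17g")
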