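"""Spectral pre-processing: reference subtraction, iterative polynomial
(ModPoly) baseline correction, fingerprint-region cropping and vector
normalisation.

The fixed chain applied by :func:`preprocess` is

1. subtract a reference spectrum (optional; models background subtraction),
2. ModPoly baseline correction on the full acquired grid,
3. crop to the analysis region (default 900–1780 cm^-1),
4. vector normalisation over the cropped region.

The baseline is fitted on the full grid *before* cropping because the wider
support stabilises the polynomial at the crop edges; normalisation runs
*after* cropping so the unit-norm constraint applies to the analysed
fingerprint. Set ``normalise_before_crop=True`` for the alternative order
when doing sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, SpectraSet

__all__ = [
    "PreprocessConfig",
    "modpoly_baseline",
    "vector_normalise",
    "crop",
    "preprocess",
    "PreprocessError",
    "NormalisationError",
    "EmptyCropError",
]


class PreprocessError(ValueError):
    pass


class NormalisationError(PreprocessError):
    """Zero-norm spectrum — an empty or dead-pixel trace."""


class EmptyCropError(PreprocessError):
    """Crop window does not overlap the grid."""


@dataclass
class PreprocessConfig:
    """Parameters of the pre-processing chain.

    Defaults reproduce the standard tissue-FTIR recipe: 5th-order polynomial
    baseline with a 200-iteration cap, fingerprint crop 900–1780 cm^-1,
    unit-norm scaling.
    """

    poly_order: int = 5
    max_iterations: int = 200
    convergence_tol: float = 1e-6
    crop_min: float = 900.0
    crop_max: float = 1780.0
    normalise: bool = True
    normalise_before_crop: bool = False

    def __post_init__(self) -> None:
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.crop_min >= self.crop_max:
            raise ValueError("crop_min must be < crop_max")


def _modpoly_matrix(wavenumbers: np.ndarray, Y: np.ndarray, order: int,
                    max_iterations: int, tol: float) -> np.ndarray:
    """Vectorised ModPoly over the rows of ``Y``; returns baselines.

    The polynomial least-squares fit on a fixed grid is the linear map
    ``fit = Q Q^T y`` (Q from the QR factorisation of the Vandermonde matrix
    on the axis rescaled to [-1, 1]), so all spectra iterate together; rows
    whose baseline estimate has converged drop out of the iteration.
    """
    x = 2.0 * (wavenumbers - wavenumbers[0]) / (wavenumbers[-1] - wavenumbers[0]) - 1.0
    V = np.polynomial.polynomial.polyvander(x, order)
    Q, _ = np.linalg.qr(V)
    work = Y.copy()
    baselines = np.empty_like(Y)
    active = np.arange(Y.shape[0])
    prev = None
    for it in range(max_iterations):
        fits = (work[active] @ Q) @ Q.T
        work[active] = np.minimum(work[active], fits)
        if prev is not None:
            scale = np.max(np.abs(fits), axis=1)
            delta = np.max(np.abs(fits - prev), axis=1)
            done = (scale == 0.0) | (delta < tol * scale)
        else:
            done = np.zeros(active.size, dtype=bool)
        if it == max_iterations - 1:
            done[:] = True
        baselines[active[done]] = fits[done]
        active = active[~done]
        prev = fits[~done]
        if active.size == 0:
            break
    return baselines


def modpoly_baseline(spectrum: Spectrum, order: int = 5, max_iterations: int = 200,
                     tol: float = 1e-6):
    """Iterative-minimum polynomial baseline (ModPoly scheme).

    Repeatedly least-squares fits a polynomial of the given order to a
    working copy of the spectrum and clips the copy to the pointwise minimum
    of itself and the fit; the fit slides under the peaks and converges to
    the baseline. Stops at ``max_iterations`` or when the baseline estimate
    changes by less than ``tol`` relative (max |delta p| / max |p|).

    Returns
    -------
    baseline : ndarray
        Final polynomial evaluated on the grid.
    corrected : Spectrum
        ``spectrum - baseline`` on the same grid with the same metadata.
    """
    w = spectrum.wavenumbers
    y = spectrum.intensities
    if w.size < order + 2:
        raise PreprocessError(
            f"under-determined baseline fit: {w.size} points for order {order} "
            f"(need >= {order + 2})"
        )
    baseline = _modpoly_matrix(w, y[None, :], order, max_iterations, tol)[0]
    return baseline, spectrum.replace_intensities(y - baseline)


def vector_normalise(spectrum: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm over the current grid."""
    norm = float(np.linalg.norm(spectrum.intensities))
    if norm == 0.0:
        raise NormalisationError(
            f"cannot normalise zero-norm spectrum {spectrum.spectrum_id!r}"
        )
    return spectrum.replace_intensities(spectrum.intensities / norm)


def crop(spectrum: Spectrum, wmin: float, wmax: float) -> Spectrum:
    """Closed-interval selection ``wmin <= w <= wmax``; metadata preserved."""
    w = spectrum.wavenumbers
    mask = (w >= wmin) & (w <= wmax)
    if not mask.any():
        raise EmptyCropError(
            f"crop [{wmin}, {wmax}] does not overlap grid "
            f"[{w[0]}, {w[-1]}] (spectrum {spectrum.spectrum_id!r})"
        )
    return Spectrum(w[mask], spectrum.intensities[mask], dict(spectrum.meta))


def preprocess(spectra_set: SpectraSet, config: PreprocessConfig | None = None,
               reference: Spectrum | None = None) -> SpectraSet:
    """Apply the full chain to every spectrum of a set.

    Errors from component steps are re-raised annotated with the offending
    ``spectrum_id``.
    """
    config = config or PreprocessConfig()
    if reference is not None and not np.array_equal(reference.wavenumbers, spectra_set.grid):
        raise PreprocessError("reference spectrum is not on the set's grid")

    grid = spectra_set.grid
    if grid.size < config.poly_order + 2:
        raise PreprocessError(
            f"under-determined baseline fit: {grid.size} points for order "
            f"{config.poly_order} (need >= {config.poly_order + 2})"
        )
    mask = (grid >= config.crop_min) & (grid <= config.crop_max)
    if not mask.any():
        raise EmptyCropError(
            f"crop [{config.crop_min}, {config.crop_max}] does not overlap grid "
            f"[{grid[0]}, {grid[-1]}]"
        )
    if len(spectra_set) == 0:
        return SpectraSet.empty(grid[mask])

    X = spectra_set.intensities
    if reference is not None:
        X = X - reference.intensities
    baselines = _modpoly_matrix(grid, X, config.poly_order, config.max_iterations,
                                config.convergence_tol)
    X = X - baselines

    def _normalise(M: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(M, axis=1)
        zero = np.flatnonzero(norms == 0.0)
        if zero.size:
            sid = spectra_set.meta["spectrum_id"].iloc[zero[0]]
            raise NormalisationError(f"spectrum {sid!r}: cannot normalise zero-norm spectrum")
        return M / norms[:, None]

    if config.normalise and config.normalise_before_crop:
        X = _normalise(X)
    X = X[:, mask]
    if config.normalise and not config.normalise_before_crop:
        X = _normalise(X)
    return spectra_set.with_intensities(X, grid[mask])
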