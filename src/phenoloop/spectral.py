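"""Image-derived phenotype metrics for hyperspectral shoot views.

Implements the study's four shoot metrics:

* a normalized-difference vegetation index (NDVI variant) computed per pixel
  as ``(m750 - m550) / (m750 + m550 + 2*mmin)``, where ``m750``/``m550`` are
  mean reflectances over the 740-750 nm and 540-560 nm windows and ``mmin``
  is the per-pixel minimum reflectance over the retained 430-800 nm range;
* image-level NDVI aggregation through equal-count binning (n=50) of sorted
  per-pixel values;
* a two-atom nonnegative spectral dictionary ("green" vs "non-green") used
  to classify pixels as healthy/unhealthy and report a per-view health
  fraction;
* scalar plant-size proxies: the Euclidean norm of the three shoot-view
  pixel counts and the count-weighted average of per-view health fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BandWindows",
    "NDVIResult",
    "SpectralDictionary",
    "HealthDictionary",
    "ndvi_pixel",
    "ndvi_image",
    "fit_health_dictionary",
    "health_fraction",
    "euclidean_size",
    "weighted_health",
]


@dataclass(frozen=True)
class BandWindows:
    """Wavelength windows (nm) entering the vegetation index.

    ``nir_window`` and ``green_window`` are inclusive [low, high] intervals
    whose mean reflectances are the ``m750`` and ``m550`` terms; ``mmin`` is
    taken over ``retained_range``.
    """

    nir_window: tuple[float, float] = (740.0, 750.0)
    green_window: tuple[float, float] = (540.0, 560.0)
    retained_range: tuple[float, float] = (430.0, 800.0)

    def __post_init__(self) -> None:
        for low, high in (self.nir_window, self.green_window, self.retained_range):
            if not low < high:
                raise ValueError(f"window bounds must satisfy low < high, got ({low}, {high})")
        lo, hi = self.retained_range
        for w in (self.nir_window, self.green_window):
            if w[0] < lo or w[1] > hi:
                raise ValueError(f"window {w} outside retained range {self.retained_range}")


@dataclass
class NDVIResult:
    per_pixel: np.ndarray
    bin_means: np.ndarray
    image_mean: float


def _window_mask(wavelengths: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (wavelengths >= window[0]) & (wavelengths <= window[1])
    if not mask.any():
        raise ValueError(f"wavelength grid does not cover window {window}")
    return mask


def _ndvi_spectra(spectra: np.ndarray, wavelengths: np.ndarray, bands: BandWindows) -> np.ndarray:
    """Vectorized index over an (..., n_bands) reflectance array."""
    spectra = np.asarray(spectra, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if spectra.shape[-1] != wavelengths.shape[0]:
        raise ValueError("last axis of spectra must match the wavelength grid")
    if np.any(spectra < 0):
        raise ValueError("reflectance must be nonnegative")
    retained = _window_mask(wavelengths, bands.retained_range)
    m750 = spectra[..., _window_mask(wavelengths, bands.nir_window)].mean(axis=-1)
    m550 = spectra[..., _window_mask(wavelengths, bands.green_window)].mean(axis=-1)
    mmin = spectra[..., retained].min(axis=-1)
    denom = m750 + m550 + 2.0 * mmin
    if np.any(denom <= 0):
        raise ValueError("undefined NDVI: zero denominator (all-zero spectrum in window)")
    return (m750 - m550) / denom


def ndvi_pixel(spectrum: np.ndarray, wavelengths: np.ndarray,
               bands: BandWindows | None = None) -> float:
    """Vegetation index of one pixel: (m750 - m550)/(m750 + m550 + 2*mmin)."""
    bands = bands or BandWindows()
    return float(_ndvi_spectra(np.asarray(spectrum, dtype=float), wavelengths, bands))


def ndvi_image(cube, mask: np.ndarray | None = None, n_bins: int = 50,
               bands: BandWindows | None = None) -> NDVIResult:
    """Per-pixel NDVI over in-mask pixels with equal-count bin aggregation.

    Pixels are sorted by NDVI and split into ``n_bins`` equal-count bins;
    ``image_mean`` is the mean of the bin means.  ``cube`` is either a
    :class:`phenoloop.synthetic.HyperspectralCube` or a (rows, cols, bands)
    array (then ``mask`` and a ``wavelengths`` attribute are required).
    """
    bands = bands or BandWindows()
    data = getattr(cube, "data", cube)
    wavelengths = getattr(cube, "wavelengths", None)
    if wavelengths is None:
        raise ValueError("cube must carry a wavelengths attribute")
    if mask is None:
        mask = getattr(cube, "mask", None)
    if mask is None:
        mask = np.ones(data.shape[:-1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    pixels = np.asarray(data, dtype=float)[mask]
    per_pixel = _ndvi_spectra(pixels, np.asarray(wavelengths), bands)
    if per_pixel.size < n_bins:
        warnings.warn(
            f"{per_pixel.size} in-mask pixels < {n_bins} bins; bins collapse to singletons",
            stacklevel=2,
        )
    order = np.sort(per_pixel)
    bin_means = np.array([chunk.mean() for chunk in np.array_split(order, n_bins) if chunk.size])
    return NDVIResult(per_pixel=per_pixel, bin_means=bin_means,
                      image_mean=float(bin_means.mean()))


@dataclass
class SpectralDictionary:
    """Two nonnegative atoms on the retained grid, labeled by their NDVI."""

    green_atom: np.ndarray
    brown_atom: np.ndarray
    wavelengths: np.ndarray
    reconstruction_error: float
    bands: BandWindows = field(default_factory=BandWindows)

    @property
    def atoms(self) -> np.ndarray:
        return np.vstack([self.green_atom, self.brown_atom])


class HealthDictionary(TransformerMixin, BaseEstimator):
    """Two-component nonnegative spectral dictionary for healthy-pixel calling.

    Fit on mean plant-pixel spectra (one row per view/plant); the spectra are
    factorized by alternating nonnegative least squares into two atoms which
    are L2-normalized and labeled green / non-green by their vegetation
    index.  ``transform`` returns nonnegative projection coefficients
    (columns: green, brown); a pixel is called healthy when its green
    coefficient exceeds the brown one.

    The factorization alternates closed-form nonnegative least squares for
    the coefficients and for the atoms (per wavelength) from a deterministic
    initialization at the spectra with the lowest and highest vegetation
    index, so mixtures of two endmembers that include (near-)pure spectra
    recover the endmembers up to scale.

    Parameters
    ----------
    bands : BandWindows, optional
        Index windows used to label the atoms.
    max_iter : int
        Alternating-update iteration cap.
    tol : float
        Relative reconstruction-error change at which to stop.
    """

    def __init__(self, bands: BandWindows | None = None, max_iter: int = 200,
                 tol: float = 1e-10):
        self.bands = bands
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None, wavelengths: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need at least 2 spectra (rows)")
        if np.any(X < 0):
            raise ValueError("spectra must be nonnegative")
        if wavelengths is None:
            wavelengths = np.linspace(430.0, 800.0, X.shape[1])
        wavelengths = np.asarray(wavelengths, dtype=float)
        bands = self.bands or BandWindows()
        # rank-deficiency check: all spectra (numerically) proportional
        sv = np.linalg.svd(X, compute_uv=False)
        if sv[1] <= 1e-9 * sv[0]:
            warnings.warn("input spectra are rank-1 (all identical up to scale); "
                          "dictionary is degenerate to a single atom", stacklevel=2)
        ndvi_rows = _ndvi_spectra(np.maximum(X, 1e-12), wavelengths, bands)
        a = X[int(np.argmax(ndvi_rows))].copy()
        b = X[int(np.argmin(ndvi_rows))].copy()
        a /= max(np.linalg.norm(a), 1e-12)
        b /= max(np.linalg.norm(b), 1e-12)
        prev_err = np.inf
        for _ in range(self.max_iter):
            C = _nnls_two_atoms(X, a, b)                    # coefficients
            AT = _nnls_two_atoms(X.T, C[:, 0], C[:, 1])     # atoms, per band
            a, b = AT[:, 0], AT[:, 1]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na < 1e-12 or nb < 1e-12:
                break  # degenerate: one atom vanished
            a, b = a / na, b / nb
            err = float(np.linalg.norm(X - _nnls_two_atoms(X, a, b) @ np.vstack([a, b])))
            if abs(prev_err - err) <= self.tol * max(err, 1e-30):
                prev_err = err
                break
            prev_err = err
        atoms = np.vstack([a, b])
        ndvis = [float(_ndvi_spectra(np.maximum(at, 1e-12), wavelengths, bands))
                 for at in atoms]
        green_idx = int(np.argmax(ndvis))
        self.wavelengths_ = wavelengths
        self.green_atom_ = atoms[green_idx]
        self.brown_atom_ = atoms[1 - green_idx]
        self.coefficients_ = _nnls_two_atoms(X, self.green_atom_, self.brown_atom_)
        self.reconstruction_error_ = float(
            np.linalg.norm(X - self.coefficients_
                           @ np.vstack([self.green_atom_, self.brown_atom_])))
        return self

    def transform(self, X) -> np.ndarray:
        """Nonnegative 2-atom projection coefficients, columns (green, brown)."""
        check_is_fitted(self, "green_atom_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return _nnls_two_atoms(X, self.green_atom_, self.brown_atom_)

    def to_dictionary(self) -> SpectralDictionary:
        check_is_fitted(self, "green_atom_")
        return SpectralDictionary(
            green_atom=self.green_atom_, brown_atom=self.brown_atom_,
            wavelengths=self.wavelengths_,
            reconstruction_error=self.reconstruction_error_,
            bands=self.bands or BandWindows(),
        )


def _nnls_two_atoms(X: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closed-form nonnegative least squares onto two atoms, vectorized.

    Solves min ||x - c_g g - c_b b||^2 s.t. c >= 0 per row.  The 2-D problem
    is solved unconstrained; if a coefficient goes negative the optimum lies
    on a boundary, so each single-atom projection is evaluated instead.
    """
    gg, bb, gb = g @ g, b @ b, g @ b
    xg, xb = X @ g, X @ b
    det = gg * bb - gb * gb
    if det <= 1e-15 * max(gg * bb, 1e-30):
        # degenerate (parallel atoms): project on g only
        cg = np.maximum(xg / gg, 0.0)
        return np.column_stack([cg, np.zeros_like(cg)])
    cg = (bb * xg - gb * xb) / det
    cb = (gg * xb - gb * xg) / det
    interior = (cg >= 0) & (cb >= 0)
    # boundary candidates
    cg_only = np.maximum(xg / gg, 0.0)
    cb_only = np.maximum(xb / bb, 0.0)
    # residual^2 up to ||x||^2: -2 c.q + c.M c
    def _obj(a, c):  # noqa: ANN001 - tiny local helper
        return -2.0 * (a * xg + c * xb) + a * a * gg + c * c * bb + 2.0 * a * c * gb

    obj_g = _obj(cg_only, np.zeros_like(cg_only))
    obj_b = _obj(np.zeros_like(cb_only), cb_only)
    use_g = obj_g <= obj_b
    out = np.column_stack([np.where(use_g, cg_only, 0.0), np.where(use_g, 0.0, cb_only)])
    out[interior] = np.column_stack([cg[interior], cb[interior]])
    return out


def fit_health_dictionary(mean_spectra: np.ndarray,
                          wavelengths: np.ndarray | None = None,
                          bands: BandWindows | None = None) -> SpectralDictionary:
    """Fit the two-atom green/non-green dictionary on mean plant spectra."""
    est = HealthDictionary(bands=bands)
    est.fit(mean_spectra, wavelengths=wavelengths)
    return est.to_dictionary()


def health_fraction(cube, mask: np.ndarray | None = None,
                    dictionary: SpectralDictionary | None = None) -> float:
    """Fraction of in-mask pixels whose green projection weight dominates."""
    if dictionary is None:
        raise ValueError("a fitted SpectralDictionary is required")
    data = getattr(cube, "data", cube)
    if mask is None:
        mask = getattr(cube, "mask", None)
    if mask is None:
        mask = np.ones(np.asarray(data).shape[:-1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    pixels = np.asarray(data, dtype=float)[mask]
    coeffs = _nnls_two_atoms(pixels, dictionary.green_atom, dictionary.brown_atom)
    return float(np.mean(coeffs[:, 0] > coeffs[:, 1]))


def euclidean_size(counts) -> float:
    """Single-scalar shoot size: sqrt(top^2 + side^2 + front^2)."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3,):
        raise ValueError("expected exactly 3 view pixel counts")
    if np.any(counts < 0):
        raise ValueError("pixel counts must be nonnegative")
    return float(np.sqrt(np.sum(counts ** 2)))


def weighted_health(health, counts) -> float:
    """Count-weighted mean of per-view health fractions."""
    health = np.asarray(health, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if health.shape != counts.shape:
        raise ValueError("health and counts must have equal length")
    if np.any(counts < 0):
        raise ValueError("pixel counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all view counts are zero")
    return float(np.sum(health * counts) / total)
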