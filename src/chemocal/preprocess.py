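"""Spectral correction operators and the seven composed pipelines.

The calibration study compares seven preprocessing methods — RAW, SG, MSC,
SNV, SGFD, MSCFD, SNVFD — each followed by per-wavelength Min-Max scaling.
The *FD variants apply a Savitzky-Golay first derivative after the scatter
correction (or as part of the SG filter itself for SGFD).

All data-dependent statistics (MSC reference spectrum, Min-Max bounds) are
learned on training spectra only and carried in a fitted-state mapping so
held-out spectra are transformed consistently.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectraSet

VALID_METHODS = ("RAW", "SG", "MSC", "SNV", "SGFD", "MSCFD", "SNVFD")


@dataclass(frozen=True)
class PreprocessSpec:
    """One preprocessing recipe.

    sg_window/sg_polyorder parameterize every Savitzky-Golay step (smoothing
    and derivative alike); minmax toggles the final per-wavelength Min-Max
    scaling.
    """

    method: str = "RAW"
    sg_window: int = 11
    sg_polyorder: int = 2
    minmax: bool = True

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {VALID_METHODS}")
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be smaller than sg_window")


def reflectance_to_absorbance(reflectance: np.ndarray) -> np.ndarray:
    """Convert diffuse reflectance to absorbance a = log10(1/R)."""
    r = np.asarray(reflectance, dtype=float)
    bad = np.argwhere(r <= 0)
    if bad.size:
        cell = tuple(int(i) for i in bad[0])
        raise ValueError(
            f"reflectance must be positive; offending cell {cell} = {r[tuple(bad[0])]}"
        )
    return -np.log10(r)


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering to mean 0, SD 1 (ddof=1)."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least 2 points per spectrum")
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        row = int(np.flatnonzero(sd[:, 0] == 0)[0])
        raise ValueError(f"constant spectrum (row {row}) cannot be SNV-corrected")
    out = (x - x.mean(axis=1, keepdims=True)) / sd
    return out if np.asarray(spectra).ndim > 1 else out[0]


def msc(spectra: np.ndarray, reference: np.ndarray | None = None):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference by OLS, x = a + b*ref, and
    corrected to (x - a)/b. The reference defaults to the column mean of the
    input (training) matrix and is returned so test-set spectra reuse it.

    Returns (corrected_matrix, reference_used).
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if reference is None:
        if x.shape[0] < 2:
            raise ValueError("MSC needs >= 2 spectra when no reference is supplied")
        reference = x.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference has zero variance")
    slope = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(slope == 0):
        raise ValueError("a spectrum is orthogonal to the MSC reference (zero slope)")
    intercept = x.mean(axis=1) - slope * reference.mean()
    corrected = (x - intercept[:, None]) / slope[:, None]
    return corrected, reference


def savgol(
    spectra: np.ndarray,
    window: int,
    polyorder: int,
    deriv: int = 0,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay filtering (deriv=0) or derivative per nm (deriv=1).

    Edges are handled by evaluating the boundary polynomial fits, so output
    length equals input length.
    """
    x = np.asarray(spectra, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window > x.shape[-1]:
        raise ValueError("window exceeds spectrum length")
    return savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=deriv, delta=delta,
        axis=-1, mode="interp",
    )


def minmax_scale(matrix: np.ndarray, fit_stats: dict | None = None):
    """Per-wavelength Min-Max scaling with train-set statistics.

    Returns (scaled, stats). When fit_stats is given, its stored min/max are
    applied (held-out values may fall outside [0, 1]); otherwise stats are
    computed from the input. Zero-range wavelengths map to 0 with a warning.
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    if fit_stats is None:
        fit_stats = {"min": x.min(axis=0), "max": x.max(axis=0)}
    lo, hi = fit_stats["min"], fit_stats["max"]
    span = hi - lo
    degenerate = span == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} wavelength(s) have zero training range; mapped to 0",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, span)
    scaled = (x - lo) / safe
    scaled[:, degenerate] = 0.0
    return scaled, fit_stats


def apply_pipeline(
    spectra: SpectraSet,
    spec: PreprocessSpec,
    fitted_state: dict | None = None,
):
    """Apply one preprocessing recipe; learn statistics on first (training) call.

    Operator order: scatter correction (MSC/SNV) or SG smoothing first, then
    the SG first derivative for *FD methods, then Min-Max. Returns
    (SpectraSet, fitted_state); pass the returned state back to transform
    held-out spectra with training statistics.
    """
    x = spectra.absorbance.copy()
    delta = spectra.grid_spacing
    fitting = fitted_state is None
    state: dict = {"spec": spec} if fitting else dict(fitted_state)
    method = spec.method

    try:
        if method in ("MSC", "MSCFD"):
            ref = None if fitting else state["msc_reference"]
            x, ref = msc(x, reference=ref)
            state["msc_reference"] = ref
        elif method in ("SNV", "SNVFD"):
            x = snv(x)
        elif method == "SG":
            x = savgol(x, spec.sg_window, spec.sg_polyorder, deriv=0, delta=delta)

        if method in ("SGFD", "MSCFD", "SNVFD"):
            x = savgol(x, spec.sg_window, spec.sg_polyorder, deriv=1, delta=delta)

        if spec.minmax:
            stats = None if fitting else state["minmax"]
            x, stats = minmax_scale(x, fit_stats=stats)
            state["minmax"] = stats
    except ValueError as err:
        raise ValueError(f"preprocessing stage {method!r} failed: {err}") from err

    state["checksum"] = state_checksum(state)
    return spectra.with_absorbance(x), state


def state_checksum(state: dict) -> str:
    """Stable digest of the fitted statistics (used to assert no test-set leakage)."""
    h = hashlib.sha256()
    spec = state.get("spec")
    if spec is not None:
        h.update(repr(spec).encode())
    for key in ("msc_reference",):
        if key in state:
            h.update(np.ascontiguousarray(state[key]).tobytes())
    if "minmax" in state:
        h.update(np.ascontiguousarray(state["minmax"]["min"]).tobytes())
        h.update(np.ascontiguousarray(state["minmax"]["max"]).tobytes())
    return h.hexdigest()
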