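"""Optical density and haemoglobin conversion (modified Beer-Lambert law).

Intensities are converted to optical density relative to the channel mean,
``OD(t) = -log10(I(t) / mean(I))``, and OD changes at the two wavelengths are
inverted through the extinction-coefficient matrix to oxy-/deoxyhaemoglobin
concentration changes.  No differential pathlength factor and no
source-detector distance scaling are applied (separations are uniform and
only relative betas are analyzed), so concentrations are in arbitrary
relative units.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EXTINCTION", "extinction_matrix", "intensity_to_od", "od_to_haemo",
           "haemo_to_od"]

# Molar extinction coefficients [cm^-1 / (mol/L)] for (HbO, HbR),
# compiled values (W.B. Gratzer / S. Prahl tabulation) at the two LED
# wavelengths; only the relative structure matters for relative betas.
EXTINCTION = {
    760: {"HbO": 586.0, "HbR": 1548.52},
    850: {"HbO": 1058.0, "HbR": 691.32},
    "source": "Gratzer/Prahl compiled haemoglobin spectra",
}

# concentrations are carried in mmol/L-scale arbitrary units so that typical
# OD excursions stay O(1); with no DPF only the relative structure matters
_UNIT_SCALE = 1e-3


def extinction_matrix(wavelengths=(760, 850)) -> np.ndarray:
    """Rows = wavelengths, columns = (HbO, HbR); mmol-scaled units."""
    return np.array([[EXTINCTION[wl]["HbO"], EXTINCTION[wl]["HbR"]]
                     for wl in wavelengths], dtype=float) * _UNIT_SCALE


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Optical density relative to the per-channel mean intensity.

    Accepts ``(n_samples,)`` or ``(n_samples, n_channels)``; refuses channels
    containing non-positive samples (flag these in QC upstream).
    """
    I = np.asarray(intensity, dtype=float)
    if np.any(I <= 0):
        raise ValueError("intensity must be strictly positive; flag channel in QC")
    return -np.log10(I / I.mean(axis=0, keepdims=I.ndim > 1))


def od_to_haemo(od_by_wl: dict[int, np.ndarray],
                E: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Invert the (unit-pathlength) Beer-Lambert system per sample.

    Parameters
    ----------
    od_by_wl : dict
        Wavelength (nm) -> OD array, both wavelengths required, identical
        shapes ``(n_samples,)`` or ``(n_samples, n_pairs)``.
    E : ndarray, optional
        2x2 extinction matrix; defaults to the packaged table.

    Returns
    -------
    (dHbO, dHbR) arrays of the input shape.  Raises on an ill-conditioned
    extinction matrix (condition number reported).
    """
    wls = sorted(od_by_wl)
    if len(wls) != 2:
        raise ValueError("need OD at exactly two wavelengths")
    if E is None:
        E = extinction_matrix(wls)
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError(f"extinction matrix ill-conditioned (cond={cond:.3g})")
    od = np.stack([np.asarray(od_by_wl[wl], dtype=float) for wl in wls])
    flat = od.reshape(2, -1)
    conc = np.linalg.solve(E, flat)
    hbo = conc[0].reshape(od.shape[1:])
    hbr = conc[1].reshape(od.shape[1:])
    return hbo, hbr


def haemo_to_od(hbo: np.ndarray, hbr: np.ndarray,
                E: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """Forward model (used by the synthetic generator): concentrations -> OD."""
    if E is None:
        E = extinction_matrix()
    conc = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)])
    od = E @ conc.reshape(2, -1)
    shape = conc.shape[1:]
    return {760: od[0].reshape(shape), 850: od[1].reshape(shape)}
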