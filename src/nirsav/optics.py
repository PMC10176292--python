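"""Modified Beer-Lambert conversion between optical density and haemoglobin.

The attenuation change at wavelength lambda over a channel of source-detector
separation d (cm) traversed with differential pathlength factor DPF is

    dOD_lambda = (eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR) * d * DPF

with concentrations in micromolar and molar extinction coefficients eps in
1/(M cm).  With two wavelengths the 2x2 system is solved per sample.  The same
DPF is applied at both wavelengths.
"""

from __future__ import annotations

import numpy as np

WAVELENGTHS_NM = (780.0, 850.0)

#: Molar extinction coefficients, 1/(M cm), rows = wavelength (780, 850 nm),
#: columns = (HbO, HbR).  Values from the standard compiled haemoglobin
#: absorption tables used throughout continuous-wave NIRS.
EXTINCTION = {
    780.0: (710.0, 1075.44),
    850.0: (1058.0, 691.32),
}

DPF_DEFAULT = 5.1


def extinction_matrix(wavelengths=WAVELENGTHS_NM) -> np.ndarray:
    """2x2 matrix E with E[i] = (eps_HbO, eps_HbR) at wavelengths[i], in 1/(uM cm)."""
    try:
        rows = [EXTINCTION[float(w)] for w in wavelengths]
    except KeyError as e:  # pragma: no cover - config error path
        raise ValueError(f"no extinction coefficients tabulated for {e} nm") from e
    return np.asarray(rows, dtype=float) * 1e-6


def od_to_concentration(
    od: np.ndarray,
    separation_cm: float | np.ndarray = 2.0,
    dpf: float = DPF_DEFAULT,
    wavelengths=WAVELENGTHS_NM,
) -> np.ndarray:
    """Solve the modified Beer-Lambert system for HbO/HbR (micromolar).

    Parameters
    ----------
    od : array (..., 2, T)
        Optical-density change series, axis -2 indexing the two wavelengths.
    separation_cm : float or array broadcastable to od[..., 0, 0]
        Channel source-detector separation.

    Returns
    -------
    array (..., 2, T), axis -2 = (HbO, HbR), units micromolar.
    """
    od = np.asarray(od, dtype=float)
    if od.shape[-2] != 2:
        raise ValueError("od must carry two wavelengths on axis -2")
    E = extinction_matrix(wavelengths)
    if abs(np.linalg.det(E)) < 1e-18:
        raise np.linalg.LinAlgError("extinction matrix is singular")
    Einv = np.linalg.inv(E)
    sep = np.asarray(separation_cm, dtype=float)
    if np.any(sep <= 0) or dpf <= 0:
        raise ValueError("separation and DPF must be positive")
    scaled = od / (sep[..., None, None] if sep.ndim else sep) / dpf
    return np.einsum("ij,...jt->...it", Einv, scaled)


def concentration_to_od(
    conc: np.ndarray,
    separation_cm: float | np.ndarray = 2.0,
    dpf: float = DPF_DEFAULT,
    wavelengths=WAVELENGTHS_NM,
) -> np.ndarray:
    """Exact algebraic inverse of :func:`od_to_concentration`.

    conc axis -2 = (HbO, HbR) in micromolar; returns dOD with axis -2 =
    wavelength.
    """
    conc = np.asarray(conc, dtype=float)
    if conc.shape[-2] != 2:
        raise ValueError("conc must carry (HbO, HbR) on axis -2")
    E = extinction_matrix(wavelengths)
    sep = np.asarray(separation_cm, dtype=float)
    if np.any(sep <= 0) or dpf <= 0:
        raise ValueError("separation and DPF must be positive")
    od = np.einsum("ij,...jt->...it", E, conc)
    return od * (sep[..., None, None] if sep.ndim else sep) * dpf


def od_to_intensity(od: np.ndarray, i0: float | np.ndarray = 1.0) -> np.ndarray:
    """I(t) = I0 * 10**(-dOD(t))."""
    i0 = np.asarray(i0, dtype=float)
    return (i0[..., None] if i0.ndim else i0) * 10.0 ** (-np.asarray(od, dtype=float))


def intensity_to_od(
    intensity: np.ndarray, reference: float | np.ndarray | None = None
) -> np.ndarray:
    """dOD(t) = -log10(I(t) / I_ref).

    With ``reference=None`` (the pipeline default) the reference is the
    temporal mean of each series, so mean(10**(-dOD)) == 1 exactly.  Passing
    the emitted intensity I0 instead makes the conversion the exact inverse of
    :func:`od_to_intensity`.
    """
    I = np.asarray(intensity, dtype=float)
    if np.any(I <= 0):
        bad = np.argwhere(~np.all(I > 0, axis=-1))
        raise ValueError(
            f"non-positive intensity sample(s) on series index {bad[:5].tolist()}"
        )
    if reference is None:
        ref = I.mean(axis=-1, keepdims=True)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.ndim and ref.shape != I.shape:
            ref = ref[..., None]
    return -np.log10(I / ref)
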