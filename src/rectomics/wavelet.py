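"""Single-level 3D discrete wavelet decomposition into 8 sub-bands.

Default family is Haar (order-1 Daubechies) with periodized boundary
handling, which keeps the transform orthogonal so input energy equals the
sum of sub-band energies.  Sub-band labels use L/H per axis in (X, Y, Z)
order: e.g. HHL = high-pass on X and Y, low-pass on Z.  Each sub-band is
upsampled back to the input grid (nearest / block replication) so the
eroded tumor mask can be applied unchanged.
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["SUBBAND_LABELS", "wavelet_decompose"]

#: Fixed sub-band order used throughout the feature layout.
SUBBAND_LABELS: tuple[str, ...] = (
    "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH",
)


def wavelet_decompose(volume: np.ndarray, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """Decompose a 3D volume into its 8 first-level wavelet sub-bands.

    Returns a dict label -> volume of the *input* shape (coefficients are
    block-replicated back up so voxel masks apply directly).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    w = pywt.Wavelet(wavelet)
    if min(volume.shape) < w.dec_len:
        raise ValueError(
            f"volume shape {volume.shape} smaller than filter length {w.dec_len}"
        )
    coeffs = pywt.dwtn(volume, w, mode="periodization")
    out: dict[str, np.ndarray] = {}
    for key, band in coeffs.items():
        label = "".join("L" if c == "a" else "H" for c in key)
        up = band
        for axis in range(3):
            up = np.repeat(up, 2, axis=axis)
        out[label] = up[tuple(slice(0, n) for n in volume.shape)]
    return {label: out[label] for label in SUBBAND_LABELS}
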