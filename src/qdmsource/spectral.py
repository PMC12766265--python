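"""Fourier-domain potential-field operations.

In the source-free half-space above the sample the field derives from a
harmonic potential, so all three components share one spectrum: with the
package's axes (y up, z toward the sensor) the projection of B onto a unit
axis u relates to the out-of-plane component by

    B_u(k) = T(k) * B_z(k),   T(k) = u_z - i (u_x k_x + u_y k_y) / |k|

which lets a raw single-axis map (projective magnetic microscopy mode) be
converted to Bz by per-wavevector division, and upward continuation by a
height dz multiplies the spectrum by exp(-|k| dz). The sign of the imaginary
part depends on the FFT convention and the row/column-to-x/y mapping; the
form above is the one validated against the analytic dipole model (a
regression test locks it).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .physics import FieldMap


@dataclass(frozen=True)
class SpectralOptions:
    """Padding / apodization / regularization settings for the transforms.

    ``pad_factor`` multiplies each map dimension before the FFT;
    ``apodization`` rolls the map edges off into the padding band with a
    half-Hann taper (interior values untouched); wavevectors where the
    transfer function magnitude falls below ``regularization_eps`` are
    zeroed instead of amplified.
    """

    pad_factor: int = 2
    apodization: str = "hann"
    regularization_eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")
        if self.apodization not in ("none", "hann"):
            raise ValueError(f"unknown apodization {self.apodization!r}")
        if self.regularization_eps <= 0:
            raise ValueError("regularization_eps must be > 0")


def _pad_taper(values: np.ndarray, opts: SpectralOptions) -> tuple[np.ndarray, tuple]:
    """Zero-pad to pad_factor * shape; optionally edge-replicate into the pad
    band and roll off with a half-Hann so the periodic extension is smooth."""
    nr, nc = values.shape
    if opts.pad_factor == 1:
        return values.copy(), (slice(0, nr), slice(0, nc))
    pr = (opts.pad_factor - 1) * nr
    pc = (opts.pad_factor - 1) * nc
    r0, c0 = pr // 2, pc // 2
    sl = (slice(r0, r0 + nr), slice(c0, c0 + nc))
    if opts.apodization == "none":
        out = np.zeros((nr + pr, nc + pc))
        out[sl] = values
        return out, sl
    # replicate edges into the pad band, then taper the band to zero
    out = np.pad(values, ((r0, pr - r0), (c0, pc - c0)), mode="edge")
    wr = _edge_window(nr + pr, r0, nr)
    wc = _edge_window(nc + pc, c0, nc)
    out *= wr[:, None]
    out *= wc[None, :]
    return out, sl


def _edge_window(n_total: int, offset: int, n_data: int) -> np.ndarray:
    """1 over the data span, half-Hann rolloff over the padding on each side."""
    w = np.ones(n_total)
    left = offset
    right = n_total - offset - n_data
    if left > 0:
        t = np.arange(left) / left
        w[:left] = 0.5 * (1.0 - np.cos(np.pi * t))
    if right > 0:
        t = np.arange(right) / right
        w[offset + n_data:] = 0.5 * (1.0 + np.cos(np.pi * t))
    return w


def _wavevectors(shape: tuple, pixel_size_um: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angular wavevector grids (rad/m) in the physical x/y axes.

    Rows run opposite to +y, so the physical k_y is the negated row
    frequency.
    """
    d = pixel_size_um * 1e-6
    ky = -2.0 * np.pi * np.fft.fftfreq(shape[0], d=d)
    kx = 2.0 * np.pi * np.fft.fftfreq(shape[1], d=d)
    kxg, kyg = np.meshgrid(kx, ky)
    k = np.hypot(kxg, kyg)
    return kxg, kyg, k


def axis_to_bz(fmap: FieldMap, u, opts: SpectralOptions | None = None) -> FieldMap:
    """Recover the out-of-plane component Bz from a single-axis projection map.

    ``u`` is the unit measurement axis of the raw map. Valid when the sensing
    plane sits in a source-free half-space, which holds for all maps produced
    here. At k = 0 the transfer function degenerates to u_z: the DC level is
    divided by u_z when that is resolvable and zeroed otherwise (an in-plane
    axis carries no information about the mean of Bz).
    """
    opts = opts or SpectralOptions()
    u = np.asarray(u, dtype=float)
    nu = np.linalg.norm(u)
    if nu == 0:
        raise ValueError("measurement axis must be nonzero")
    u = u / nu
    padded, sl = _pad_taper(fmap.values, opts)
    kxg, kyg, k = _wavevectors(padded.shape, fmap.pixel_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = u[2] - 1j * (u[0] * kxg + u[1] * kyg) / k
    T[k == 0] = 1.0  # DC handled separately
    good = np.abs(T) >= opts.regularization_eps
    frac_bad = 1.0 - good.mean()
    if abs(u[2]) < opts.regularization_eps or frac_bad > 0.1:
        warnings.warn(
            "measurement axis (nearly) in-plane: transfer function singular "
            f"on part of the spectrum ({frac_bad:.1%} of wavevectors zeroed); "
            "output is regularized",
            RuntimeWarning,
            stacklevel=2,
        )
    spec = np.fft.fft2(padded)
    out_spec = np.zeros_like(spec)
    np.divide(spec, T, out=out_spec, where=good)
    dc = k == 0
    if abs(u[2]) >= opts.regularization_eps:
        out_spec[dc] = spec[dc] / u[2]
    else:
        out_spec[dc] = 0.0
    bz = np.fft.ifft2(out_spec).real[sl]
    return fmap.copy_with(
        values=bz,
        component="bz",
        metadata={
            "spectral": {
                "op": "axis_to_bz",
                "axis": tuple(u),
                "pad_factor": opts.pad_factor,
                "apodization": opts.apodization,
                "regularization_eps": opts.regularization_eps,
            }
        },
    )


def project_bz_onto_axis(fmap: FieldMap, u, opts: SpectralOptions | None = None) -> FieldMap:
    """Forward companion of :func:`axis_to_bz`: synthesize the single-axis
    projection B_u from an out-of-plane map by multiplying with T(k)."""
    opts = opts or SpectralOptions()
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    padded, sl = _pad_taper(fmap.values, opts)
    kxg, kyg, k = _wavevectors(padded.shape, fmap.pixel_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = u[2] - 1j * (u[0] * kxg + u[1] * kyg) / k
    T[k == 0] = u[2]
    vals = np.fft.ifft2(np.fft.fft2(padded) * T).real[sl]
    return fmap.copy_with(
        values=vals,
        component="b_axis",
        metadata={"spectral": {"op": "project_bz_onto_axis", "axis": tuple(u)}},
    )


def upward_continue(fmap: FieldMap, dz_um: float, opts: SpectralOptions | None = None) -> FieldMap:
    """Continue a map upward by ``dz_um`` micrometres (exp(-|k| dz) filter).

    Downward continuation (dz < 0) amplifies noise without bound and is
    refused.
    """
    if dz_um < 0:
        raise ValueError("downward continuation refused: dz must be >= 0")
    opts = opts or SpectralOptions()
    if dz_um == 0:
        return fmap.copy_with(values=fmap.values.copy())
    padded, sl = _pad_taper(fmap.values, opts)
    _, _, k = _wavevectors(padded.shape, fmap.pixel_size)
    spec = np.fft.fft2(padded) * np.exp(-k * dz_um * 1e-6)
    vals = np.fft.ifft2(spec).real[sl]
    return fmap.copy_with(
        values=vals,
        metadata={
            "spectral": {
                "op": "upward_continue",
                "dz_um": dz_um,
                "pad_factor": opts.pad_factor,
                "apodization": opts.apodization,
            }
        },
    )
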