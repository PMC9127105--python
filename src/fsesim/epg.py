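"""Extended-phase-graph (EPG) signal formation for fast-spin-echo trains.

The EPG formalism tracks the transverse and longitudinal configuration
states (F+(k), F-(k), Z(k)) of the magnetization within a voxel under RF
pulses, ideal crusher gradients and relaxation.  It is an exact surrogate for
an ensemble of uniformly dephased isochromats and captures the stimulated
echoes produced by non-180-degree refocusing trains.

Sequence model (CPMG timing): excitation about the y axis at t = 0; per echo
period of duration ESP: relax ESP/2, unit gradient shift, refocusing pulse
about the x axis, unit gradient shift, relax ESP/2, echo.  The echo amplitude
is |F+(0)| (ideal crushers suppress all other coherences at readout).
Longitudinal recovery between shots (TR) is not simulated: the sequences are
single-shot and full recovery is assumed.

The per-voxel decay curves are assembled into a compact "T2 decay matrix":
voxels sharing (T1, T2, flip scale) within a quantization tolerance are
computed once and broadcast, which leaves the result identical to a naive
voxelwise loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import RelaxationMaps
from .inu import INUField

__all__ = ["epg_fse_train", "T2DecayMatrix", "build_t2_decay_matrix"]


def _rf_matrix(alpha_rad: np.ndarray, phase_rad: float) -> np.ndarray:
    """Per-order mixing matrix of an RF pulse acting on (F+, F-, Z).

    ``alpha_rad`` may be a batch vector; returns shape (B, 3, 3).
    """
    a = np.atleast_1d(np.asarray(alpha_rad, dtype=float))
    co2 = np.cos(a / 2) ** 2
    si2 = np.sin(a / 2) ** 2
    sa = np.sin(a)
    ca = np.cos(a)
    ep = np.exp(1j * phase_rad)
    T = np.empty((a.size, 3, 3), dtype=complex)
    T[:, 0, 0] = co2
    T[:, 0, 1] = ep ** 2 * si2
    T[:, 0, 2] = -1j * ep * sa
    T[:, 1, 0] = np.conj(ep) ** 2 * si2
    T[:, 1, 1] = co2
    T[:, 1, 2] = 1j * np.conj(ep) * sa
    T[:, 2, 0] = -0.5j * np.conj(ep) * sa
    T[:, 2, 1] = 0.5j * ep * sa
    T[:, 2, 2] = ca
    return T


def _epg_batch(t1_ms: np.ndarray, t2_ms: np.ndarray, esp_ms: float, etl: int,
               exc_deg: np.ndarray, refoc_deg: np.ndarray) -> np.ndarray:
    """Echo amplitudes |F+(0)| for a batch of voxels.

    Shapes: t1/t2/exc are (B,), refoc is (B, etl); returns (B, etl).
    Relaxation times may be +inf (relaxation disabled).
    """
    B = t1_ms.size
    K = 2 * etl + 2                     # two unit shifts per period -> exact ladder
    Fp = np.zeros((B, K), dtype=complex)
    Fm = np.zeros((B, K), dtype=complex)
    Z = np.zeros((B, K), dtype=complex)
    Z[:, 0] = 1.0

    with np.errstate(divide="ignore"):
        e1 = np.exp(-esp_ms / 2.0 / t1_ms)
        e2 = np.exp(-esp_ms / 2.0 / t2_ms)

    def relax(Fp, Fm, Z):
        Fp[:] *= e2[:, None]
        Fm[:] *= e2[:, None]
        Z[:] *= e1[:, None]
        Z[:, 0] += 1.0 - e1

    def shift(Fp, Fm):
        Fp[:, 1:] = Fp[:, :-1]
        Fp[:, 0] = np.conj(Fm[:, 1])
        Fm[:, :-1] = Fm[:, 1:]
        Fm[:, -1] = 0.0

    def rf(T, Fp, Fm, Z):
        return (
            T[:, 0, 0, None] * Fp + T[:, 0, 1, None] * Fm + T[:, 0, 2, None] * Z,
            T[:, 1, 0, None] * Fp + T[:, 1, 1, None] * Fm + T[:, 1, 2, None] * Z,
            T[:, 2, 0, None] * Fp + T[:, 2, 1, None] * Fm + T[:, 2, 2, None] * Z,
        )

    # excitation about +y (phase 90 deg): Z0 -> F+(0) = sin(alpha)
    Fp, Fm, Z = rf(_rf_matrix(np.deg2rad(exc_deg), np.pi / 2), Fp, Fm, Z)

    echoes = np.empty((B, etl))
    for j in range(etl):
        relax(Fp, Fm, Z)
        shift(Fp, Fm)
        Fp, Fm, Z = rf(_rf_matrix(np.deg2rad(refoc_deg[:, j]), 0.0), Fp, Fm, Z)
        shift(Fp, Fm)
        relax(Fp, Fm, Z)
        echoes[:, j] = np.abs(Fp[:, 0])
    return echoes


def epg_fse_train(t1_ms, t2_ms, esp_ms: float, etl: int,
                  excitation_flip_deg: float = 90.0,
                  refocusing_flips_deg=180.0) -> np.ndarray:
    """Echo-train amplitudes of a CPMG-conditioned FSE shot for one voxel.

    Parameters
    ----------
    t1_ms, t2_ms
        Relaxation times in ms (np.inf disables relaxation).  Must be > 0.
    esp_ms
        Echo spacing in ms (> 0); echo j occurs at (j+1)*esp_ms.
    etl
        Echo train length (>= 1).
    excitation_flip_deg, refocusing_flips_deg
        Nominal flip angles; the refocusing schedule may be a scalar
        (constant train) or a length-``etl`` sequence.

    Returns the ``etl`` echo magnitudes, all within [0, 1] for unit initial
    magnetization.
    """
    t1 = float(t1_ms)
    t2 = float(t2_ms)
    if not (t1 > 0 and t2 > 0):
        raise ValueError("relaxation times must be positive")
    if esp_ms <= 0:
        raise ValueError("echo spacing must be positive")
    if etl < 1:
        raise ValueError("echo train length must be >= 1")
    refoc = np.broadcast_to(np.asarray(refocusing_flips_deg, dtype=float), (etl,))
    return _epg_batch(np.array([t1]), np.array([t2]), float(esp_ms), int(etl),
                      np.array([float(excitation_flip_deg)]),
                      refoc[None, :].copy())[0]


@dataclass
class T2DecayMatrix:
    """Voxelwise echo-train amplitudes in compact (combo-indexed) form.

    ``combo_index`` assigns each voxel to a row of ``amplitudes``
    (row 0 is background, identically zero across echoes).  The dense 4D
    (x, y, z, echo) grid is available through :attr:`signal`.
    """

    combo_index: np.ndarray            # 3D int array
    amplitudes: np.ndarray             # (n_combos, etl), row 0 = background
    echo_times_ms: np.ndarray          # (etl,), echo j at (j+1)*esp
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def etl(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def shape(self):
        return self.combo_index.shape

    @property
    def signal(self) -> np.ndarray:
        """Dense 4D decay grid (materialized on demand)."""
        return self.amplitudes[self.combo_index]

    @property
    def foreground(self) -> np.ndarray:
        return self.combo_index != 0


def build_t2_decay_matrix(maps: RelaxationMaps, esp_ms: float, etl: int,
                          excitation_flip_deg: float = 90.0,
                          refocusing_flips_deg=180.0,
                          inu: INUField | None = None,
                          inu_quantization: float = 0.01) -> T2DecayMatrix:
    """EPG decay curves for every voxel of a relaxation map.

    The local flip-angle scale (the INU field value, quantized to
    ``inu_quantization``) multiplies both the excitation and the refocusing
    flip angles.  Voxels sharing (T1, T2, scale) are simulated once.
    """
    if inu is not None and inu.shape != maps.shape:
        raise ValueError("INU field grid does not match the relaxation maps; "
                         "resample it first (resample_inu)")
    refoc = np.broadcast_to(np.asarray(refocusing_flips_deg, dtype=float), (etl,))
    fg = maps.T2 > 0
    combo_index = np.zeros(maps.shape, dtype=np.int32)
    if not fg.any():
        amps = np.zeros((1, etl))
    else:
        if inu is None:
            scale = np.ones(int(fg.sum()))
        else:
            q = float(inu_quantization)
            scale = np.round(inu.values[fg] / q) * q
        key = np.stack([maps.T1[fg], maps.T2[fg], scale], axis=1)
        combos, inverse = np.unique(key, axis=0, return_inverse=True)
        combo_index[fg] = inverse.astype(np.int32) + 1
        amps_fg = _epg_batch(
            combos[:, 0], combos[:, 1], float(esp_ms), int(etl),
            excitation_flip_deg * combos[:, 2],
            refoc[None, :] * combos[:, 2, None],
        )
        amps = np.vstack([np.zeros((1, etl)), amps_fg])
    echo_times = (np.arange(etl) + 1) * float(esp_ms)
    return T2DecayMatrix(combo_index=combo_index, amplitudes=amps,
                         echo_times_ms=echo_times, spacing=maps.spacing,
                         origin=maps.origin)
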