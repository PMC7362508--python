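"""Two-point Dixon water-fat separation.

Reference inversion of the two-echo spoiled gradient-echo signal model

    s_k = (W + F e^{i theta_k}) e^{i 2 pi psi TE_k / 1000},   k in {1, 2}

with real, non-negative water (W) and fat (F) amplitudes, fat-water phase
theta_k = 2 pi delta_f TE_k / 1000 (delta_f the chemical shift, about
-220 Hz at 1.5 T) and an optional known off-resonance field map psi (Hz).
Per voxel the two complex measurements give four real equations in the two
unknowns, solved in least squares; on noiseless data with the correct psi
the recovery is exact.  Field-map *estimation* is deliberately not
implemented: psi is an input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EchoPair", "separate_ideal", "separate_with_fieldmap"]


@dataclass
class EchoPair:
    """Two registered complex echo volumes with their echo times (ms) and
    the assumed water-fat shift (Hz)."""

    s1: np.ndarray
    s2: np.ndarray
    te1_ms: float
    te2_ms: float
    delta_f_hz: float = -220.0

    def __post_init__(self):
        self.s1 = np.asarray(self.s1, dtype=np.complex128)
        self.s2 = np.asarray(self.s2, dtype=np.complex128)
        if self.s1.shape != self.s2.shape:
            raise ValueError("echo volumes have different shapes")
        if self.te1_ms <= 0 or self.te2_ms <= 0:
            raise ValueError("echo times must be positive")
        if self.te2_ms <= self.te1_ms:
            raise ValueError("te2_ms must exceed te1_ms")

    @property
    def thetas(self) -> tuple[float, float]:
        return tuple(2.0 * np.pi * self.delta_f_hz * te / 1000.0
                     for te in (self.te1_ms, self.te2_ms))


def separate_ideal(pair: EchoPair) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares W/F separation assuming zero background phase.

    Solves, per voxel, ``s_k = W + F e^{i theta_k}`` over real W, F by
    stacking real and imaginary parts (4 equations, 2 unknowns) and
    solving the 2x2 normal equations in closed form.  Negative solutions
    (possible under noise) are clipped to zero.
    """
    t1, t2 = pair.thetas
    e1, e2 = np.exp(1j * t1), np.exp(1j * t2)
    if abs(e1 - e2) < 1e-9:
        raise ValueError("echo times do not separate water and fat "
                         "(theta1 == theta2 mod 2*pi)")
    c1, s1_ = np.cos(t1), np.sin(t1)
    c2, s2_ = np.cos(t2), np.sin(t2)
    # normal equations of A [W, F]^T = b with
    # A = [[1, c1], [0, s1], [1, c2], [0, s2]],
    # b = [Re s1, Im s1, Re s2, Im s2]
    a11 = 2.0
    a12 = c1 + c2
    a22 = 2.0  # cos^2 + sin^2 summed over both echoes
    det = a11 * a22 - a12 * a12
    b1 = pair.s1.real + pair.s2.real
    b2 = (c1 * pair.s1.real + s1_ * pair.s1.imag
          + c2 * pair.s2.real + s2_ * pair.s2.imag)
    water = (a22 * b1 - a12 * b2) / det
    fat = (a11 * b2 - a12 * b1) / det
    return np.clip(water, 0.0, None), np.clip(fat, 0.0, None)


def separate_with_fieldmap(pair: EchoPair,
                           psi_hz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demodulate a known field map, then separate.

    ``psi_hz`` is broadcast against the echo volumes (e.g. a static 3D map
    against a 4D cine series); exact on noiseless data generated with the
    same psi.
    """
    psi = np.asarray(psi_hz, dtype=float)
    if psi.ndim == pair.s1.ndim - 1 and psi.shape == pair.s1.shape[:-1]:
        psi = psi[..., None]  # static map against a cine series
    try:
        np.broadcast_shapes(psi.shape, pair.s1.shape)
    except ValueError as err:
        raise ValueError(f"field map shape {psi.shape} does not broadcast "
                         f"against echoes {pair.s1.shape}") from err
    demod = EchoPair(
        s1=pair.s1 * np.exp(-1j * 2.0 * np.pi * psi * pair.te1_ms / 1000.0),
        s2=pair.s2 * np.exp(-1j * 2.0 * np.pi * psi * pair.te2_ms / 1000.0),
        te1_ms=pair.te1_ms, te2_ms=pair.te2_ms, delta_f_hz=pair.delta_f_hz)
    return separate_ideal(demod)
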