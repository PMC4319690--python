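"""Independent oracles used by the test suite.

Everything here is deliberately written against closed forms or brute
force, never against the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import eval_legendre


def two_shell_sphere_potential(
    r: np.ndarray,
    cos_theta: np.ndarray,
    r_core: float,
    r_outer: float,
    sigma_core: float,
    sigma_shell: float,
    current: float,
    lmax: int = 61,
) -> np.ndarray:
    """Potential of antipodal point-current electrodes on a two-shell sphere.

    Axisymmetric Legendre series for a sphere of radius ``r_outer`` with a
    concentric core of radius ``r_core``: +I enters at the north pole,
    -I leaves at the south pole. Only odd-degree terms survive the
    antisymmetry. Interior regularity, potential and radial-current
    continuity at the core interface, and the surface current condition
    sigma_shell dphi/dr = s_l P_l determine the coefficients per degree.
    All lengths in meters, current in amperes, potential in volts.
    """
    r = np.asarray(r, dtype=float)
    cos_theta = np.asarray(cos_theta, dtype=float)
    x1 = r_core / r_outer
    x = r / r_outer
    phi = np.zeros(np.broadcast(r, cos_theta).shape)
    for l in range(1, lmax + 1, 2):
        s_l = current * (2 * l + 1) / (2.0 * np.pi * r_outer**2)
        # unknowns: A (core), B, C (shell), in the scaled radius x = r/R2
        mat = np.array(
            [
                [x1**l, -(x1**l), -(x1 ** -(l + 1))],
                [
                    sigma_core * l * x1 ** (l - 1),
                    -sigma_shell * l * x1 ** (l - 1),
                    sigma_shell * (l + 1) * x1 ** -(l + 2),
                ],
                [0.0, sigma_shell * l, -sigma_shell * (l + 1)],
            ]
        )
        rhs = np.array([0.0, 0.0, s_l * r_outer])
        a, b, c = np.linalg.solve(mat, rhs)
        p_l = eval_legendre(l, cos_theta)
        inside = x <= x1
        term = np.where(
            inside,
            a * np.power(x, l),
            b * np.power(np.maximum(x, 1e-12), l)
            + c * np.power(np.maximum(x, 1e-12), -(l + 1)),
        )
        phi = phi + term * p_l
    return phi


def signed_rank_brute_force(values: np.ndarray) -> tuple[float, float]:
    """Exact signed-rank statistic and two-sided p by 2^n enumeration."""
    from scipy.stats import rankdata

    x = np.asarray(values, dtype=float)
    x = x[x != 0]
    ranks = rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    n = len(ranks)
    sums = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product((-1, 1), repeat=n)
    ]
    sums = np.asarray(sums)
    p_le = np.mean(sums <= w_obs)
    p_ge = np.mean(sums >= w_obs)
    return float(w_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))


def bandpass_cascade_gain(
    freq_hz: float, center: float, half_width: float, order: int, fs: float
) -> float:
    """Amplitude gain of the forward-backward HP+LP Butterworth cascade.

    Computed from the digital frequency responses directly (each filtfilt
    pass contributes |H|^2), independent of the filtering code under test.
    """
    from scipy import signal

    w = 2 * np.pi * freq_hz / fs
    b_hp, a_hp = signal.butter(order, center - half_width, btype="highpass", fs=fs)
    b_lp, a_lp = signal.butter(order, center + half_width, btype="lowpass", fs=fs)
    _, h_hp = signal.freqz(b_hp, a_hp, worN=[w])
    _, h_lp = signal.freqz(b_lp, a_lp, worN=[w])
    return float(np.abs(h_hp[0]) ** 2 * np.abs(h_lp[0]) ** 2)
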