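"""Independent brute-force oracles used by the tests.

Everything here is written directly from the definitions, without
importing the implementations it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_msum(x) -> float:
    """Literal extremum-pairing rule.

    Enumerate strict interior relative maxima and minima (a flat plateau
    counts once, at its first index).  For every maximum, walk forward
    through the minima that occur later in the series and take the
    second one; for every minimum, take the second later maximum.  Sum
    the absolute value gaps and divide by the number of lines drawn.
    """
    x = np.asarray(x, dtype=float)
    maxima, minima = [], []
    last_sign, run_start = 0, 0
    for i in range(1, len(x)):
        d = x[i] - x[i - 1]
        if d == 0:
            continue
        sign = 1 if d > 0 else -1
        if last_sign == 1 and sign == -1:
            maxima.append((run_start, x[run_start]))
        elif last_sign == -1 and sign == 1:
            minima.append((run_start, x[run_start]))
        last_sign, run_start = sign, i
    import math
    lines = []
    for idx, val in maxima:
        later = [v for j, v in minima if j > idx]
        if len(later) >= 2:
            lines.append(abs(val - later[1]))
    for idx, val in minima:
        later = [v for j, v in maxima if j > idx]
        if len(later) >= 2:
            lines.append(abs(val - later[1]))
    # fsum: correctly rounded regardless of enumeration order
    return math.fsum(lines) / len(lines) if lines else 0.0


def natural_cubic_spline(knot_x, knot_y, eval_x) -> np.ndarray:
    """Natural cubic spline by direct tridiagonal solve of the moments.

    Second derivatives M satisfy M_0 = M_{n-1} = 0 and, for interior i,
    h_{i-1} M_{i-1} + 2(h_{i-1}+h_i) M_i + h_i M_{i+1}
      = 6[(y_{i+1}-y_i)/h_i - (y_i-y_{i-1})/h_{i-1}].
    """
    kx = np.asarray(knot_x, dtype=float)
    ky = np.asarray(knot_y, dtype=float)
    n = len(kx)
    h = np.diff(kx)
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 6 * ((ky[i + 1] - ky[i]) / h[i] - (ky[i] - ky[i - 1]) / h[i - 1])
    M = np.linalg.solve(A, rhs)
    out = np.empty(len(eval_x))
    for j, t in enumerate(np.asarray(eval_x, dtype=float)):
        i = int(np.clip(np.searchsorted(kx, t, side="right") - 1, 0, n - 2))
        d = t - kx[i]
        c0 = ky[i]
        c1 = (ky[i + 1] - ky[i]) / h[i] - h[i] * (2 * M[i] + M[i + 1]) / 6
        c2 = M[i] / 2
        c3 = (M[i + 1] - M[i]) / (6 * h[i])
        out[j] = c0 + c1 * d + c2 * d * d + c3 * d ** 3
    return out


def butterworth_gain(f_hz: float, cutoff_hz: float, order: int,
                     fs_hz: float | None = None) -> float:
    """Analytic magnitude response |H(f)| of a Butterworth low-pass.

    With ``fs_hz`` given, returns the response of the digital filter
    obtained by the bilinear transform with cutoff pre-warping: the
    frequency ratio becomes tan(pi f/fs) / tan(pi fc/fs), which matters
    for frequencies near Nyquist.  Without it, the analog response.
    """
    if fs_hz is None:
        ratio = f_hz / cutoff_hz
    else:
        ratio = np.tan(np.pi * f_hz / fs_hz) / np.tan(np.pi * cutoff_hz / fs_hz)
    return 1.0 / np.sqrt(1.0 + ratio ** (2 * order))
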