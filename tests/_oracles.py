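"""Independent numerical oracles for the test suite.

These deliberately avoid the package's solution path (augmented matrix
exponentials): a fixed-step RK4 integrator using the method of steps for
the transport delay, and an adaptive-quadrature occupancy integral for
residence times.
"""

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp


@njit(cache=True)
def _rk4_upstream(a, gut_fwd, b, h2, n_half):
    """(q1, q2) on the half-step grid 0, h/2, h, ... (n_half+1 values)."""
    q1 = np.empty(n_half + 1)
    q2 = np.empty(n_half + 1)
    y1, y2 = 1.0, 0.0
    q1[0], q2[0] = y1, y2
    for i in range(n_half):
        k11 = -a * y1
        k12 = gut_fwd * y1 - b * y2
        y1b = y1 + 0.5 * h2 * k11
        y2b = y2 + 0.5 * h2 * k12
        k21 = -a * y1b
        k22 = gut_fwd * y1b - b * y2b
        y1c = y1 + 0.5 * h2 * k21
        y2c = y2 + 0.5 * h2 * k22
        k31 = -a * y1c
        k32 = gut_fwd * y1c - b * y2c
        y1d = y1 + h2 * k31
        y2d = y2 + h2 * k32
        k41 = -a * y1d
        k42 = gut_fwd * y1d - b * y2d
        y1 = y1 + h2 * (k11 + 2 * k21 + 2 * k31 + k41) / 6.0
        y2 = y2 + h2 * (k12 + 2 * k22 + 2 * k32 + k42) / 6.0
        q1[i + 1] = y1
        q2[i + 1] = y2
    return q1, q2


@njit(cache=True)
def _rk4_downstream(q2_half, gut_fwd, direct, k_delay, hep, L65, L56, L106,
                    h, n_steps, stride):
    """FD (plasma amount) every ``stride`` steps; delay handled by indexing
    the upstream history ``k_delay`` full steps back (method of steps)."""
    n_out = n_steps // stride + 1
    fd = np.zeros(n_out)
    q4 = 0.0
    q5 = 0.0
    q6 = 0.0

    def forcing(idx_half):
        if idx_half < 0:
            return 0.0
        return q2_half[idx_half]

    for i in range(n_steps):
        # half-grid indices for t_i, t_i + h/2, t_i + h, minus the delay
        i0 = 2 * i - 2 * k_delay
        i1 = 2 * i + 1 - 2 * k_delay
        i2 = 2 * i + 2 - 2 * k_delay
        o0 = gut_fwd * forcing(i0)
        o1 = gut_fwd * forcing(i1)
        o2 = gut_fwd * forcing(i2)
        u0 = direct * q2_half[2 * i]
        u1 = direct * q2_half[2 * i + 1]
        u2 = direct * q2_half[2 * i + 2]

        def rhs(q4v, q5v, q6v, o, u):
            d4 = o - hep * q4v
            d5 = hep * q4v + u + L56 * q6v - L65 * q5v
            d6 = L65 * q5v - (L56 + L106) * q6v
            return d4, d5, d6

        a4, a5, a6 = rhs(q4, q5, q6, o0, u0)
        b4, b5, b6 = rhs(q4 + 0.5 * h * a4, q5 + 0.5 * h * a5,
                         q6 + 0.5 * h * a6, o1, u1)
        c4, c5, c6 = rhs(q4 + 0.5 * h * b4, q5 + 0.5 * h * b5,
                         q6 + 0.5 * h * b6, o1, u1)
        d4, d5, d6 = rhs(q4 + h * c4, q5 + h * c5, q6 + h * c6, o2, u2)
        q4 += h * (a4 + 2 * b4 + 2 * c4 + d4) / 6.0
        q5 += h * (a5 + 2 * b5 + 2 * c5 + d5) / 6.0
        q6 += h * (a6 + 2 * b6 + 2 * c6 + d6) / 6.0
        if (i + 1) % stride == 0:
            fd[(i + 1) // stride] = q5
    return fd


def rk4_fd(chain, t_end: float, h: float = 1e-4, stride: int = 100):
    """Brute-force FD curve for one arm chain on a fixed grid.

    ``chain`` is the package's internal arm description (rates per day);
    the delay time must be an integer multiple of ``h``.  Returns (times,
    fd) every ``stride`` steps.
    """
    a = chain.gut_fwd + chain.gut_loss
    b = chain.gut_fwd + chain.direct
    n_steps = int(round(t_end / h))
    k_delay = int(round(chain.DT / h))
    if abs(k_delay * h - chain.DT) > 1e-12:
        raise ValueError("delay must be a multiple of the step size")
    q1, q2 = _rk4_upstream(a, chain.gut_fwd, b, h / 2.0, 2 * n_steps + 2)
    fd = _rk4_downstream(q2, chain.gut_fwd, chain.direct, k_delay, chain.hep,
                         chain.L65, chain.L56, chain.L106, h, n_steps, stride)
    times = np.arange(fd.size) * (h * stride)
    return times, fd


def occupancy_residence_times(L65, L56, L106, t_end=2000.0):
    """T(5,5), T(6,5) by integrating compartment occupancy for a unit
    amount placed in plasma, via an adaptive ODE solve with running
    time-integrals (independent of any matrix inverse)."""

    def rhs(_, y):
        q5, q6 = y[0], y[1]
        return [-L65 * q5 + L56 * q6,
                L65 * q5 - (L56 + L106) * q6,
                q5, q6]

    sol = solve_ivp(rhs, (0.0, t_end), [1.0, 0.0, 0.0, 0.0], method="LSODA",
                    rtol=1e-10, atol=1e-13)
    assert sol.success
    return float(sol.y[2, -1]), float(sol.y[3, -1])
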