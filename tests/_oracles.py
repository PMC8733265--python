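"""Independent oracles for the equilibrium solvers.

These deliberately avoid the code paths under test: the binary solver is
checked against interval bisection on the raw mass-balance residual, and
the competition solver against the closed-form cubic in free receptor
solved with numpy's companion-matrix root finder.
"""

from __future__ import annotations

import numpy as np


def binary_complex_bisection(rt: float, lt: float, kd: float, iters: int = 200) -> float:
    """[RL] by bisection on f(x) = (rt-x)(lt-x) - kd*x over [0, min(rt, lt)].

    f(0) = rt*lt >= 0 and f(min) = -kd*min <= 0, and f is strictly
    decreasing on the bracket, so plain bisection is exact to the budget.
    """

    def f(x: float) -> float:
        return (rt - x) * (lt - x) - kd * x

    lo, hi = 0.0, min(rt, lt)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def competition_free_receptor_cubic(
    rt: float, at: float, bt: float, kda: float, kdb: float
) -> float:
    """Free receptor from the exact ternary-equilibrium cubic.

    Multiplying the receptor mass balance by (kda + R)(kdb + R) gives
    R^3 + c2 R^2 + c1 R + c0 = 0 with the coefficients below; the unique
    physical root lies in [0, rt].
    """
    c2 = kda + kdb + at + bt - rt
    c1 = kda * kdb + at * kdb + bt * kda - rt * (kda + kdb)
    c0 = -rt * kda * kdb
    roots = np.roots([1.0, c2, c1, c0])
    real = roots[np.abs(roots.imag) < 1.0e-8 * max(1.0, np.abs(roots).max())].real
    tol = 1.0e-9 * max(rt, 1.0)
    physical = real[(real >= -tol) & (real <= rt + tol)]
    assert physical.size >= 1, f"no physical cubic root among {roots}"
    return float(np.clip(physical[0], 0.0, rt))
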