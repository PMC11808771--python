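#!/usr/bin/env python
"""Re-derive the Lebedev quadrature tables frozen in stresskit/lebedev.py.

For each rule degree the octahedral orbit structure is fixed; orbit
parameters are solved by nonlinear least squares with the weights
eliminated by a linear solve at every step, enforcing exactness on all
even monomials x^(2a) y^(2b) z^(2c) up to the rule degree (the exact
sphere moments are products of double factorials). Residuals reach
~1e-15; the solutions reproduce the classical tables, including the
negative corner weight of the 74-point rule.

Usage: python scripts/derive_lebedev_tables.py
Prints the orbit weights/parameters for degrees 9-17 (the lower rules
are rational and hard-coded directly).
"""

from math import sqrt

import numpy as np
from scipy.optimize import least_squares

from stresskit.lebedev import _orbit


def dfact(n):
    r = 1
    while n > 1:
        r *= n
        n -= 2
    return r


def exact_moment(a, b, c):
    n = a + b + c
    return dfact(2 * a - 1) * dfact(2 * b - 1) * dfact(2 * c - 1) / dfact(2 * n + 1)


def monomials(degree):
    out = []
    for n in range(degree // 2 + 1):
        for a in range(n, -1, -1):
            for b in range(n - a, -1, -1):
                c = n - a - b
                if a >= b >= c:
                    out.append((a, b, c))
    return out


def moment_matrix(structure, params, mons):
    cols = []
    pi = 0
    for kind, has_param in structure:
        par = params[pi] if has_param else None
        if has_param:
            pi += 1
        P = _orbit(kind, par)
        cols.append(
            np.array([
                np.sum(P[:, 0] ** (2 * a) * P[:, 1] ** (2 * b) * P[:, 2] ** (2 * c))
                for a, b, c in mons
            ])
        )
    A = np.array(cols).T
    b = np.array([exact_moment(a, b_, c) for a, b_, c in mons])
    return A, b


def solve_rule(structure, degree, tries=2000, seed=7):
    mons = monomials(degree)
    n_par = sum(1 for _, h in structure if h)
    rng = np.random.default_rng(seed)

    def residual(p):
        A, b = moment_matrix(structure, p, mons)
        w, *_ = np.linalg.lstsq(A, b, rcond=None)
        return A @ w - b

    for _ in range(tries):
        p0 = rng.uniform(0.05, 0.7, n_par)
        sol = least_squares(residual, p0, bounds=(1e-3, 0.70710),
                            xtol=3e-16, ftol=3e-16, gtol=3e-16, max_nfev=600)
        r = residual(sol.x)
        if np.max(np.abs(r)) < 1e-14:
            A, b = moment_matrix(structure, sol.x, mons)
            w, *_ = np.linalg.lstsq(A, b, rcond=None)
            return sol.x, w, float(np.max(np.abs(r)))
    raise RuntimeError(f"no solution found for degree {degree}")


RULES = {
    9: [(1, False), (3, False), (5, True)],
    11: [(1, False), (2, False), (3, False), (4, True)],
    13: [(1, False), (2, False), (3, False), (4, True), (5, True)],
    15: [(1, False), (3, False), (4, True), (4, True), (5, True)],
    17: [(1, False), (3, False), (4, True), (4, True), (4, True), (5, True)],
}


def main():
    for degree, structure in RULES.items():
        params, weights, res = solve_rule(structure, degree)
        npts = sum(len(_orbit(k, params[0] if h else None)) for k, h in structure)
        print(f"degree {degree} ({npts} points), max moment residual {res:.2e}")
        pi = 0
        for (kind, has_param), w in zip(structure, weights):
            par = None
            if has_param:
                par = params[pi]
                pi += 1
            print(f"  orbit kind {kind}: weight {w:.16e}"
                  + (f"  parameter {par:.16f}" if par is not None else ""))


if __name__ == "__main__":
    main()
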