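"""Lebedev quadrature on the sphere.

Rules are invariant under the full octahedral group (with inversion) and
integrate all spherical harmonics up to their degree exactly. Each rule
is stored as a list of symmetry orbits ``(kind, weight, parameter)``;
weights are normalized to sum to 1 over the unit sphere and scaled to
4*pi on construction.

The orbit parameters and weights below were obtained by solving the
defining exactness equations (moment matching for all even monomials up
to the rule degree) to ~1e-15 residual; they reproduce the classical
tabulated rules, including the well-known negative corner weight of the
74-point rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

__all__ = ["LebedevSphere", "lebedev_sphere", "available_degrees", "lebedev_unit_points"]

# orbit kinds: 1 = (1,0,0)x6, 2 = (a,a,0)x12, 3 = (a,a,a)x8,
#              4 = (l,l,m)x24 with m = sqrt(1-2l^2), 5 = (p,q,0)x24 with q = sqrt(1-p^2)
_RULES = {
    3: [(1, 1.0 / 6.0, None)],
    5: [(1, 1.0 / 15.0, None), (3, 3.0 / 40.0, None)],
    7: [(1, 1.0 / 21.0, None), (2, 4.0 / 105.0, None), (3, 9.0 / 280.0, None)],
    9: [
        (1, 9.5238095238093182e-03, None),
        (3, 3.2142857142857167e-02, None),
        (5, 2.8571428571428588e-02, 0.4597008433809829),
    ],
    11: [
        (1, 1.2698412698412881e-02, None),
        (2, 2.2574955908289250e-02, None),
        (3, 2.1093749999999925e-02, None),
        (4, 2.0173335537918852e-02, 0.3015113445777641),
    ],
    13: [
        (1, 5.1306717973432451e-04, None),
        (2, 1.6604069565742122e-02, None),
        (3, -2.9586038961028356e-02, None),
        (4, 2.6576207082156082e-02, 0.4803844614152523),
        (5, 1.6522170993715429e-02, 0.3207726489807768),
    ],
    15: [
        (1, 1.1544011544011964e-02, None),
        (3, 1.1943909085856293e-02, None),
        (4, 1.1876501294537434e-02, 0.6943540066026653),
        (4, 1.1110555710603237e-02, 0.3696028464541448),
        (5, 1.1812303746904266e-02, 0.3742430390903456),
    ],
    17: [
        (1, 3.8282704977729001e-03, None),
        (3, 9.7937375118657254e-03, None),
        (4, 9.5954713356854009e-03, 0.3956894730655402),
        (4, 9.9428148910578971e-03, 0.6904210483823495),
        (4, 8.2117372831832028e-03, 0.1851156353643704),
        (5, 9.6949963616750571e-03, 0.4783690288138971),
    ],
}


def available_degrees() -> list:
    return sorted(_RULES)


def _orbit(kind: int, par) -> np.ndarray:
    if kind == 1:
        pts = []
        for ax in range(3):
            for s in (1.0, -1.0):
                p = [0.0, 0.0, 0.0]
                p[ax] = s
                pts.append(p)
        return np.array(pts)
    if kind == 2:
        a = 1.0 / sqrt(2.0)
        pts = []
        for i, j in ((0, 1), (0, 2), (1, 2)):
            for si in (1.0, -1.0):
                for sj in (1.0, -1.0):
                    p = [0.0, 0.0, 0.0]
                    p[i] = si * a
                    p[j] = sj * a
                    pts.append(p)
        return np.array(pts)
    if kind == 3:
        a = 1.0 / sqrt(3.0)
        return np.array(
            [[sx * a, sy * a, sz * a] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
        )
    if kind == 4:
        l = par
        m = sqrt(max(0.0, 1.0 - 2.0 * l * l))
        pts = []
        for pos in range(3):
            for sm in (1.0, -1.0):
                for s1 in (1.0, -1.0):
                    for s2 in (1.0, -1.0):
                        comp = [s1 * l, s2 * l]
                        comp.insert(pos, sm * m)
                        pts.append(comp)
        return np.array(pts)
    if kind == 5:
        p_ = par
        q = sqrt(max(0.0, 1.0 - p_ * p_))
        pts = []
        for i, j in ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)):
            for si in (1.0, -1.0):
                for sj in (1.0, -1.0):
                    v = [0.0, 0.0, 0.0]
                    v[i] = si * p_
                    v[j] = sj * q
                    pts.append(v)
        return np.array(pts)
    raise ValueError(f"unknown orbit kind {kind}")


def lebedev_unit_points(degree: int):
    """Unit-sphere nodes and weights (weights sum to 4*pi)."""
    try:
        rule = _RULES[degree]
    except KeyError:
        raise ValueError(
            f"no Lebedev rule of degree {degree}; available degrees: {available_degrees()}"
        ) from None
    pts = []
    wts = []
    for kind, w, par in rule:
        P = _orbit(kind, par)
        pts.append(P)
        wts.append(np.full(len(P), w))
    x = np.vstack(pts)
    w = np.concatenate(wts) * 4.0 * np.pi
    return x, w


@dataclass(frozen=True)
class LebedevSphere:
    """Quadrature sphere: center, radius, unit nodes, weights and
    outward normals. ``surface_integral(f_at_points)`` evaluates
    ``radius^2 * sum(w_k * f_k)``."""

    center: tuple
    radius: float
    degree: int
    unit_points: np.ndarray  # (n, 3), |x| = 1
    weights: np.ndarray  # sum = 4*pi

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.center) + self.radius * self.unit_points

    @property
    def normals(self) -> np.ndarray:
        """Outward unit normals (radial directions)."""
        return self.unit_points

    @property
    def n_points(self) -> int:
        return len(self.weights)

    def surface_integral(self, values: np.ndarray) -> np.ndarray:
        """Integrate sampled values over the sphere surface.

        `values` has shape (n, ...); integration contracts the first axis.
        """
        v = np.asarray(values)
        return self.radius**2 * np.tensordot(self.weights, v, axes=(0, 0))


def lebedev_sphere(center, radius: float, degree: int = 17) -> LebedevSphere:
    if radius <= 0:
        raise ValueError("sphere radius must be positive")
    x, w = lebedev_unit_points(degree)
    return LebedevSphere(tuple(float(c) for c in np.asarray(center, float)),
                         float(radius), int(degree), x, w)
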