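"""Exchange-correlation functionals (closed-shell).

Built-in default is SVWN5: Slater exchange plus the VWN5 parametrization
of the correlation energy of the homogeneous electron gas
(spin-unpolarized). A GGA evaluator can be plugged in; it must supply
the gradient-channel derivative d(rho*eps_xc)/d(grad rho) that enters
the exchange-correlation stress.

Evaluator contract: ``evaluator(rho, sigma=None)`` with ``sigma =
|grad rho|^2`` returns ``(eps_xc, dfdrho, dfdsigma)`` where ``f = rho *
eps_xc``; for LDA ``dfdsigma`` is None and ``dfdrho`` is already the
full v_xc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .fields import ScalarField, VectorField, differentiate

__all__ = ["XCFunctional", "svwn5", "lda_slater", "toy_gga", "no_xc", "xc_eval"]

RHO_FLOOR = 1e-12

_CX = -(3.0 / 4.0) * (3.0 / np.pi) ** (1.0 / 3.0)  # Slater exchange prefactor

# VWN5 paramagnetic parameters
_VWN_A = 0.0310907
_VWN_X0 = -0.10498
_VWN_B = 3.72744
_VWN_C = 12.9352


@dataclass(frozen=True)
class XCFunctional:
    name: str
    kind: str  # "lda" | "gga" | "none"
    evaluator: Callable

    def __call__(self, rho, sigma=None):
        return self.evaluator(rho, sigma)


def _clip_density(rho):
    rho = np.asarray(rho, float)
    if np.any(rho < -1e-8):
        raise ValueError(f"density has negative values down to {rho.min():.3e}")
    return np.clip(rho, 0.0, None)


def _slater(rho):
    eps = _CX * rho ** (1.0 / 3.0)
    vx = (4.0 / 3.0) * eps
    return eps, vx


def _vwn5(rho):
    """VWN5 correlation energy per electron and potential (paramagnetic)."""
    rs = (3.0 / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
    x = np.sqrt(rs)
    b, c, x0, A = _VWN_B, _VWN_C, _VWN_X0, _VWN_A
    Q = np.sqrt(4 * c - b * b)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    atn = np.arctan(Q / (2 * x + b))
    eps = A * (
        np.log(x * x / X)
        + (2 * b / Q) * atn
        - (b * x0 / X0) * (np.log((x - x0) ** 2 / X) + (2 * (b + 2 * x0) / Q) * atn)
    )
    dXdx = 2 * x + b
    datn = -2.0 / (dXdx**2 + Q * Q)  # d atan(Q/(2x+b))/dx / Q
    deps_dx = A * (
        2.0 / x
        - dXdx / X
        + 2 * b * datn
        - (b * x0 / X0) * (2.0 / (x - x0) - dXdx / X + 2 * (b + 2 * x0) * datn)
    )
    # v_c = eps - (rs/3) deps/drs = eps - (x/6) deps/dx
    vc = eps - (x / 6.0) * deps_dx
    return eps, vc


def _eval_svwn5(rho, sigma=None):
    rho = _clip_density(rho)
    eps = np.zeros_like(rho)
    v = np.zeros_like(rho)
    ok = rho > RHO_FLOOR
    if np.any(ok):
        ex, vx = _slater(rho[ok])
        ec, vc = _vwn5(rho[ok])
        eps[ok] = ex + ec
        v[ok] = vx + vc
    return eps, v, None


def _eval_slater(rho, sigma=None):
    rho = _clip_density(rho)
    eps = np.zeros_like(rho)
    v = np.zeros_like(rho)
    ok = rho > RHO_FLOOR
    if np.any(ok):
        eps[ok], v[ok] = _slater(rho[ok])
    return eps, v, None


def _eval_none(rho, sigma=None):
    z = np.zeros_like(np.asarray(rho, float))
    return z, z.copy(), None


svwn5 = XCFunctional("SVWN5", "lda", _eval_svwn5)
lda_slater = XCFunctional("Slater-X", "lda", _eval_slater)
no_xc = XCFunctional("none", "none", _eval_none)


def toy_gga(a: float = 0.5, b: float = 0.05) -> XCFunctional:
    """Analytically simple GGA, eps_xc = -a rho^(1/3) - b |grad rho|^2 / rho^(4/3).

    Used to exercise the gradient channel of the stress with a
    closed-form functional derivative.
    """

    def _eval(rho, sigma=None):
        rho = _clip_density(rho)
        if sigma is None:
            raise ValueError("toy GGA needs sigma = |grad rho|^2")
        sigma = np.asarray(sigma, float)
        eps = np.zeros_like(rho)
        dfdrho = np.zeros_like(rho)
        dfdsigma = np.zeros_like(rho)
        ok = rho > RHO_FLOOR
        r = rho[ok]
        s = sigma[ok]
        eps[ok] = -a * r ** (1.0 / 3.0) - b * s / r ** (4.0 / 3.0)
        dfdrho[ok] = -(4.0 / 3.0) * a * r ** (1.0 / 3.0) + (b / 3.0) * s / r ** (4.0 / 3.0)
        dfdsigma[ok] = -b / r ** (1.0 / 3.0)
        return eps, dfdrho, dfdsigma

    return XCFunctional(f"toyGGA(a={a},b={b})", "gga", _eval)


def xc_eval(
    functional: XCFunctional,
    rho: ScalarField,
    grad_rho: Optional[VectorField] = None,
):
    """Evaluate a functional on grid fields.

    Returns ``(eps_xc, v_xc, fgrad)`` as fields; ``fgrad`` is the
    gradient-channel derivative d(rho eps)/d(grad rho) (None for LDA).
    For a GGA the full potential v_xc = df/drho - div(fgrad) is
    assembled here with finite differences.
    """
    grid = rho.grid
    if functional.kind == "gga":
        if grad_rho is None:
            grad_rho = differentiate(rho, "gradient")
        sigma = np.sum(grad_rho.values**2, axis=-1)
        eps, dfdrho, dfdsigma = functional(rho.values, sigma)
        fgrad = 2.0 * dfdsigma[..., None] * grad_rho.values
        div = np.zeros(grid.shape)
        for i in range(3):
            div += differentiate(ScalarField(grid, fgrad[..., i]), "gradient").values[..., i]
        vxc = dfdrho - div
        return ScalarField(grid, eps), ScalarField(grid, vxc), VectorField(grid, fgrad)
    eps, vxc, _ = functional(rho.values)
    return ScalarField(grid, eps), ScalarField(grid, vxc), None
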