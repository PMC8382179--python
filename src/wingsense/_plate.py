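"""Assumed-modes (Rayleigh-Ritz) machinery for the clamped flat-plate wing.

The wing is a thin Kirchhoff plate occupying x in [0, span] (spanwise, clamped
along x = 0) and y in [0, chord] (chordwise, free edges).  Transverse
deflection is expanded as

    w(x, y, t) = sum_k eta_k(t) * Phi_k(x, y),

where the Phi_k are mass-orthonormal eigenmodes of the Rayleigh-Ritz problem
built from a separable basis of clamped-free beam functions in x and
free-free beam functions (including the rigid translation and rotation) in y.
The rigid chordwise rotation term is what carries wing twist.

Everything here is geometry/material only; the time-dependent forcing and
integration live in :mod:`wingsense.wing`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss

# clamped-free (cantilever) beam eigenvalue roots beta*L; beyond the tabled
# values the asymptote (2k-1) pi/2 is exact to double precision
_CF_ROOTS = np.concatenate([
    [1.875104068711961, 4.694091132974175, 7.854757438237613,
     10.995540734875467, 14.137168391046471],
    (2.0 * np.arange(6, 12) - 1.0) * np.pi / 2.0])
# free-free elastic beam roots beta*L; asymptote (2k+1) pi/2
_FF_ROOTS = np.concatenate([
    [4.730040744862704, 7.853204624095838, 10.995607838001671],
    (2.0 * np.arange(4, 10) + 1.0) * np.pi / 2.0])


def _clamped_free(xi: np.ndarray, root: float, deriv: int) -> np.ndarray:
    """Cantilever beam eigenfunction (or derivative) on xi in [0, 1]."""
    b = root
    sigma = (np.cosh(b) + np.cos(b)) / (np.sinh(b) + np.sin(b))
    z = b * xi
    if deriv == 0:
        return np.cosh(z) - np.cos(z) - sigma * (np.sinh(z) - np.sin(z))
    if deriv == 1:
        return b * (np.sinh(z) + np.sin(z) - sigma * (np.cosh(z) - np.cos(z)))
    if deriv == 2:
        return b**2 * (np.cosh(z) + np.cos(z) - sigma * (np.sinh(z) + np.sin(z)))
    raise ValueError(deriv)


def _free_free(xi: np.ndarray, root: float, deriv: int) -> np.ndarray:
    """Elastic free-free beam eigenfunction (or derivative) on xi in [0, 1]."""
    b = root
    sigma = (np.cosh(b) - np.cos(b)) / (np.sinh(b) - np.sin(b))
    z = b * xi
    if deriv == 0:
        return np.cosh(z) + np.cos(z) - sigma * (np.sinh(z) + np.sin(z))
    if deriv == 1:
        return b * (np.sinh(z) - np.sin(z) - sigma * (np.cosh(z) + np.cos(z)))
    if deriv == 2:
        return b**2 * (np.cosh(z) - np.cos(z) - sigma * (np.sinh(z) - np.sin(z)))
    raise ValueError(deriv)


class _SpanBasis:
    """Clamped-free beam functions in the spanwise coordinate, L2-normalized."""

    def __init__(self, n: int, length: float):
        self.n = n
        self.length = length
        self._roots = _CF_ROOTS[:n]
        # normalize so that integral of phi^2 over [0, L] equals 1
        xg, wg = leggauss(64)
        xi = 0.5 * (xg + 1.0)
        w = 0.5 * wg * length
        self._norm = np.empty(n)
        for i, r in enumerate(self._roots):
            self._norm[i] = 1.0 / np.sqrt(np.sum(_clamped_free(xi, r, 0) ** 2 * w))

    def eval(self, x: np.ndarray, deriv: int = 0) -> np.ndarray:
        """Shape (n, len(x)); derivatives are with respect to physical x."""
        xi = np.asarray(x, float) / self.length
        out = np.stack([_clamped_free(xi, r, deriv) for r in self._roots])
        return out * (self._norm / self.length**deriv)[:, None]


class _ChordBasis:
    """Free-free basis in the chordwise coordinate: rigid translation, rigid
    rotation about mid-chord, then elastic free-free modes.  L2-normalized."""

    def __init__(self, n: int, length: float):
        self.n = n
        self.length = length
        self._n_elastic = max(0, n - 2)

    def eval(self, y: np.ndarray, deriv: int = 0) -> np.ndarray:
        y = np.asarray(y, float)
        c = self.length
        xi = y / c
        rows = []
        if self.n >= 1:  # rigid translation
            rows.append(np.full_like(y, 1.0 / np.sqrt(c)) if deriv == 0
                        else np.zeros_like(y))
        if self.n >= 2:  # rigid rotation about mid-chord (the twist carrier)
            if deriv == 0:
                rows.append(np.sqrt(12.0 / c**3) * (y - c / 2.0))
            elif deriv == 1:
                rows.append(np.full_like(y, np.sqrt(12.0 / c**3)))
            else:
                rows.append(np.zeros_like(y))
        xg, wg = leggauss(64)
        xig = 0.5 * (xg + 1.0)
        wq = 0.5 * wg * c
        for r in _FF_ROOTS[: self._n_elastic]:
            norm = 1.0 / np.sqrt(np.sum(_free_free(xig, r, 0) ** 2 * wq))
            rows.append(_free_free(xi, r, deriv) * norm / c**deriv)
        return np.stack(rows)


@dataclass
class PlateModel:
    """Mass-orthonormal eigenmodes of the clamped rectangular plate.

    Parameters follow the physical wing: dimensions in meters, Young's modulus
    in Pa.  ``n_span``/``n_chord`` set the Ritz basis size (defaults give a
    9-term basis: 3 spanwise bending x [translation, twist, camber]).
    """

    span: float
    chord: float
    thickness: float
    youngs_modulus: float
    density: float = 1200.0
    poisson: float = 0.3
    # orthotropic rigidity multipliers over the flat-plate D = E h^3/12(1-nu^2):
    # corrugation/venation stiffens spanwise bending far more than chordwise
    # bending or torsion
    rigidity_factor: float = 1.0          # spanwise (D_x)
    chord_rigidity_factor: float = 1.0    # chordwise (D_y)
    torsion_rigidity_factor: float = 1.0  # twisting (D_xy)
    n_span: int = 3
    n_chord: int = 3
    n_quad: tuple[int, int] = (32, 20)

    omega: np.ndarray = field(init=False)       # modal angular frequencies (rad/s)
    modes: np.ndarray = field(init=False)       # (n_basis, n_modes) Ritz coefficients
    quad_x: np.ndarray = field(init=False)
    quad_y: np.ndarray = field(init=False)
    quad_w: np.ndarray = field(init=False)
    phi_quad: np.ndarray = field(init=False)    # (n_modes, n_quad) mode shapes at quad pts
    geometric_stiffness: np.ndarray = field(init=False)  # (n_modes, n_modes), per unit rate^2

    def __post_init__(self):
        L, c, h = self.span, self.chord, self.thickness
        D0 = self.youngs_modulus * h**3 / (12.0 * (1.0 - self.poisson**2))
        Dx = self.rigidity_factor * D0
        Dy = self.chord_rigidity_factor * D0
        Dxy = self.torsion_rigidity_factor * D0
        D1 = self.poisson * np.sqrt(Dx * Dy)  # orthotropic coupling rigidity
        rho_h = self.density * h

        sb = _SpanBasis(self.n_span, L)
        cb = _ChordBasis(self.n_chord, c)

        # tensor quadrature grid
        xg, xw = leggauss(self.n_quad[0])
        yg, yw = leggauss(self.n_quad[1])
        xq = 0.5 * (xg + 1.0) * L
        yq = 0.5 * (yg + 1.0) * c
        X, Y = np.meshgrid(xq, yq, indexing="ij")
        WQ = np.outer(0.5 * xw * L, 0.5 * yw * c)
        self.quad_x = X.ravel()
        self.quad_y = Y.ravel()
        self.quad_w = WQ.ravel()

        # separable basis values and derivatives at quadrature nodes
        P = {d: sb.eval(xq, d) for d in (0, 1, 2)}       # (n_span, nx)
        Q = {d: cb.eval(yq, d) for d in (0, 1, 2)}       # (n_chord, ny)

        n_basis = self.n_span * self.n_chord
        nq = self.quad_x.size

        def field_vals(dx: int, dy: int) -> np.ndarray:
            out = np.empty((n_basis, nq))
            k = 0
            for i in range(self.n_span):
                for j in range(self.n_chord):
                    out[k] = np.outer(P[dx][i], Q[dy][j]).ravel()
                    k += 1
            return out

        N00 = field_vals(0, 0)
        Nxx = field_vals(2, 0)
        Nyy = field_vals(0, 2)
        Nxy = field_vals(1, 1)

        w = self.quad_w
        M = rho_h * (N00 * w) @ N00.T
        nu = self.poisson
        K = (Dx * (Nxx * w) @ Nxx.T + Dy * (Nyy * w) @ Nyy.T
             + D1 * ((Nxx * w) @ Nyy.T + (Nyy * w) @ Nxx.T)
             + 2.0 * (1.0 - nu) * Dxy * (Nxy * w) @ Nxy.T)

        from scipy.linalg import eigh
        lam, V = eigh(K, M)
        lam = np.clip(lam, 0.0, None)
        self.omega = np.sqrt(lam)
        self.modes = V  # M-orthonormal: V.T @ M @ V = I
        self.phi_quad = V.T @ N00

        # geometric stiffness from spanwise centrifugal tension at unit
        # rotation rate about a chordwise axis through the root:
        # T(x) = rho_h (L^2 - x^2) / 2, energy 1/2 int T w_x^2 dA
        Nx = field_vals(1, 0)
        tension = rho_h * (L**2 - self.quad_x**2) / 2.0
        Kg = (Nx * (tension * w)) @ Nx.T
        self.geometric_stiffness = V.T @ Kg @ V
        self._span_basis = sb
        self._chord_basis = cb
        self._rho_h = rho_h

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def mode_shapes(self, x: np.ndarray, y: np.ndarray,
                    dx: int = 0, dy: int = 0) -> np.ndarray:
        """Evaluate (derivatives of) all eigenmodes at points (x_i, y_i).

        Returns an array of shape (n_modes, len(x)).
        """
        P = self._span_basis.eval(np.asarray(x, float), dx)
        Q = self._chord_basis.eval(np.asarray(y, float), dy)
        n_basis = self.n_span * self.n_chord
        vals = np.empty((n_basis, len(np.atleast_1d(x))))
        k = 0
        for i in range(self.n_span):
            for j in range(self.n_chord):
                vals[k] = P[i] * Q[j]
                k += 1
        return self.modes.T @ vals

    def strain_matrix(self, x: np.ndarray, y: np.ndarray,
                      direction: str = "spanwise") -> np.ndarray:
        """Surface normal strain per unit modal coordinate at points (x, y).

        eps = -(h/2) * d2w/dx2 (spanwise) or -(h/2) * d2w/dy2 (chordwise),
        evaluated analytically from the basis.  Shape (len(x), n_modes).
        """
        if direction == "spanwise":
            curv = self.mode_shapes(x, y, dx=2, dy=0)
        elif direction == "chordwise":
            curv = self.mode_shapes(x, y, dx=0, dy=2)
        else:
            raise ValueError(f"unknown strain direction: {direction!r}")
        return (-(self.thickness / 2.0) * curv).T
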