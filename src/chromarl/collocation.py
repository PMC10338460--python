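"""Orthogonal-collocation grids for the column model.

The axial and radial domains are split into equal-width elements. Within each
element every field is represented by a degree-``order`` interpolating
polynomial whose nodes are the element boundaries plus the roots of the
shifted Legendre polynomial of degree ``order - 1`` (Gauss points). Adjacent
elements share the boundary node (C0 by construction); C1 continuity is
imposed when the discretized equations are assembled by replacing the PDE row
at each interface node with a first-derivative matching condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid1D", "CollocationGrid", "build_grid_1d", "build_collocation_grid"]


class ConfigurationError(ValueError):
    """Invalid discretization or physical configuration."""


def _element_reference_nodes(order: int) -> np.ndarray:
    """Nodes on [0, 1]: endpoints plus Gauss-Legendre points of P_{order-1}."""
    if order < 1:
        raise ConfigurationError(f"polynomial order must be >= 1, got {order}")
    if order == 1:
        return np.array([0.0, 1.0])
    gauss, _ = np.polynomial.legendre.leggauss(order - 1)
    return np.concatenate(([0.0], 0.5 * (gauss + 1.0), [1.0]))


def lagrange_diff_matrix(x: np.ndarray) -> np.ndarray:
    """First-derivative matrix of Lagrange interpolation through nodes ``x``.

    Exact for polynomials of degree <= len(x) - 1 evaluated at the nodes.
    Uses barycentric weights; rows sum to zero exactly by construction of the
    diagonal.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    w = np.empty(n)
    for j in range(n):
        w[j] = 1.0 / np.prod(x[j] - np.delete(x, j))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = (w[j] / w[i]) / (x[i] - x[j])
        D[i, i] = -np.sum(D[i, :])  # constants differentiate to zero
    return D


def _quad_weights(nodes: np.ndarray, a: float, b: float, moment) -> np.ndarray:
    """Weights w with sum w_j f(x_j) = int_a^b f(x) omega(x) dx exactly for
    polynomials f up to degree len(nodes)-1. ``moment(k)`` returns
    int_a^b (x - xc)^k omega(x) dx for the element midpoint xc."""
    xc = 0.5 * (a + b)
    n = len(nodes)
    V = np.vander(nodes - xc, n, increasing=True).T  # V[k, j] = (x_j - xc)^k
    m = np.array([moment(k) for k in range(n)])
    return np.linalg.solve(V, m)


@dataclass
class Grid1D:
    """Multi-element collocation grid on [0, length]."""

    length: float
    n_elements: int
    order: int
    nodes: np.ndarray                 # (n_nodes,)
    elem_index: np.ndarray            # (n_elements, order+1) global node ids
    D1_elem: np.ndarray               # (n_elements, order+1, order+1)
    D2_elem: np.ndarray
    quad_weights: np.ndarray          # plain: sum w f = int f dx
    D1: np.ndarray = field(repr=False, default=None)  # global, averaged at interfaces
    D2: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    @property
    def interface_nodes(self) -> np.ndarray:
        """Global indices of element interfaces (excluding domain boundaries)."""
        return np.arange(1, self.n_elements) * self.order

    def interior_mask(self) -> np.ndarray:
        """True where the PDE is collocated (not boundary, not interface)."""
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[0] = mask[-1] = False
        mask[self.interface_nodes] = False
        return mask


def build_grid_1d(length: float, n_elements: int, order: int) -> Grid1D:
    if length <= 0:
        raise ConfigurationError(f"domain length must be positive, got {length}")
    if n_elements < 1:
        raise ConfigurationError(f"element count must be >= 1, got {n_elements}")
    ref = _element_reference_nodes(order)
    width = length / n_elements
    n_nodes = n_elements * order + 1
    nodes = np.empty(n_nodes)
    elem_index = np.empty((n_elements, order + 1), dtype=np.int64)
    for e in range(n_elements):
        gids = e * order + np.arange(order + 1)
        elem_index[e] = gids
        nodes[gids] = e * width + ref * width

    D_ref = lagrange_diff_matrix(ref)
    D1_loc = D_ref / width
    D2_loc = (D_ref @ D_ref) / width**2
    D1_elem = np.broadcast_to(D1_loc, (n_elements, order + 1, order + 1)).copy()
    D2_elem = np.broadcast_to(D2_loc, (n_elements, order + 1, order + 1)).copy()

    # plain quadrature weights, exact through degree `order`
    qw = np.zeros(n_nodes)
    for e in range(n_elements):
        a, b = e * width, (e + 1) * width
        half = 0.5 * (b - a)

        def mom(k, half=half):
            # int_a^b (x - xc)^k dx
            return 0.0 if k % 2 else 2.0 * half ** (k + 1) / (k + 1)

        qw[elem_index[e]] += _quad_weights(nodes[elem_index[e]], a, b, mom)

    # global derivative operators: interface rows average the two elements
    D1g = np.zeros((n_nodes, n_nodes))
    D2g = np.zeros((n_nodes, n_nodes))
    counts = np.zeros(n_nodes)
    for e in range(n_elements):
        gi = elem_index[e]
        for li, g in enumerate(gi):
            D1g[g, gi] += D1_elem[e, li]
            D2g[g, gi] += D2_elem[e, li]
        counts[gi] += 1
    D1g /= counts[:, None]
    D2g /= counts[:, None]

    return Grid1D(length, n_elements, order, nodes, elem_index,
                  D1_elem, D2_elem, qw, D1g, D2g)


def sphere_quad_weights(grid: Grid1D) -> np.ndarray:
    """Weights w with sum w_j f(r_j) = int_0^R f(r) r^2 dr, exact for
    polynomial f up to the grid order (used for volume averages over
    spherical resin particles)."""
    n_nodes = grid.n_nodes
    qw = np.zeros(n_nodes)
    width = grid.length / grid.n_elements
    for e in range(grid.n_elements):
        a, b = e * width, (e + 1) * width
        xc = 0.5 * (a + b)
        half = 0.5 * (b - a)

        def mom(k, xc=xc, half=half):
            # int (x-xc)^k x^2 dx = int (x-xc)^(k+2) + 2 xc (x-xc)^(k+1) + xc^2 (x-xc)^k
            def plain(p):
                return 0.0 if p % 2 else 2.0 * half ** (p + 1) / (p + 1)

            return plain(k + 2) + 2.0 * xc * plain(k + 1) + xc**2 * plain(k)

        qw[grid.elem_index[e]] += _quad_weights(
            grid.nodes[grid.elem_index[e]], a, b, mom)
    return qw


@dataclass
class CollocationGrid:
    """Axial x radial collocation discretization of one column."""

    axial: Grid1D
    radial: Grid1D
    radial_sphere_weights: np.ndarray  # sum w f(r) = int f r^2 dr over [0, r_p]

    @property
    def n_axial(self) -> int:
        return self.axial.n_nodes

    @property
    def n_radial(self) -> int:
        return self.radial.n_nodes

    def radial_volume_average(self, f: np.ndarray) -> np.ndarray:
        """Volume-weighted average over the particle: 3/r_p^3 int f r^2 dr.

        ``f`` has the radial coordinate on its last axis.
        """
        r_p = self.radial.length
        return (f @ self.radial_sphere_weights) * (3.0 / r_p**3)


def build_collocation_grid(L: float, r_p: float, n_z: int, n_r: int,
                           order: int) -> CollocationGrid:
    axial = build_grid_1d(L, n_z, order)
    radial = build_grid_1d(r_p, n_r, order)
    return CollocationGrid(axial, radial, sphere_quad_weights(radial))
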