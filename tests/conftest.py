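"""Shared fixtures: analytic meshes and small synthetic populations."""

from __future__ import annotations

import numpy as np
import pytest

from lvshape.mesh import TriangleMesh


def make_icosphere(radius: float = 1.0, subdiv: int = 2) -> TriangleMesh:
    """Subdivided icosahedron projected onto the sphere (analytic oracle)."""
    t = (1 + 5**0.5) / 2
    V = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    F = [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ]
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    for _ in range(subdiv):
        V = list(V)
        mid: dict[tuple[int, int], int] = {}
        NF = []

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in mid:
                p = (np.asarray(V[i]) + np.asarray(V[j])) / 2
                p /= np.linalg.norm(p)
                V.append(p)
                mid[key] = len(V) - 1
            return mid[key]

        for a, b, c in F:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            NF += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        F = NF
        V = np.asarray(V)
    return TriangleMesh(np.asarray(V) * radius, np.asarray(F))


def make_ellipse_contour(a: float, b: float, n: int = 400) -> np.ndarray:
    """Closed ellipse polyline, long axis along +y, starting at the top."""
    th = np.linspace(0.5 * np.pi, 2.5 * np.pi, n, endpoint=False)
    return np.column_stack([b * np.cos(th), a * np.sin(th)])


@pytest.fixture(scope="session")
def unit_sphere() -> TriangleMesh:
    return make_icosphere(1.0, 3)


@pytest.fixture(scope="session")
def sphere30() -> TriangleMesh:
    return make_icosphere(30.0, 4)


@pytest.fixture(scope="session")
def sphere25_coarse() -> TriangleMesh:
    return make_icosphere(25.0, 2)


def copy_mesh(m: TriangleMesh, label: str) -> TriangleMesh:
    return TriangleMesh(m.vertices.copy(), m.faces.copy(), label)
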