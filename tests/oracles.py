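"""Independent brute-force oracles used only by tests.

These deliberately avoid the code paths of the package: connected components
via scipy's labeling, local thickness via an exhaustive all-centres ×
all-radii disc search with distances computed by explicit minimisation, and
Holm adjustment via a literal transcription of the step-down definition.
"""

import numpy as np
from scipy import ndimage

FOUR = ndimage.generate_binary_structure(2, 1)


def label_holes(marrow: np.ndarray) -> tuple[int, np.ndarray]:
    """4-connected components of a marrow map: (count, sorted pixel areas)."""
    lab, n = ndimage.label(marrow, structure=FOUR)
    areas = np.sort(ndimage.sum_labels(np.ones_like(lab), lab,
                                       index=np.arange(1, n + 1)))
    return n, areas


def brute_local_thickness(phase: np.ndarray, obstacles: np.ndarray
                          ) -> np.ndarray:
    """Exhaustive maximal-disc thickness in pixel units.

    For every phase centre c: the distance d(c) to the nearest obstacle pixel
    by explicit minimisation, the maximal disc radius d(c) − 1/2, and for
    every phase pixel p the diameter of the largest maximal disc covering it.
    """
    phase = np.asarray(phase, bool)
    obstacles = np.asarray(obstacles, bool)
    pc = np.argwhere(phase)
    oc = np.argwhere(obstacles)
    out = np.zeros(phase.shape)
    radii = {}
    for (i, j) in pc:
        d2 = ((oc[:, 0] - i) ** 2 + (oc[:, 1] - j) ** 2).min()
        radii[(i, j)] = np.sqrt(d2) - 0.5
    for (ci, cj), r in radii.items():
        if r <= 0:
            continue
        cover = (pc[:, 0] - ci) ** 2 + (pc[:, 1] - cj) ** 2 <= r * r + 1e-12
        for (pi, pj) in pc[cover]:
            out[pi, pj] = max(out[pi, pj], 2.0 * r)
    return out


def holm_stepdown(pvals) -> np.ndarray:
    """Literal step-down Holm definition, input order preserved."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def euler_number(binary: np.ndarray) -> int:
    """Components (8-connected) minus holes (enclosed 4-connected background)."""
    binary = np.asarray(binary, bool)
    _, n_comp = ndimage.label(binary, structure=np.ones((3, 3)))
    padded = np.pad(~binary, 1, constant_values=True)
    lab, n_bg = ndimage.label(padded, structure=FOUR)
    outside = lab[0, 0]
    n_holes = n_bg - 1  # all background components except the outside
    return n_comp - n_holes
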