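"""Conditional-random-field refinement of probability maps.

Labelings g over the pixel grid follow a Gibbs distribution

    p(U = g | F) = exp(−L(g|F)) / Z(F)

whose energy decomposes into unary and pairwise terms

    −L(g|F) = Σ_i t_i(g_i) + Σ_{(i,j)} t_ij(g_i, g_j).

Here the unary potential is the negative log of the segmenter's per-pixel
class probability, t_i(g_i) = −log p_i(g_i), and the pairwise potential is a
Potts term on the 4-neighborhood, t_ij(a, b) = w·1[a ≠ b], optionally
generalized to w·M[a, b] for a symmetric class-compatibility matrix M.  The
partition function Z(F) is intractable and never needed: MAP inference only
compares energies.

Inference is iterated conditional modes (ICM): starting from the argmax
labeling (or a caller-supplied one), checkerboard sweeps set each pixel to
the locally energy-minimal class until a sweep changes nothing.  Each
half-sweep updates an independent set of pixels, so the total energy is
non-increasing — asserted at every sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CRFError(ValueError):
    pass


_EPS = 1e-10


@dataclass
class CRFModel:
    """Unary potentials plus a Potts-style pairwise term on the 4-neighborhood.

    ``unary[k, i, j]`` is the cost of assigning class k at pixel (i, j);
    ``pairwise_weight`` scales the symmetric compatibility matrix
    ``pairwise_matrix`` (default Potts: 1 off-diagonal, 0 on it).
    """

    unary: np.ndarray  # (K, H, W)
    pairwise_weight: float = 0.5
    pairwise_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.unary = np.asarray(self.unary, dtype=float)
        if self.unary.ndim != 3:
            raise CRFError(f"unary must be (K, H, W), got {self.unary.shape}")
        K = self.unary.shape[0]
        if self.pairwise_matrix is None:
            self.pairwise_matrix = 1.0 - np.eye(K)
        else:
            self.pairwise_matrix = np.asarray(self.pairwise_matrix, dtype=float)
            if self.pairwise_matrix.shape != (K, K):
                raise CRFError(f"pairwise_matrix must be ({K}, {K})")
            if not np.allclose(self.pairwise_matrix, self.pairwise_matrix.T):
                raise CRFError("pairwise_matrix must be symmetric")

    @property
    def n_classes(self) -> int:
        return self.unary.shape[0]

    @classmethod
    def from_probabilities(
        cls,
        prob_map: np.ndarray,
        pairwise_weight: float = 0.5,
        pairwise_matrix: np.ndarray | None = None,
    ) -> "CRFModel":
        """Unary t_i = −log p_i; zero probabilities are clamped to a small epsilon."""
        prob_map = np.asarray(prob_map, dtype=float)
        if prob_map.ndim != 3:
            raise CRFError(f"probability map must be (K, H, W), got {prob_map.shape}")
        unary = -np.log(np.clip(prob_map, _EPS, None))
        return cls(unary=unary, pairwise_weight=pairwise_weight, pairwise_matrix=pairwise_matrix)


def crf_energy(labeling: np.ndarray, crf: CRFModel) -> float:
    """Exact energy Σ t_i(g_i) + Σ t_ij(g_i, g_j) over 4-neighbor edges.

    Each undirected edge is counted once.
    """
    labeling = np.asarray(labeling)
    if labeling.shape != crf.unary.shape[1:]:
        raise CRFError(f"labeling shape {labeling.shape} does not match unary {crf.unary.shape[1:]}")
    lab = labeling.astype(int)
    unary = np.take_along_axis(crf.unary, lab[None], axis=0).sum()
    M = crf.pairwise_matrix
    pair = M[lab[:-1, :], lab[1:, :]].sum() + M[lab[:, :-1], lab[:, 1:]].sum()
    return float(unary + crf.pairwise_weight * pair)


def _neighbor_cost(crf: CRFModel, lab: np.ndarray) -> np.ndarray:
    """Per-pixel, per-class pairwise cost given the current neighbor labels."""
    K = crf.n_classes
    H, W = lab.shape
    M = crf.pairwise_matrix
    cost = np.zeros((K, H, W))
    for k in range(K):
        row = M[k]
        c = np.zeros((H, W))
        c[1:, :] += row[lab[:-1, :]]
        c[:-1, :] += row[lab[1:, :]]
        c[:, 1:] += row[lab[:, :-1]]
        c[:, :-1] += row[lab[:, 1:]]
        cost[k] = c
    return cost


def icm(
    crf: CRFModel,
    init: np.ndarray,
    max_iter: int = 20,
) -> tuple[np.ndarray, list[float]]:
    """Checkerboard ICM from a given initial labeling.

    Returns the final labeling and the energy after initialization and after
    every sweep; monotone non-increase is asserted.
    """
    lab = np.asarray(init).astype(int).copy()
    if lab.shape != crf.unary.shape[1:]:
        raise CRFError("initial labeling shape mismatch")
    H, W = lab.shape
    yy, xx = np.indices((H, W))
    colors = [( (yy + xx) % 2 == 0 ), ((yy + xx) % 2 == 1)]
    energies = [crf_energy(lab, crf)]
    for _ in range(max_iter):
        changed = False
        for mask in colors:
            cost = crf.unary + crf.pairwise_weight * _neighbor_cost(crf, lab)
            best = cost.argmin(axis=0)  # ties -> smaller class index
            if np.any(best[mask] != lab[mask]):
                changed = True
                lab[mask] = best[mask]
        e = crf_energy(lab, crf)
        assert e <= energies[-1] + 1e-9, "ICM energy increased"
        energies.append(e)
        if not changed:
            break
    return lab.astype(np.uint8), energies


def crf_refine(
    prob_map: np.ndarray,
    pairwise_weight: float = 0.5,
    max_iter: int = 20,
    restarts: tuple[str, ...] = ("argmax",),
) -> np.ndarray:
    """Approximate MAP labeling of the Gibbs model by ICM.

    ``restarts`` selects the initial labelings tried ("argmax",
    "background", "foreground"); the lowest-energy result wins.  With
    ``pairwise_weight=0`` the result is exactly the per-pixel argmax.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    crf = CRFModel.from_probabilities(prob_map, pairwise_weight=pairwise_weight)
    argmax = prob_map.argmax(axis=0).astype(np.uint8)
    if pairwise_weight == 0:
        return argmax
    inits = {
        "argmax": argmax,
        "background": np.zeros_like(argmax),
        "foreground": np.ones_like(argmax) * min(1, crf.n_classes - 1),
    }
    best_lab, best_e = None, np.inf
    for name in restarts:
        if name not in inits:
            raise CRFError(f"unknown restart {name!r}")
        lab, energies = icm(crf, inits[name], max_iter=max_iter)
        if energies[-1] < best_e:
            best_lab, best_e = lab, energies[-1]
    return best_lab
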