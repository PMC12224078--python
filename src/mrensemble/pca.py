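"""Principal component analysis of a coordinate ensemble.

Each model is flattened to a 3N vector over the shared atom selection
(after optional rigid pre-alignment to the first model, so rigid-body
motion does not masquerade as an internal mode).  The PC scores place
every model on a low-dimensional map; displacement structures along a
component visualize what that component moves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import ConsensusSet, Structure
from .superpose import kabsch_superpose

__all__ = ["PCAResult", "pca_ensemble", "pc_displacement"]


@dataclass
class PCAResult:
    mean_vector: np.ndarray  # (3N,)
    eigenvalues: np.ndarray  # descending, >= 0
    components: np.ndarray  # (n_components, 3N), orthonormal rows
    scores: np.ndarray  # (m, n_components)
    labels: list[str]
    keys: list  # atom keys defining the 3N layout
    template: Structure  # carries atom identities for displacement output

    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    def scores_frame(self):
        import pandas as pd

        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.labels, columns=cols)


def pca_ensemble(
    models: Sequence[Structure],
    selection: ConsensusSet,
    prealign: bool = True,
) -> PCAResult:
    """PCA of an ensemble over a shared selection.

    With m models there are at most m-1 nonzero eigenvalues; the SVD of the
    centered (m x 3N) data matrix is used, which has the same nonzero
    spectrum as the 3N x 3N covariance.  Eigenvalues use the 1/(m-1)
    normalization, so their sum equals the total centered variance.
    """
    m = len(models)
    if m < 3:
        raise ValueError("need at least three models for a meaningful PCA")
    keys = list(selection.keys)
    rows = []
    for i, s in enumerate(models):
        x = s.coords(keys)
        if prealign and i > 0:
            sup = kabsch_superpose(s, models[0], selection)
            x = sup.apply(x)
        rows.append(x.reshape(-1))
    data = np.array(rows)  # (m, 3N)
    mean = data.mean(axis=0)
    centered = data - mean

    u, svals, vt = np.linalg.svd(centered, full_matrices=False)
    n_comp = min(m - 1, vt.shape[0])
    svals = svals[:n_comp]
    vt = vt[:n_comp]
    u = u[:, :n_comp]
    eigenvalues = svals**2 / (m - 1)

    # deterministic sign: largest-magnitude element of each component positive
    for i in range(n_comp):
        peak = np.argmax(np.abs(vt[i]))
        if vt[i, peak] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]

    scores = u * svals  # (m, n_comp); pairwise distances match 3N distances
    labels = [s.label or f"model{i}" for i, s in enumerate(models)]
    template = models[0].subset(keys)
    # order template atoms identically to the key layout
    amap = template.atom_map()
    template.atoms = [amap[k] for k in keys]
    return PCAResult(
        mean_vector=mean,
        eigenvalues=eigenvalues,
        components=vt,
        scores=scores,
        labels=labels,
        keys=keys,
        template=template,
    )


def pc_displacement(result: PCAResult, component_index: int, amplitude: float) -> Structure:
    """Mean structure displaced by ``amplitude`` along one component.

    ``amplitude`` is in score units (Å of collective displacement), so the
    range of observed scores along the component is a natural choice.
    """
    if not 0 <= component_index < len(result.components):
        raise IndexError(
            f"component {component_index} out of range (have {len(result.components)})"
        )
    vec = result.mean_vector + amplitude * result.components[component_index]
    out = result.template.copy(label=f"PC{component_index + 1}_{amplitude:+.2f}")
    coords = vec.reshape(-1, 3)
    for atom, pos in zip(out.atoms, coords):
        atom.position = pos.copy()
    return out
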