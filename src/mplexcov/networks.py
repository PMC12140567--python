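"""Group-level correlation layers and the multiplex supra-adjacency matrix.

A structural-covariance layer is built per group and per modality: the
entry (i, j) is the Pearson correlation of residualized region values i
and j across the subjects of the group. The weighted layer is binarized
at a threshold d — by default d is an edge DENSITY, i.e. the round(d * E)
strongest positive edges are retained out of the E = n(n-1)/2 possible
ones; an absolute-correlation mode (edge iff r > d) is also available.
Negative correlations are discarded before either rule.

The binary layers are then assembled into the supra-adjacency matrix

    W = [[A_layer1, C       ],
         [C,        A_layer2]]

with interlayer coupling C = c * I linking each node only to its own
replica in the other layer (multiplex topology). The default sweep runs
densities 0.40 to 0.70 in steps of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_DENSITIES: tuple[float, ...] = (0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70)

THRESHOLD_MODES = ("density", "absolute")


@dataclass
class LayerMatrix:
    """Weighted group-level correlation matrix for one modality.

    Symmetric, off-diagonal entries in [-1, 1], diagonal fixed at 0
    (self-connections are excluded).
    """

    modality: str
    weights: np.ndarray
    group: str = ""
    n_subjects: int = 0
    regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        off = w[~np.eye(len(w), dtype=bool)]
        if off.size and (np.abs(off) > 1 + 1e-12).any():
            raise ValueError("off-diagonal weights must lie in [-1, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def group_correlation(
    residuals: pd.DataFrame | np.ndarray,
    modality: str,
    group: str = "",
) -> LayerMatrix:
    """Pearson-correlate all region pairs across subjects of one group.

    Raises
    ------
    ValueError
        If fewer than 3 subjects, or a region has zero variance (named).
    """
    if isinstance(residuals, pd.DataFrame):
        regions = tuple(residuals.columns)
        data = residuals.to_numpy(dtype=float)
    else:
        data = np.asarray(residuals, dtype=float)
        regions = tuple(f"v{j}" for j in range(data.shape[1]))
    n_subjects, _ = data.shape
    if n_subjects < 3:
        raise ValueError(
            f"group correlation needs >= 3 subjects (got {n_subjects})"
        )
    sd = data.std(axis=0)
    if (sd == 0).any():
        bad = [regions[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance region(s): {bad}")
    corr = np.corrcoef(data, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return LayerMatrix(
        modality=modality,
        weights=corr,
        group=group,
        n_subjects=n_subjects,
        regions=regions,
    )


def edge_count(n_regions: int, density: float) -> int:
    """Edges retained at a density: round-half-away-from-zero of d * E."""
    total = n_regions * (n_regions - 1) // 2
    return int(np.floor(density * total + 0.5))


def binarize_weights(
    weights: np.ndarray, d: float, mode: str = "density"
) -> np.ndarray:
    """Binarize a symmetric weight matrix at threshold d.

    density mode: keep exactly ``edge_count(n, d)`` strongest positive
    edges; ties broken by sorting on (-weight, i, j), i < j, which is
    deterministic across platforms. absolute mode: keep edges with
    weight > d. Negative weights are zeroed first in both modes; if fewer
    positive edges exist than the density asks for, only the positive
    ones are kept.
    """
    if not 0.0 < d < 1.0:
        raise ValueError(f"threshold d must lie in (0, 1), got {d}")
    if mode not in THRESHOLD_MODES:
        raise ValueError(f"threshold mode must be one of {THRESHOLD_MODES}")
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju].copy()
    vals[vals < 0] = 0.0
    adj = np.zeros((n, n), dtype=float)
    if mode == "absolute":
        keep = np.flatnonzero(vals > d)
    else:
        m = edge_count(n, d)
        order = np.lexsort((ju, iu, -vals))
        keep = order[:m]
        keep = keep[vals[keep] > 0]
    adj[iu[keep], ju[keep]] = 1.0
    adj += adj.T
    return adj


def threshold_binarize(
    layer: LayerMatrix, d: float, mode: str = "density"
) -> np.ndarray:
    """Binary adjacency of a weighted layer at threshold d (see module doc)."""
    return binarize_weights(layer.weights, d, mode)


@dataclass
class MultiplexNetwork:
    """Binary layers plus replica coupling, assembled into supra-adjacency W.

    ``supra`` is the 2n x 2n (for M = 2) block matrix with the binary
    intralayer adjacencies on the diagonal blocks and the interlayer
    coupling C = coupling_strength * I on every off-diagonal block.
    """

    layers: list[np.ndarray]
    coupling: np.ndarray
    threshold: float
    threshold_mode: str = "density"
    supra: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("a multiplex network needs >= 2 layers")
        n = self.layers[0].shape[0]
        for a in self.layers:
            if a.shape != (n, n):
                raise ValueError("all layers must share the same node count")
            if not np.array_equal(a, a.T):
                raise ValueError("layers must be symmetric")
            if np.any((a != 0) & (a != 1)):
                raise ValueError("layers must be binary")
            if np.any(np.diag(a) != 0):
                raise ValueError("layers must have zero diagonal")
        if self.coupling.shape != (n, n):
            raise ValueError("coupling block must be n x n")
        M = len(self.layers)
        blocks = [
            [
                self.layers[a] if a == b else self.coupling
                for b in range(M)
            ]
            for a in range(M)
        ]
        self.supra = np.block(blocks)

    @property
    def n_nodes(self) -> int:
        return self.layers[0].shape[0]

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def build_supra(
    layers: list[np.ndarray],
    coupling_strength: float = 1.0,
    threshold: float = 0.5,
    threshold_mode: str = "density",
) -> MultiplexNetwork:
    """Assemble binary layers and replica coupling into a MultiplexNetwork."""
    if not layers:
        raise ValueError("no layers given")
    n = layers[0].shape[0]
    coupling = coupling_strength * np.eye(n)
    return MultiplexNetwork(
        layers=[np.asarray(a, dtype=float) for a in layers],
        coupling=coupling,
        threshold=threshold,
        threshold_mode=threshold_mode,
    )


def layer_to_edge_list(layer: LayerMatrix) -> pd.DataFrame:
    """Upper-triangle edge list (region_i, region_j, weight) of a layer."""
    n = layer.n_regions
    iu, ju = np.triu_indices(n, k=1)
    return pd.DataFrame(
        {
            "region_i": [layer.regions[i] for i in iu],
            "region_j": [layer.regions[j] for j in ju],
            "weight": layer.weights[iu, ju],
        }
    )
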