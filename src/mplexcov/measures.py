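"""Multiplex graph measures: intralayer degrees, overlapping degree, MPC.

For a node i with degree k_i^a in layer a (a = 1..M, coupling edges not
counted), the overlapping degree is

    o_i = sum_a k_i^a

and the multiplex participation coefficient is

    p_i = M/(M-1) * (1 - sum_a (k_i^a / o_i)^2),

which is 1 when the degree is spread evenly over the layers and 0 when it
is confined to a single layer. An isolated node (o_i = 0) is assigned
p_i = 0: it participates in no layer, and the 0/0 in the formula is
resolved downward. This convention biases the global MPC (the mean of p_i
over ALL nodes, isolated ones included) downward at sparse densities; it
is kept because it holds the node count constant across thresholds and
groups. Global overlapping degree is likewise the mean of o_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import MultiplexNetwork


def intralayer_degrees(net: MultiplexNetwork) -> np.ndarray:
    """n x M matrix of within-layer degrees k_i^a (coupling excluded)."""
    return np.column_stack([layer.sum(axis=1) for layer in net.layers])


def degrees_to_participation(k: np.ndarray) -> np.ndarray:
    """MPC from an n x M degree matrix; isolated nodes get 0."""
    k = np.asarray(k, dtype=float)
    M = k.shape[1]
    o = k.sum(axis=1)
    p = np.zeros(len(k))
    active = o > 0
    ratios = k[active] / o[active, None]
    p[active] = M / (M - 1) * (1.0 - (ratios**2).sum(axis=1))
    return np.clip(p, 0.0, 1.0)


def overlapping_degree(net: MultiplexNetwork) -> tuple[np.ndarray, float]:
    """Per-node o_i = sum_a k_i^a and its mean over nodes."""
    o = intralayer_degrees(net).sum(axis=1)
    return o, float(o.mean())


def nodal_mpc(net: MultiplexNetwork) -> np.ndarray:
    """Multiplex participation coefficient p_i per node."""
    return degrees_to_participation(intralayer_degrees(net))


def global_mpc(net: MultiplexNetwork) -> float:
    """Mean nodal MPC over all nodes (isolated nodes enter at 0)."""
    return float(nodal_mpc(net).mean())


@dataclass(frozen=True)
class MeasureResult:
    """All multiplex measures of one network at one threshold."""

    threshold: float
    nodal_degree_per_layer: np.ndarray  # n x M
    overlapping_degree: np.ndarray  # n
    nodal_mpc: np.ndarray  # n
    global_mpc: float
    global_overlapping_degree: float
    n_layers: int

    def to_frame(
        self, regions: tuple[str, ...], layer_names: tuple[str, ...]
    ) -> pd.DataFrame:
        """Per-region table: k per layer, o, p."""
        data = {"region": list(regions)}
        for a, name in enumerate(layer_names):
            data[f"k_{name}"] = self.nodal_degree_per_layer[:, a]
        data["o"] = self.overlapping_degree
        data["p"] = self.nodal_mpc
        return pd.DataFrame(data)


def compute_measures(net: MultiplexNetwork) -> MeasureResult:
    """Degrees, overlapping degree, and nodal/global MPC of a network."""
    k = intralayer_degrees(net)
    o = k.sum(axis=1)
    p = degrees_to_participation(k)
    return MeasureResult(
        threshold=net.threshold,
        nodal_degree_per_layer=k,
        overlapping_degree=o,
        nodal_mpc=p,
        global_mpc=float(p.mean()),
        global_overlapping_degree=float(o.mean()),
        n_layers=net.n_layers,
    )
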