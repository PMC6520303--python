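"""Weighted graph metrics on full (unthresholded) connectivity matrices.

The network keeps every edge weight — no arbitrary threshold — and three
characteristics are computed:

* ``Cw`` — average weighted clustering coefficient (Onnela's form): weights
  are scaled by the network maximum, a node's triangle intensity is
  t_i = ½ Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}, and
  C_i = 2 t_i / (k_i (k_i − 1)) with k_i the node degree (count of
  nonzero-weight neighbours); Cw is the mean over nodes.
* ``Lw`` — characteristic path length (Watts–Strogatz): shortest-path
  distance with edge length 1/w (the brain-connectivity-toolbox
  convention), averaged over all ordered node pairs.
* ``SWI`` — small-worldness index (Humphries–Gurney):
  (Cw/C_rand) / (Lw/L_rand), with the random reference values taken as the
  means over weight-permuted surrogate networks (upper-triangle weights
  shuffled uniformly, symmetry restored). Normalizing both Cw and Lw this
  way limits the influence of overall connectivity strength.

Input matrices must be nonnegative (PLI); dwPLI matrices can carry negative
weights and are not valid graph input here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GraphMetricsRecord",
    "clustering_coefficient",
    "characteristic_path_length",
    "surrogate_normalize",
    "small_worldness",
    "graph_metrics",
]


def _validate_weight_matrix(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if W.shape[0] < 2:
        raise ValueError("need at least two nodes")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("diagonal must be zero")
    if W.min() < 0:
        raise ValueError(
            "negative weights: graph metrics are defined for nonnegative "
            "(PLI) matrices only — dwPLI matrices are not valid input")
    if not np.all(np.isfinite(W)):
        raise ValueError("non-finite weights")
    return W


def clustering_coefficient(W: np.ndarray) -> float:
    """Average weighted clustering coefficient (Onnela)."""
    W = _validate_weight_matrix(W)
    wmax = W.max()
    if wmax == 0:
        return 0.0
    What = (W / wmax) ** (1.0 / 3.0)
    t = np.diag(What @ What @ What) / 2.0
    k = (W > 0).sum(axis=1)
    C = np.zeros(W.shape[0])
    ok = k >= 2
    C[ok] = 2.0 * t[ok] / (k[ok] * (k[ok] - 1.0))
    return float(C.mean())


def characteristic_path_length(W: np.ndarray) -> float:
    """Characteristic path length with edge length 1/weight."""
    W = _validate_weight_matrix(W)
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    D = shortest_path(lengths, method="D", directed=False, unweighted=False)
    n = W.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.isinf(D[off]).any():
        raise ValueError("graph is disconnected: path length undefined")
    return float(D[off].mean())


def _permute_weights(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    w = rng.permutation(W[iu])
    S = np.zeros_like(W)
    S[iu] = w
    return S + S.T


def surrogate_normalize(W: np.ndarray, n_surrogates: int = 100,
                        seed: int = 0) -> tuple[float, float, float, float]:
    """Normalize Cw and Lw against weight-permuted surrogate networks.

    Returns ``(Cw_nrm, Lw_nrm, C_rand, L_rand)`` where C_rand/L_rand are
    the surrogate-ensemble means and the normalized values are
    observed/random. Both ratios are invariant to uniform weight scaling.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be at least 1")
    W = _validate_weight_matrix(W)
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_surrogates):
        S = _permute_weights(W, rng)
        cs.append(clustering_coefficient(S))
        ls.append(characteristic_path_length(S))
    C_rand = float(np.mean(cs))
    L_rand = float(np.mean(ls))
    if C_rand == 0 or L_rand == 0:
        raise ValueError("degenerate surrogate ensemble (zero mean metric)")
    return (clustering_coefficient(W) / C_rand,
            characteristic_path_length(W) / L_rand, C_rand, L_rand)


def small_worldness(Cw_nrm: float, Lw_nrm: float) -> float:
    """Small-worldness index: normalized clustering over normalized path length."""
    if Lw_nrm == 0:
        raise ValueError("normalized path length is zero")
    return float(Cw_nrm / Lw_nrm)


@dataclass
class GraphMetricsRecord:
    """Graph characteristics of one connectivity matrix."""

    subject_id: str
    session_id: int
    band_name: str
    Cw: float
    Lw: float
    Cw_nrm: float
    Lw_nrm: float
    SWI: float
    n_surrogates: int
    surrogate_seed: int


def graph_metrics(matrix, n_surrogates: int = 100,
                  seed: int = 0) -> GraphMetricsRecord:
    """All graph characteristics of one :class:`ConnectivityMatrix`.

    The same surrogate ensemble normalizes Cw and Lw and enters the SWI.
    """
    if getattr(matrix, "method", "pli") == "dwpli":
        raise ValueError(
            "dwPLI matrices may contain negative weights and are excluded "
            "from graph analysis; use the PLI matrix")
    W = matrix.values
    Cw = clustering_coefficient(W)
    Lw = characteristic_path_length(W)
    Cn, Ln, _, _ = surrogate_normalize(W, n_surrogates=n_surrogates, seed=seed)
    return GraphMetricsRecord(
        subject_id=matrix.subject_id, session_id=matrix.session_id,
        band_name=matrix.band_name, Cw=Cw, Lw=Lw, Cw_nrm=Cn, Lw_nrm=Ln,
        SWI=small_worldness(Cn, Ln), n_surrogates=n_surrogates,
        surrogate_seed=seed)
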