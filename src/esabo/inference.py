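"""All-pairs ESABO scoring and signed network extraction.

Given a binarized samples x taxa table, every unordered taxon pair receives
a symmetrized ESABO z-score (the permutation null shuffles only the second
vector, so both orders are computed and averaged).  Thresholding the score
matrix yields a signed interaction network: pairs at or above the positive
threshold become synergistic (mutualistic) edges, pairs at or below the
negative threshold competitive ones.  Taxa that are present in every sample
or absent from every sample have a degenerate permutation null and are
reported as unscorable rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .core import esabo_score

logger = logging.getLogger(__name__)

__all__ = [
    "InferredNetwork",
    "NetworkSummary",
    "score_all_pairs",
    "extract_signed_network",
    "summarize_network",
]


@dataclass(frozen=True)
class InferredNetwork:
    """Signed, scored edge list extracted from an all-pairs score matrix."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, int, float], ...]  # (taxon_a, taxon_b, sign, score)
    pos_threshold: float
    neg_threshold: float
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def positive_edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, s) for a, b, sign, s in self.edges if sign == 1]

    @property
    def negative_edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, s) for a, b, sign, s in self.edges if sign == -1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.edges), columns=["taxon_a", "taxon_b", "sign", "score"]
        )


@dataclass(frozen=True)
class NetworkSummary:
    """Per-node signed degrees and per-sign connected components."""

    degrees: pd.DataFrame  # index taxon, columns k_pos / k_neg
    positive_components: tuple[frozenset[str], ...]
    negative_components: tuple[frozenset[str], ...]


def score_all_pairs(
    table: pd.DataFrame,
    op: str = "AND",
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Symmetrized ESABO z-score for every unordered taxon pair.

    Returns a square taxa x taxa DataFrame; each off-diagonal entry is the
    mean of the two ordered z-scores (shuffling either vector).  The
    diagonal and any pair involving a constant (always present / always
    absent) taxon are NaN.  Raises if fewer than two columns vary.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 taxa")
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    values = table.to_numpy(dtype=np.int8)
    taxa = list(table.columns)
    variable = [(values[:, k].min() != values[:, k].max()) for k in range(len(taxa))]
    if sum(variable) < 2:
        raise ValueError(
            "fewer than 2 non-constant taxa; nothing can be scored "
            "(constant columns have a degenerate permutation null)"
        )
    for k, ok in enumerate(variable):
        if not ok:
            logger.warning("taxon %r is constant across samples; unscorable", taxa[k])
    rng = np.random.default_rng(seed)
    scores = np.full((len(taxa), len(taxa)), np.nan)
    max_asym = 0.0
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if not (variable[i] and variable[j]):
                continue
            r_ij = esabo_score(values[:, i], values[:, j], op, n_shuffles, rng)
            r_ji = esabo_score(values[:, j], values[:, i], op, n_shuffles, rng)
            if r_ij.is_defined and r_ji.is_defined:
                scores[i, j] = scores[j, i] = 0.5 * (r_ij.z_score + r_ji.z_score)
                max_asym = max(max_asym, abs(r_ij.z_score - r_ji.z_score))
    logger.info("largest order asymmetry of z before symmetrization: %.3f", max_asym)
    return pd.DataFrame(scores, index=taxa, columns=taxa)


def extract_signed_network(
    scores: pd.DataFrame,
    pos_threshold: float = 1.0,
    neg_threshold: float = -1.0,
    provenance: dict[str, Any] | None = None,
) -> InferredNetwork:
    """Threshold a symmetric score matrix into a signed edge list.

    Scores >= ``pos_threshold`` become +1 edges, scores <= ``neg_threshold``
    become -1 edges; everything strictly in between, and NaN (unscorable)
    entries, yield no edge.
    """
    if pos_threshold <= neg_threshold:
        raise ValueError("pos_threshold must exceed neg_threshold")
    if list(scores.index) != list(scores.columns):
        raise ValueError("score matrix must have identical row and column labels")
    taxa = list(scores.index)
    values = scores.to_numpy(dtype=float)
    edges: list[tuple[str, str, int, float]] = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            s = values[i, j]
            if np.isnan(s):
                continue
            if s >= pos_threshold:
                edges.append((taxa[i], taxa[j], 1, float(s)))
            elif s <= neg_threshold:
                edges.append((taxa[i], taxa[j], -1, float(s)))
    return InferredNetwork(
        nodes=tuple(taxa),
        edges=tuple(edges),
        pos_threshold=pos_threshold,
        neg_threshold=neg_threshold,
        provenance=dict(provenance or {}),
    )


def summarize_network(net: InferredNetwork) -> NetworkSummary:
    """Signed degree table and connected components of each sign subnetwork."""
    k_pos = {t: 0 for t in net.nodes}
    k_neg = {t: 0 for t in net.nodes}
    g_pos = nx.Graph()
    g_neg = nx.Graph()
    for a, b, sign, _score in net.edges:
        if sign == 1:
            k_pos[a] += 1
            k_pos[b] += 1
            g_pos.add_edge(a, b)
        else:
            k_neg[a] += 1
            k_neg[b] += 1
            g_neg.add_edge(a, b)
    degrees = pd.DataFrame(
        {"k_pos": pd.Series(k_pos), "k_neg": pd.Series(k_neg)}
    ).loc[list(net.nodes)]
    pos_comp = tuple(frozenset(c) for c in nx.connected_components(g_pos))
    neg_comp = tuple(frozenset(c) for c in nx.connected_components(g_neg))
    return NetworkSummary(degrees, pos_comp, neg_comp)
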