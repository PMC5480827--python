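"""Reading and writing abundance tables, networks and synthetic fixtures.

Canonical on-disk dialect is TSV (tab-delimited, UTF-8, '.' decimal) with a
header row and row labels; comma-separated files are accepted on read.
Networks travel as three-column edge lists (node_a, node_b, sign) with an
optional GraphML export for graph tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .simulator import (
    InteractionNetwork,
    add_binary_noise,
    generate_random_signed_network,
    sample_attractor_table,
)

__all__ = [
    "read_abundance_table",
    "write_table",
    "read_network",
    "write_network",
    "write_graphml",
    "write_score_matrix",
    "write_metadata",
    "generate_fixture",
]


def read_abundance_table(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    """Read a samples x taxa abundance table from TSV or CSV.

    The first row must be a header and the first column row labels; the body
    must be numeric and non-negative.  With ``transpose=True`` the file is
    taken as taxa x samples and flipped so rows are always samples.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate column labels")
    table = pd.read_csv(path, sep=sep, index_col=0)
    if table.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row labels")
    try:
        table = table.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric entries in table body: {exc}") from exc
    if table.isna().any().any():
        raise ValueError(f"{path}: missing or unparseable entries (ragged rows?)")
    if (table.to_numpy() < 0).any():
        bad = table.lt(0)
        row = bad.any(axis=1).idxmax()
        colname = bad.loc[row].idxmax()
        raise ValueError(f"{path}: negative abundance at row {row!r}, column {colname!r}")
    if transpose:
        table = table.T
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled table as TSV."""
    table.to_csv(path, sep="\t")


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    """Write a signed edge list as three-column TSV (node_a, node_b, sign)."""
    frame = pd.DataFrame(network.edges(), columns=["node_a", "node_b", "sign"])
    frame.to_csv(path, sep="\t", index=False)


def read_network(path: str | Path, labels: list[str] | None = None) -> InteractionNetwork:
    """Read a signed edge-list TSV back into a network.

    Node labels default to the sorted set of labels appearing in the file;
    pass ``labels`` explicitly to include isolated nodes or fix ordering.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    required = {"node_a", "node_b", "sign"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
    if labels is None:
        labels = sorted(set(frame["node_a"]) | set(frame["node_b"]))
    positive = [
        (r.node_a, r.node_b) for r in frame.itertuples() if int(r.sign) == 1
    ]
    negative = [
        (r.node_a, r.node_b) for r in frame.itertuples() if int(r.sign) == -1
    ]
    if len(positive) + len(negative) != len(frame):
        raise ValueError(f"{path}: signs must be +1 or -1")
    return InteractionNetwork.from_edges(labels, positive, negative)


def write_graphml(network: InteractionNetwork, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(network.labels)
    for a, b, sign in network.edges():
        g.add_edge(a, b, sign=sign)
    nx.write_graphml(g, path)


def write_score_matrix(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a square taxon x taxon score matrix as TSV (NaN = unscorable)."""
    scores.to_csv(path, sep="\t")


def write_metadata(path: str | Path, parameters: dict[str, Any]) -> None:
    """Record the full parameterization of a run in a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(parameters, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _pseudo_counts(
    binary: pd.DataFrame,
    rng: np.random.Generator,
    magnitude_range: tuple[float, float] = (1.0, 1000.0),
) -> pd.DataFrame:
    """Map presence/absence to pseudo-counts with a heavy-tailed hierarchy.

    Each taxon gets a characteristic magnitude drawn log-uniformly from
    ``magnitude_range`` (a few taxa high-abundance, most low-abundance, as
    in relative-abundance census data); present entries scatter log-normally
    around it and are clipped to a minimum count of 1 so that binarization
    at threshold 1 recovers the binary matrix exactly.
    """
    lo, hi = magnitude_range
    n_samples, n_taxa = binary.shape
    magnitudes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_taxa))
    jitter = np.exp(rng.normal(0.0, 0.5, size=(n_samples, n_taxa)))
    counts = np.round(magnitudes * jitter).clip(min=1)
    counts = counts * binary.to_numpy()
    return pd.DataFrame(
        counts.astype(int), index=binary.index, columns=binary.columns
    )


def generate_fixture(
    n_samples: int,
    n_taxa: int,
    m_pos: int,
    m_neg: int,
    noise_level: float = 0.0,
    abundance_mapping: str = "binary",
    seed: int | np.random.Generator | None = None,
    n_initial: int | None = None,
) -> tuple[pd.DataFrame, InteractionNetwork]:
    """Synthetic abundance table with known ground-truth interactions.

    A random connected signed network is simulated to its attractors; the
    table takes up to ``n_samples`` distinct attractor rows, falling back to
    basin-weighted sampling when the repertoire is smaller than requested.
    Binary noise is applied after sampling.  ``abundance_mapping='binary'``
    emits the 0/1 matrix itself; ``'pseudo_counts'`` maps presences to
    heavy-tailed integer counts (zero entries exactly where the binary
    matrix is 0, so binarization at threshold 1 round-trips).

    Returns ``(table, network)``; ship both, the network is the evaluation
    ground truth.
    """
    if abundance_mapping not in ("binary", "pseudo_counts"):
        raise ValueError("abundance_mapping must be 'binary' or 'pseudo_counts'")
    rng = np.random.default_rng(seed)
    network = generate_random_signed_network(n_taxa, m_pos, m_neg, rng)
    if n_initial is None:
        n_initial = max(1000, 4 * n_samples)
    table = sample_attractor_table(network, n_initial, rng, weighting="distinct")
    if table.shape[0] >= n_samples:
        keep = rng.choice(table.shape[0], size=n_samples, replace=False)
        table = table.iloc[np.sort(keep)]
    else:
        table = sample_attractor_table(
            network, n_samples, rng, weighting="basin_weighted"
        )
    if noise_level > 0:
        table = add_binary_noise(table, noise_level, rng)
    if abundance_mapping == "pseudo_counts":
        table = _pseudo_counts(table, rng)
    table.index = [f"sample_{k + 1:04d}" for k in range(table.shape[0])]
    return table, network
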