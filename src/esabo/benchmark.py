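"""Calibration study: edge-sign recovery on simulated communities.

Ensembles of random signed networks are simulated to their attractor tables
and every true edge (plus, optionally, a sample of absent pairs) is scored
with the symmetrized ESABO z and the binary Jaccard indices.  Prediction
quality condenses a score population into a single number in [-1, 1]: the
normalized excess of correctly over incorrectly classified links of one
sign class.  Sweeps over connectivity and noise, and the estimate of how
often a true synergistic edge is pushed to a strongly negative z-score by
network context ("outliers"), are built on the same ensemble machinery.
"""

from __future__ import annotations

import logging
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import esabo_score, jaccard_scores
from .simulator import (
    add_binary_noise,
    generate_random_signed_network,
    sample_attractor_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "prediction_quality_z",
    "prediction_quality_jaccard",
    "score_network_edges",
    "run_ensemble",
    "sweep",
    "estimate_outlier_fraction",
]


def prediction_quality_z(z_values: Sequence[float], link_class: str) -> float:
    """Normalized excess of correctly over incorrectly classified links.

    For the positive (synergistic) class: (#{z > 1} - #{z < -1}) / n; for
    the negative (competitive) class the two counts swap roles.  Scores in
    [-1, 1] contribute nothing either way.  NaN inputs must be filtered
    upstream.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("empty z-score list")
    if np.isnan(z).any():
        raise ValueError("undefined (NaN) z-scores must be excluded upstream")
    hits = int(np.sum(z > 1))
    misses = int(np.sum(z < -1))
    if link_class == "positive":
        return (hits - misses) / z.size
    if link_class == "negative":
        return (misses - hits) / z.size
    raise ValueError("link_class must be 'positive' or 'negative'")


def prediction_quality_jaccard(j_values: Sequence[float], link_class: str) -> float:
    """Threshold-rule prediction quality for the binary Jaccard indices.

    A link counts +1 when its index exceeds 0.6, -1 when it falls in
    (0.4, 0.6], and -1 below -0.4 (vacuous for a non-negative index; kept
    for fidelity to the rule as stated); the sum is normalized by the number
    of links.  The positive class is scored on j11, the negative class on
    j00 — that selection happens in the caller.
    """
    if link_class not in ("positive", "negative"):
        raise ValueError("link_class must be 'positive' or 'negative'")
    j = np.asarray(j_values, dtype=float)
    if j.size == 0:
        raise ValueError("empty Jaccard list")
    if np.isnan(j).any():
        raise ValueError("undefined (NaN) indices must be excluded upstream")
    score = np.sum(j > 0.6) - np.sum((j > 0.4) & (j <= 0.6)) - np.sum(j < -0.4)
    return float(score) / j.size


def score_network_edges(
    network,
    table: pd.DataFrame,
    rng: np.random.Generator,
    n_shuffles: int = 200,
    include_absent: bool = False,
) -> pd.DataFrame:
    """Score every true edge (and optionally sampled absent pairs) of one network.

    Returns one row per scored pair with the symmetrized ESABO z (mean over
    both shuffle orders) and the two Jaccard indices.  ``true_sign`` is +1,
    -1, or 0 for absent pairs.
    """
    values = table.to_numpy(dtype=np.int8)
    col = {lab: k for k, lab in enumerate(table.columns)}
    pairs: list[tuple[str, str, int]] = [
        (a, b, sign) for a, b, sign in network.edges()
    ]
    if include_absent:
        absent = network.non_edges()
        n_pick = min(len(absent), max(network.n_positive, network.n_negative))
        idx = rng.choice(len(absent), size=n_pick, replace=False)
        pairs += [(*absent[k], 0) for k in idx]
    rows = []
    for a, b, sign in pairs:
        b_a = values[:, col[a]]
        b_b = values[:, col[b]]
        if b_a.min() == b_a.max() or b_b.min() == b_b.max():
            z = float("nan")
        else:
            r_ab = esabo_score(b_a, b_b, "AND", n_shuffles, rng)
            r_ba = esabo_score(b_b, b_a, "AND", n_shuffles, rng)
            z = (
                0.5 * (r_ab.z_score + r_ba.z_score)
                if r_ab.is_defined and r_ba.is_defined
                else float("nan")
            )
        j11, j00 = jaccard_scores(b_a, b_b)
        rows.append((a, b, sign, z, j11, j00))
    return pd.DataFrame(
        rows, columns=["node_a", "node_b", "true_sign", "z", "j11", "j00"]
    )


def run_ensemble(
    n_networks: int,
    n_nodes: int = 15,
    m_pos: int = 15,
    m_neg: int = 15,
    n_initial: int = 1000,
    n_shuffles: int = 200,
    noise_level: float = 0.0,
    seed: int | np.random.Generator | None = None,
    include_absent: bool = False,
    weighting: str = "distinct",
    min_attractors: int = 100,
    max_network_tries: int = 500,
) -> pd.DataFrame:
    """Edge scores pooled over an ensemble of random connected networks.

    Each ensemble member is a connected random signed network whose sampled
    attractor repertoire must exceed ``min_attractors`` distinct steady
    states (networks below the bar are regenerated, up to
    ``max_network_tries`` attempts, and the rejection is logged).  Its
    attractor table (``distinct`` or ``basin_weighted``) is optionally
    corrupted with binary noise before scoring.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for net_id in range(n_networks):
        for attempt in range(max_network_tries):
            network = generate_random_signed_network(n_nodes, m_pos, m_neg, rng)
            table = sample_attractor_table(network, n_initial, rng, weighting="distinct")
            n_distinct = table.shape[0]
            if n_distinct > min_attractors:
                break
            logger.debug(
                "network %d attempt %d rejected: %d distinct attractors <= %d",
                net_id, attempt, n_distinct, min_attractors,
            )
        else:
            raise RuntimeError(
                f"no network with more than {min_attractors} distinct attractors "
                f"found in {max_network_tries} tries "
                f"(n_nodes={n_nodes}, m_pos={m_pos}, m_neg={m_neg})"
            )
        if weighting == "basin_weighted":
            table = sample_attractor_table(network, n_initial, rng, weighting="basin_weighted")
        elif weighting != "distinct":
            raise ValueError("weighting must be 'distinct' or 'basin_weighted'")
        if noise_level > 0:
            table = add_binary_noise(table, noise_level, rng)
        scores = score_network_edges(
            network, table, rng, n_shuffles=n_shuffles, include_absent=include_absent
        )
        scores.insert(0, "network_id", net_id)
        scores["n_attractors"] = n_distinct
        frames.append(scores)
    return pd.concat(frames, ignore_index=True)


def _qualities(edge_scores: pd.DataFrame) -> list[dict[str, Any]]:
    """Prediction quality per (class, method) from pooled edge scores."""
    out = []
    for link_class, sign, j_col in (("positive", 1, "j11"), ("negative", -1, "j00")):
        sub = edge_scores[edge_scores["true_sign"] == sign]
        z = sub["z"].to_numpy()
        j = sub[j_col].to_numpy()
        n_undef = int(np.isnan(z).sum())
        if n_undef:
            logger.info("%d undefined z-scores excluded (%s class)", n_undef, link_class)
        record = {
            "link_class": link_class,
            "n_edges": len(sub),
            "n_undefined_z": n_undef,
        }
        z_ok = z[~np.isnan(z)]
        j_ok = j[~np.isnan(j)]
        record_z = dict(record, method="esabo_z")
        record_z["quality"] = (
            prediction_quality_z(z_ok, link_class) if z_ok.size else float("nan")
        )
        record_j = dict(record, method="jaccard")
        record_j["quality"] = (
            prediction_quality_jaccard(j_ok, link_class) if j_ok.size else float("nan")
        )
        out.extend([record_z, record_j])
    return out


def sweep(
    parameter: str,
    values: Sequence[float],
    base_config: dict[str, Any] | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Prediction-quality sweep over connectivity or noise.

    ``connectivity`` varies M+ = M- over ``values``; ``noise`` varies the
    binary noise level at fixed connectivity (default M+ = M- = 10).  Each
    condition is averaged over an ensemble (default 20 networks of 15
    nodes).  Returns a tidy frame with one row per condition x class x
    method.
    """
    if parameter not in ("connectivity", "noise"):
        raise ValueError("parameter must be 'connectivity' or 'noise'")
    config: dict[str, Any] = {
        "n_networks": 20,
        "n_nodes": 15,
        "m_pos": 10,
        "m_neg": 10,
        "n_initial": 1000,
        "n_shuffles": 200,
        "noise_level": 0.0,
    }
    config.update(base_config or {})
    rng = np.random.default_rng(seed)
    rows = []
    for value in values:
        cfg = dict(config)
        if parameter == "connectivity":
            m = int(value)
            if m < cfg["n_nodes"] - 1:
                raise ValueError(
                    f"M+ = M- = {m} cannot connect {cfg['n_nodes']} nodes"
                )
            cfg["m_pos"] = cfg["m_neg"] = m
        else:
            cfg["noise_level"] = float(value)
        edge_scores = run_ensemble(seed=rng, **cfg)
        for record in _qualities(edge_scores):
            record.update(
                parameter=parameter,
                value=value,
                n_networks=cfg["n_networks"],
                n_nodes=cfg["n_nodes"],
                m_pos=cfg["m_pos"],
                m_neg=cfg["m_neg"],
                noise_level=cfg["noise_level"],
            )
            rows.append(record)
    columns = [
        "parameter", "value", "link_class", "method", "quality",
        "n_edges", "n_undefined_z", "n_networks", "n_nodes",
        "m_pos", "m_neg", "noise_level",
    ]
    return pd.DataFrame(rows)[columns]


def estimate_outlier_fraction(
    n_networks: int = 40,
    n_nodes: int = 15,
    m: int = 15,
    runs_per_network: int = 500,
    n_shuffles: int = 200,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Fraction of true synergistic edges with a strongly negative score.

    Pools every positive edge of an ensemble of random connected networks
    (each sampled from ``runs_per_network`` initial conditions) and returns
    the fraction whose ESABO z-score is <= -1 — synergistic links that
    network frustration pushes to the competitive side.
    """
    edge_scores = run_ensemble(
        n_networks=n_networks,
        n_nodes=n_nodes,
        m_pos=m,
        m_neg=m,
        n_initial=runs_per_network,
        n_shuffles=n_shuffles,
        seed=seed,
        include_absent=False,
    )
    z = edge_scores.loc[edge_scores["true_sign"] == 1, "z"].to_numpy()
    z = z[~np.isnan(z)]
    if z.size == 0:
        raise RuntimeError("no defined z-scores for positive edges")
    return float(np.mean(z <= -1))
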