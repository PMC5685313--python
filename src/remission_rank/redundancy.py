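"""Patient redundancy reduction.

Phenotypically similar patients inflate cross-validated performance
because near-duplicates straddle the train/test boundary.  Similarity
is the Gower coefficient over the mixed continuous/dichotomous
covariate vector (the remission label is excluded — using the outcome
in a redundancy filter would leak label structure), and pairs above the
threshold are resolved by a greedy Hobohm-style reduction that removes
the highest-degree node of the similarity graph until no edges remain,
preferring at equal degree to remove the patient with more missing
observations, which leaves a more complete final data set.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .datatypes import CohortTable

#: Covariates excluded from the similarity vector by default: tobacco
#: use is dropped for its missingness, mirroring the modelling set.
DEFAULT_EXCLUDED = ("tobacco_use",)


def gower_pair(x, y, variable_types, numeric_ranges) -> float:
    """Gower similarity of two mixed-type vectors.

    s = sum_k w_k s_k / sum_k w_k with s_k = 1 - |x_k - y_k| / range_k
    for continuous variables and the symmetric 0/1 match indicator for
    dichotomous ones; w_k = 0 when either value is missing or the
    variable's range is 0.
    """
    num, den = 0.0, 0.0
    for k, (xv, yv) in enumerate(zip(x, y)):
        if np.isnan(xv) or np.isnan(yv):
            continue
        if variable_types[k] == "continuous":
            rng = numeric_ranges[k]
            if rng == 0:
                continue
            num += 1.0 - abs(xv - yv) / rng
        else:
            num += 1.0 if xv == yv else 0.0
        den += 1.0
    if den == 0:
        raise ValueError("incomparable pair: no jointly observed variables")
    return num / den


def _gower_matrix(values: np.ndarray, kinds, ranges) -> np.ndarray:
    """All-pairs Gower similarity, vectorized per variable."""
    n, p = values.shape
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for k in range(p):
        col = values[:, k]
        ok = ~np.isnan(col)
        w = np.outer(ok, ok).astype(float)
        filled = np.where(ok, col, 0.0)
        if kinds[k] == "continuous":
            if ranges[k] == 0:
                continue
            s = 1.0 - np.abs(filled[:, None] - filled[None, :]) / ranges[k]
        else:
            s = (filled[:, None] == filled[None, :]).astype(float)
        num += w * s
        den += w
    with np.errstate(invalid="ignore"):
        sim = num / den
    return sim


def build_similarity_graph(cohort: CohortTable, threshold: float = 0.925,
                           exclude=DEFAULT_EXCLUDED) -> nx.Graph:
    """Graph over sample ids with an edge for every pair whose Gower
    similarity is strictly above the threshold.

    Numeric ranges are computed once over the full cohort on raw
    (untransformed) values, ignoring missing entries.  Each node
    carries its covariate missing-value count as attribute
    ``n_missing``.
    """
    cols = [c for c in cohort.covariates if c not in set(exclude)]
    kinds = [cohort.covariate_kind(c) for c in cols]
    values = cohort.data[cols].to_numpy(dtype=float)
    ranges = []
    for k, c in enumerate(cols):
        col = values[:, k]
        obs = col[~np.isnan(col)]
        ranges.append(float(obs.max() - obs.min()) if len(obs) else 0.0)

    if np.isnan(values).all(axis=1).any():
        raise ValueError("a patient has no observed similarity variables")
    sim = _gower_matrix(values, kinds, ranges)
    if np.isnan(sim).any():
        raise ValueError("incomparable pair: no jointly observed variables")

    ids = cohort.sample_ids
    g = nx.Graph()
    miss_counts = np.isnan(values).sum(axis=1)
    for i, sid in enumerate(ids):
        g.add_node(sid, n_missing=int(miss_counts[i]))
    ii, jj = np.where(np.triu(sim > threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(ids[i], ids[j])
    return g


def hobohm2_reduce(graph: nx.Graph,
                   tiebreak=("degree", "missing", "id"),
                   return_trace: bool = False):
    """Greedy reduction of the similarity graph to an independent set.

    Repeatedly removes the node with the highest current degree until
    the graph is edgeless; ties on degree are broken by removing the
    node with more missing observations first, then by sample id for
    determinism.  Returns the surviving sample ids in input order, or
    (survivors, removal trace of (sample_id, degree at removal)) when
    ``return_trace`` is set.
    """
    g = graph.copy()
    keys = {
        "degree": lambda n: g.degree(n),
        "missing": lambda n: g.nodes[n].get("n_missing", 0),
        "id": lambda n: str(n),
    }
    if tuple(tiebreak)[0] != "degree" or set(tiebreak) != set(keys):
        raise ValueError("tiebreak must be a permutation starting with 'degree'")
    order = list(tiebreak)
    trace = []
    while g.number_of_edges() > 0:
        busy = [n for n, d in g.degree if d > 0]
        victim = max(busy, key=lambda n: tuple(keys[o](n) for o in order))
        trace.append((victim, g.degree(victim)))
        g.remove_node(victim)
    survivors = set(g.nodes)
    kept = [n for n in graph.nodes if n in survivors]
    return (kept, trace) if return_trace else kept


def reduce_cohort(cohort: CohortTable, threshold: float = 0.925,
                  exclude=DEFAULT_EXCLUDED,
                  tiebreak=("degree", "missing", "id")):
    """Similarity graph + Hobohm reduction in one call.

    Returns (reduced CohortTable, kept ids, removal trace of
    (sample_id, degree at removal)).
    """
    graph = build_similarity_graph(cohort, threshold=threshold,
                                   exclude=exclude)
    kept, trace = hobohm2_reduce(graph, tiebreak=tiebreak, return_trace=True)
    return cohort.subset(kept), kept, trace
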