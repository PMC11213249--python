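"""Context-specific regulatory subnetworks and functional-term enrichment.

A directed TF->target network is filtered to a biological context: an edge
survives only when both endpoints are expressed above thresholds in the
selected cell types (single-cell evidence) and time/age samples (bulk
evidence).  The filtered network is summarized as a functional-term graph:
for each ordered term pair (A, B) the number of gene edges running from an
A-annotated source to a B-annotated target is compared with the expectation
under independent term assignment, via an exact binomial upper tail.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionContext",
    "filter_network",
    "pafway_term_network",
    "threshold_scan",
    "compare_condition_networks",
]


@dataclass
class ExpressionContext:
    """Expression evidence defining a biological context.

    A gene passes iff its single-cell expression exceeds ``sc_threshold``
    (strict >) in at least one selected cell type AND its bulk expression
    exceeds ``bulk_threshold`` in at least one selected sample.  Setting
    ``quantifier="all"`` requires every selected column instead.  Genes
    absent from a table fail that table's test (conservative).
    """

    sc_expression: pd.DataFrame      # genes x cell types
    bulk_expression: pd.DataFrame    # genes x samples
    cell_types: list = field(default_factory=list)
    samples: list = field(default_factory=list)
    sc_threshold: float = 0.0
    bulk_threshold: float = 0.0
    quantifier: str = "any"

    def __post_init__(self):
        if not self.cell_types:
            raise ValueError("empty cell-type selection")
        if not self.samples:
            raise ValueError("empty sample selection")
        if not (np.isfinite(self.sc_threshold) and np.isfinite(self.bulk_threshold)):
            # -inf is allowed (pass-everything); NaN is not
            if np.isnan(self.sc_threshold) or np.isnan(self.bulk_threshold):
                raise ValueError("thresholds must not be NaN")
        if self.quantifier not in ("any", "all"):
            raise ValueError("quantifier must be 'any' or 'all'")

    def passing_genes(self) -> pd.Index:
        sc = self.sc_expression[list(self.cell_types)]
        bulk = self.bulk_expression[list(self.samples)]
        agg = "max" if self.quantifier == "any" else "min"
        sc_pass = sc.agg(agg, axis=1) > self.sc_threshold
        bulk_pass = bulk.agg(agg, axis=1) > self.bulk_threshold
        passing = sc_pass[sc_pass].index.intersection(bulk_pass[bulk_pass].index)
        return passing


def filter_network(edges: pd.DataFrame, context: ExpressionContext) -> pd.DataFrame:
    """Edges whose source AND target both pass the context's expression test."""
    passing = set(context.passing_genes())
    edge_genes = set(edges["source"]) | set(edges["target"])
    uncovered = edge_genes - set(context.sc_expression.index) - set(
        context.bulk_expression.index
    )
    if uncovered:
        logger.info(
            "%d edge genes absent from expression tables fail the filter",
            len(uncovered),
        )
    keep = edges["source"].isin(passing) & edges["target"].isin(passing)
    return edges.loc[keep].reset_index(drop=True)


def pafway_term_network(
    edges: pd.DataFrame,
    annotations: dict[str, list[str]],
    terms=None,
) -> pd.DataFrame:
    """Functional-term pair enrichment over the network topology.

    For each ordered term pair (A, B): observed = edges from an A-source to a
    B-target; base probability p0 = (fraction of the network's source genes
    carrying A) x (fraction of its target genes carrying B); expected = N * p0
    and p-value = exact binomial upper tail P(X >= observed) at
    Binomial(N, p0).  Term frequencies are computed over the genes present in
    the (filtered) network, conditioned on the role (source vs target) the
    gene plays — regulator pools are much smaller than target pools, so a
    role-blind frequency would misstate the null edge probability.  Terms
    annotating no network gene yield observed 0, p = 1.
    """
    if len(edges) == 0:
        raise ValueError("empty edge list")
    network_genes = pd.Index(sorted(set(edges["source"]) | set(edges["target"])))
    src_genes = pd.Index(sorted(set(edges["source"])))
    tgt_genes = pd.Index(sorted(set(edges["target"])))
    terms = list(terms) if terms is not None else sorted(annotations)
    if not any(set(annotations.get(t, ())) & set(network_genes) for t in terms):
        logger.warning("no annotated gene appears in the network")

    carry = {
        t: network_genes.isin(set(annotations.get(t, ()))) for t in terms
    }
    freq_src = {
        t: src_genes.isin(set(annotations.get(t, ()))).mean() if len(src_genes) else 0.0
        for t in terms
    }
    freq_tgt = {
        t: tgt_genes.isin(set(annotations.get(t, ()))).mean() if len(tgt_genes) else 0.0
        for t in terms
    }
    pos = {g: i for i, g in enumerate(network_genes)}
    src_idx = edges["source"].map(pos).to_numpy()
    tgt_idx = edges["target"].map(pos).to_numpy()
    N = len(edges)

    rows = []
    for a, b in itertools.product(terms, repeat=2):
        observed = int((carry[a][src_idx] & carry[b][tgt_idx]).sum())
        p0 = freq_src[a] * freq_tgt[b]
        expected = N * p0
        # binom.sf(k-1) = P(X >= k); observed 0 -> exactly 1
        pval = float(scipy.stats.binom.sf(observed - 1, N, p0)) if p0 > 0 else (
            1.0 if observed == 0 else 0.0
        )
        pval = min(max(pval, np.nextafter(0, 1)), 1.0)
        rows.append(
            {"term_a": a, "term_b": b, "observed": observed,
             "expected": expected, "p_value": pval}
        )
    out = pd.DataFrame(rows)
    out.attrs["n_edges"] = N
    return out


def count_significant(term_network: pd.DataFrame, alpha: float = 0.05) -> int:
    return int((term_network["p_value"] < alpha).sum())


def _slice_flags(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima (strictly greater than both neighbours) and inflection
    points (discrete second difference changes sign) along a 1-D profile."""
    n = len(counts)
    local_max = np.zeros(n, dtype=bool)
    inflection = np.zeros(n, dtype=bool)
    if n >= 3:
        interior = slice(1, n - 1)
        c = counts.astype(float)
        local_max[interior] = (c[1:-1] > c[:-2]) & (c[1:-1] > c[2:])
        d2 = c[2:] - 2 * c[1:-1] + c[:-2]  # second difference at 1..n-2
        for i in range(2, n - 1):
            if d2[i - 1] * d2[i - 2] < 0:
                inflection[i] = True
    return local_max, inflection


def threshold_scan(
    edges: pd.DataFrame,
    context: ExpressionContext,
    sc_grid,
    bulk_grid,
    annotations: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan (sc_threshold, bulk_threshold) grids; per grid point, filter the
    network in the given context and count significant term-pair edges
    (p < alpha).  Flags mark local maxima and inflection points along each
    1-D slice (the other threshold held fixed)."""
    sc_grid, bulk_grid = list(sc_grid), list(bulk_grid)
    if not sc_grid or not bulk_grid:
        raise ValueError("threshold grids must be non-empty")
    counts = np.zeros((len(sc_grid), len(bulk_grid)), dtype=int)
    for i, s in enumerate(sc_grid):
        for j, b in enumerate(bulk_grid):
            ctx = ExpressionContext(
                sc_expression=context.sc_expression,
                bulk_expression=context.bulk_expression,
                cell_types=context.cell_types,
                samples=context.samples,
                sc_threshold=s,
                bulk_threshold=b,
                quantifier=context.quantifier,
            )
            sub = filter_network(edges, ctx)
            if len(sub) == 0 or annotations is None:
                counts[i, j] = 0
            else:
                counts[i, j] = count_significant(
                    pafway_term_network(sub, annotations), alpha
                )

    lm_sc = np.zeros_like(counts, dtype=bool)
    inf_sc = np.zeros_like(counts, dtype=bool)
    lm_bulk = np.zeros_like(counts, dtype=bool)
    inf_bulk = np.zeros_like(counts, dtype=bool)
    for j in range(len(bulk_grid)):
        lm_sc[:, j], inf_sc[:, j] = _slice_flags(counts[:, j])
    for i in range(len(sc_grid)):
        lm_bulk[i, :], inf_bulk[i, :] = _slice_flags(counts[i, :])

    rows = []
    for i, s in enumerate(sc_grid):
        for j, b in enumerate(bulk_grid):
            rows.append(
                {
                    "sc_threshold": s,
                    "bulk_threshold": b,
                    "n_significant": counts[i, j],
                    "local_maximum": bool(lm_sc[i, j] or lm_bulk[i, j]),
                    "inflection_point": bool(inf_sc[i, j] or inf_bulk[i, j]),
                }
            )
    return pd.DataFrame(rows)


def compare_condition_networks(
    term_networks: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Venn partition of significant term edges across named conditions.

    Returns one row per term pair significant anywhere, with a boolean
    membership column per condition plus ``shared_all`` and ``unique_to``.
    """
    if len(term_networks) < 2:
        raise ValueError("need at least 2 condition networks to compare")
    sig_sets = {
        name: set(
            map(tuple, tn.loc[tn["p_value"] < alpha, ["term_a", "term_b"]].to_numpy())
        )
        for name, tn in term_networks.items()
    }
    all_pairs = sorted(set().union(*sig_sets.values()))
    names = list(sig_sets)
    rows = []
    for pair in all_pairs:
        member = {name: pair in sig_sets[name] for name in names}
        holders = [n for n, m in member.items() if m]
        rows.append(
            {
                "term_a": pair[0],
                "term_b": pair[1],
                **member,
                "shared_all": len(holders) == len(names),
                "unique_to": holders[0] if len(holders) == 1 else "",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_a", "term_b", *names, "shared_all", "unique_to"],
    )
    out.attrs["set_sizes"] = {n: len(s) for n, s in sig_sets.items()}
    return out
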