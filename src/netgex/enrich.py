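"""Gene-set over-representation with exact hypergeometric tails and BH-FDR."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._types import GeneSetCollection

__all__ = ["read_gmt", "hypergeom_ora", "bh_fdr"]

log = logging.getLogger(__name__)


def read_gmt(path) -> GeneSetCollection:
    """Parse a standard GMT file (term, description, genes...).

    Gene symbols are case-sensitive; duplicate genes within a term are
    deduplicated (logged); a duplicate term name is an error.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}: needs >= 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in terms:
                raise ValueError(f"{path}: duplicate term name {name!r} at line {lineno}")
            uniq = frozenset(genes)
            if len(uniq) < len(genes):
                log.info("term %s: %d duplicate gene(s) removed", name, len(genes) - len(uniq))
            terms[name] = (desc, uniq)
    return GeneSetCollection(terms=terms)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_ora(
    selected: list[str] | set[str],
    population: list[str] | set[str],
    sets: GeneSetCollection,
    min_term: int = 3,
    max_term_fraction: float = 0.5,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``selected`` in each set.

    Gene sets are intersected with the population first; terms smaller than
    ``min_term`` or larger than ``max_term_fraction`` of the population after
    intersection are skipped. Returns a DataFrame sorted by q then p with
    columns term, N, K, n, k, p, q, overlap.
    """
    population = set(population)
    if not population:
        raise ValueError("population is empty")
    selected = set(selected)
    stray = selected - population
    if stray:
        raise ValueError(f"selected genes outside population: {sorted(stray)[:5]}")
    N, n = len(population), len(selected)
    max_k = max_term_fraction * N
    rows = []
    for name, (desc, genes) in sets:
        term = genes & population
        K = len(term)
        if K < min_term or K > max_k:
            log.info("term %s skipped (size %d after intersection)", name, K)
            continue
        overlap = sorted(term & selected)
        k = len(overlap)
        # upper tail P(X >= k) includes k itself
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        rows.append(
            {"term": name, "description": desc, "N": N, "K": K, "n": n, "k": k,
             "p": p, "overlap": ",".join(overlap)}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["term", "description", "N", "K", "n", "k", "p", "q", "overlap"])
        return df
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values(["q", "p"], kind="stable").reset_index(drop=True)[
        ["term", "description", "N", "K", "n", "k", "p", "q", "overlap"]
    ]
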