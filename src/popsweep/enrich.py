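"""Binomial over-representation test with Benjamini–Hochberg FDR.

For a selected gene set of size ``n`` drawn from a universe of ``M``
annotated genes, a term containing ``m`` genes and hit by ``k`` selected
genes gets the exact binomial tail ``p = P(X ≥ k)`` with
``X ~ Binomial(n, m/M)``.  A hypergeometric alternative (sampling without
replacement) is available for comparison.  Adjusted p-values come from
the Benjamini–Hochberg step-up procedure (statsmodels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class TermMap:
    """Gene→term annotation: term id → gene set, over a background universe."""

    terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.terms.values()) if self.terms else set()
        if not self.universe:
            raise ValueError("empty gene universe")
        for term, genes in self.terms.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(f"term {term!r} has genes outside the universe: {sorted(extra)[:5]}")

    @classmethod
    def from_table(cls, path, universe: set[str] | None = None) -> "TermMap":
        """Read a two-column gene <TAB> term file."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"],
                         dtype=str, comment="#")
        terms: dict[str, set[str]] = {}
        for gene, term in zip(df["gene"], df["term"]):
            terms.setdefault(term, set()).add(gene)
        return cls(terms=terms, universe=universe or set(df["gene"]))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_enrichment(
    selected_genes,
    term_map: TermMap,
    method: str = "binomial",
) -> pd.DataFrame:
    """Per-term over-representation of *selected_genes*.

    Selected genes outside the universe are dropped with a warning.
    Returns a table sorted by p-value with columns term, k (selected in
    term), n (selected total), m (term size), M (universe size), p_value
    and fdr_adjusted_p.
    """
    selected = set(selected_genes)
    outside = selected - term_map.universe
    if outside:
        logger.warning(
            "%d selected genes outside the universe are ignored", len(outside)
        )
        selected &= term_map.universe
    if not selected:
        logger.warning("empty selected gene set: no enrichment computed")
        return pd.DataFrame(
            columns=["term", "k", "n", "m", "M", "p_value", "fdr_adjusted_p"]
        )

    n = len(selected)
    M = len(term_map.universe)
    rows = []
    for term, genes in sorted(term_map.terms.items()):
        m = len(genes)
        k = len(selected & genes)
        if method == "binomial":
            p = float(sps.binom.sf(k - 1, n, m / M))  # P(X ≥ k)
        elif method == "hypergeometric":
            p = float(sps.hypergeom.sf(k - 1, M, m, n))
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((term, k, n, m, M, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "k", "n", "m", "M", "p_value"])
    out["fdr_adjusted_p"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
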