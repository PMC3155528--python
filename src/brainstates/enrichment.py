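"""Enrichment statistics over multi-state genes.

Three tests, all gene-level: (1) one-sided binomial enrichment of up
states per (category, region) cell, with the null success probability
p0 = U / (G * R) — the rate at which a multi-state gene carries an up
state in any one region; (2) Fisher's exact (one-sided hypergeometric)
over-representation of a category among multi-state genes; (3)
hypergeometric term enrichment of a selected gene list with
Benjamini-Hochberg FDR computed within term classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .multistate import MultiStateTable


@dataclass(frozen=True)
class EnrichmentResult:
    unit: str
    observed: int
    background: int
    null_parameter: float
    p_value: float
    adjusted_p: float
    significant: bool


def up_state_probability(table: MultiStateTable | tuple[int, int, int]) -> float:
    """p0 = U / (G * R): up-state assignments over gene-region slots.

    Accepts either a fitted :class:`MultiStateTable` or an explicit
    (U, G, R) triple of printed totals.
    """
    if isinstance(table, tuple):
        U, G, R = table
    else:
        U, G, R = table.U, table.G, table.R
    if G <= 0 or R <= 0:
        raise ValueError("no multi-state genes: p0 undefined")
    p0 = U / (G * R)
    if not 0 < p0 <= 1:
        raise ValueError(f"p0 = {p0} outside (0, 1]")
    return p0


def binomial_tail(x: int, n: int, p: float) -> float:
    """P(X >= x) for X ~ Binomial(n, p), exact."""
    if x <= 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, p))


def region_category_binomial(
    table: MultiStateTable,
    categories: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    p0: float | None = None,
) -> pd.DataFrame:
    """One-sided binomial test per (category, region) cell.

    For a category with n multi-state genes, of which x carry an up state
    in region r, the p-value is P(X >= x), X ~ Binomial(n, p0).
    Bonferroni multiplicity is the number of tested cells
    (categories x regions); cells are significant at adjusted p < alpha.
    Empty categories (no multi-state genes) are skipped.
    """
    if p0 is None:
        p0 = up_state_probability(table)
    multi = table.multi_state_genes
    tested: list[tuple[str, int, dict[str, int]]] = []
    for cat, genes in categories.items():
        members = sorted(set(genes) & multi)
        if not members:
            continue
        per_region = {r: 0 for r in table.region_ids}
        for g in members:
            for r in table.gene_up_regions(g):
                per_region[r] += 1
        tested.append((cat, len(members), per_region))
    m = len(tested) * table.R
    columns = ["category", "region", "observed", "category_size", "p0",
               "p_value", "adjusted_p", "significant", "multiplicity"]
    if not tested:
        return pd.DataFrame(columns=columns)
    rows = []
    for cat, n, per_region in tested:
        for r in table.region_ids:
            x = per_region[r]
            p = binomial_tail(x, n, p0)
            adj = min(1.0, m * p)
            rows.append(
                {
                    "category": cat,
                    "region": r,
                    "observed": x,
                    "category_size": n,
                    "p0": p0,
                    "p_value": p,
                    "adjusted_p": adj,
                    "significant": adj < alpha,
                    "multiplicity": m,
                }
            )
    return pd.DataFrame(rows)


def category_fisher(
    multi_state_genes: Iterable[str],
    category: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """One-sided (enrichment) Fisher exact test for a category.

    2x2 table over the gene universe: category membership x multi-state
    status; the p-value is the hypergeometric upper tail.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    category = set(category) & universe
    multi = set(multi_state_genes) & universe
    x = len(category & multi)
    table = np.array(
        [
            [x, len(category) - x],
            [len(multi) - x, len(universe) - len(category) - len(multi) + x],
        ]
    )
    p = float(stats.fisher_exact(table, alternative="greater").pvalue)
    return EnrichmentResult(
        unit="category",
        observed=x,
        background=len(category),
        null_parameter=len(multi) / len(universe),
        p_value=p,
        adjusted_p=p,
        significant=p < 0.05,
    )


def hypergeom_tail(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeom(N population, K successes, n draws)."""
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def term_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    term_classes: Mapping[str, str] | None = None,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric term enrichment with within-class BH-FDR.

    ``term_classes`` maps each term to its class (e.g. the three GO
    namespaces); FDR is computed separately inside each class.  Terms with
    no universe genes are skipped.  Significant terms have FDR <= threshold.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    rows = []
    for term, genes in term_sets.items():
        members = set(genes) & universe
        if not members:
            continue
        x = len(members & selected)
        p = hypergeom_tail(x, len(universe), len(members), len(selected))
        rows.append(
            {
                "term": term,
                "term_class": (term_classes or {}).get(term, "all"),
                "observed": x,
                "term_size": len(members),
                "selected_size": len(selected),
                "universe_size": len(universe),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["fdr"] = []
        df["significant"] = []
        return df
    df["fdr"] = np.nan
    for _, idx in df.groupby("term_class").groups.items():
        df.loc[idx, "fdr"] = bh_fdr(df.loc[idx, "p_value"])
    df["significant"] = df["fdr"] <= fdr_threshold
    return df.sort_values(["term_class", "p_value"], kind="mergesort").reset_index(
        drop=True
    )
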