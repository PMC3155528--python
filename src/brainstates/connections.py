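"""Ligand-receptor connectivity among regions from up-state co-occurrence.

For each ordered region pair (A, B), the connection count is the number of
neurohormone/neurotransmitter pathways with at least one ligand gene "up"
in A and at least one receptor gene "up" in B (middle and high states both
count as up; diagonal entries are intrinsic, same-region signalling).
Edges are drawn where the count exceeds the 0.05 empirical quantile of all
pair counts AND survives a Bonferroni-corrected one-sided binomial test
with success probability p0^2 — the chance that a random multi-state gene
pair is up in a designated region pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable
import warnings

import numpy as np
import pandas as pd

from .enrichment import binomial_tail
from .multistate import MultiStateTable


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    pathway_class: str
    ligand_genes: frozenset[str]
    receptor_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ligand_genes or not self.receptor_genes:
            raise ValueError(f"{self.pathway_id}: ligand and receptor sets must be non-empty")


@dataclass
class PathwayCatalog:
    pathways: list[Pathway]

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PathwayCatalog":
        """Build from long-format rows: pathway_id, class, role, gene_symbol."""
        required = {"pathway_id", "class", "role", "gene_symbol"}
        if not required.issubset(frame.columns):
            raise ValueError(f"catalog needs columns {sorted(required)}")
        pathways = []
        for pid, grp in frame.groupby("pathway_id", sort=True):
            ligands = frozenset(grp.loc[grp["role"] == "ligand", "gene_symbol"])
            receptors = frozenset(grp.loc[grp["role"] == "receptor", "gene_symbol"])
            pathways.append(
                Pathway(str(pid), str(grp["class"].iloc[0]), ligands, receptors)
            )
        return cls(pathways)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PathwayCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for pw in self.pathways:
            for g in sorted(pw.ligand_genes):
                rows.append((pw.pathway_id, pw.pathway_class, "ligand", g))
            for g in sorted(pw.receptor_genes):
                rows.append((pw.pathway_id, pw.pathway_class, "receptor", g))
        pd.DataFrame(
            rows, columns=["pathway_id", "class", "role", "gene_symbol"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ConnectionMatrix:
    """Ordered region-pair counts; rows = ligand region, cols = receptor."""

    counts: pd.DataFrame  # R x R int
    n_pathways_used: int
    contributing: dict[tuple[str, str], tuple[str, ...]]

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def intrinsic_counts(self) -> pd.Series:
        return pd.Series(np.diag(self.counts.to_numpy()), index=self.counts.index)


def pair_counts(
    table: MultiStateTable,
    catalog: PathwayCatalog,
    known_genes: Iterable[str] | None = None,
) -> ConnectionMatrix:
    """Count pathways connecting each ordered region pair.

    Only pathways with at least one multi-state ligand gene AND one
    multi-state receptor gene contribute.  Catalog genes absent from the
    annotation universe are skipped with a warning.
    """
    regions = list(table.region_ids)
    r_index = {r: i for i, r in enumerate(regions)}
    known = set(known_genes) if known_genes is not None else set(table.genes.index)
    multi = table.multi_state_genes

    def up_vector(genes: frozenset[str]) -> np.ndarray:
        vec = np.zeros(len(regions), bool)
        for g in genes:
            if g not in known:
                warnings.warn(f"catalog gene {g!r} not in annotation; skipped")
                continue
            if g in multi:
                for r in table.gene_up_regions(g):
                    vec[r_index[r]] = True
        return vec

    counts = np.zeros((len(regions), len(regions)), int)
    contributing: dict[tuple[str, str], list[str]] = {}
    used = 0
    for pw in catalog:
        lig_multi = {g for g in pw.ligand_genes if g in multi}
        rec_multi = {g for g in pw.receptor_genes if g in multi}
        if not lig_multi or not rec_multi:
            continue
        used += 1
        lig_up = up_vector(pw.ligand_genes)
        rec_up = up_vector(pw.receptor_genes)
        hit = np.outer(lig_up, rec_up)
        counts += hit
        for i, j in zip(*np.nonzero(hit)):
            contributing.setdefault((regions[i], regions[j]), []).append(
                pw.pathway_id
            )
    frame = pd.DataFrame(counts, index=regions, columns=regions)
    return ConnectionMatrix(
        frame, used, {k: tuple(v) for k, v in contributing.items()}
    )


@dataclass
class ConnectionEdges:
    cutoff: int
    alpha: float
    multiplicity: int
    edges: pd.DataFrame  # source, target, count, p_value, adjusted_p
    all_pairs: pd.DataFrame


def infer_edges(
    matrix: ConnectionMatrix,
    p0: float,
    q: float = 0.05,
    alpha: float = 0.01,
) -> ConnectionEdges:
    """Threshold + test pair counts into directed edges.

    The count cutoff is the upper empirical q-quantile (linear
    interpolation, floored to an integer) of the flattened count matrix —
    only about a fraction q of pairs can exceed it — applied strictly
    (count > cutoff).  Each pair is additionally tested one-sided binomial,
    X ~ Binomial(n_pathways_used, p0^2), Bonferroni-corrected over all
    ordered pairs including the diagonal.
    """
    n = matrix.n_pathways_used
    if n == 0:
        raise ValueError("no usable pathways: cannot infer edges")
    flat = matrix.counts.to_numpy().ravel()
    cutoff = int(np.floor(np.quantile(flat, 1.0 - q)))
    p_pair = p0**2
    m = flat.size
    rows = []
    for src in matrix.region_ids:
        for dst in matrix.region_ids:
            count = int(matrix.counts.at[src, dst])
            p = binomial_tail(count, n, p_pair)
            adj = min(1.0, m * p)
            rows.append(
                {
                    "source": src,
                    "target": dst,
                    "count": count,
                    "intrinsic": src == dst,
                    "p_value": p,
                    "adjusted_p": adj,
                    "edge": count > cutoff and adj < alpha,
                }
            )
    all_pairs = pd.DataFrame(rows)
    edges = all_pairs[all_pairs["edge"]].drop(columns="edge").reset_index(drop=True)
    return ConnectionEdges(cutoff, alpha, m, edges, all_pairs)


def intrinsic_pairs(
    table: MultiStateTable, catalog: PathwayCatalog
) -> pd.DataFrame:
    """Ligand-receptor gene pairs sharing up-state regions, ranked.

    Within each pathway, every (ligand gene, receptor gene) pair whose up
    regions intersect is returned with its matched regions, ranked by the
    number of matched states descending (ties by pathway then gene names).
    """
    multi = table.multi_state_genes
    rows = []
    for pw in catalog:
        for lg in sorted(pw.ligand_genes):
            if lg not in multi:
                continue
            lup = table.gene_up_regions(lg)
            for rg in sorted(pw.receptor_genes):
                if rg not in multi:
                    continue
                matched = lup & table.gene_up_regions(rg)
                if matched:
                    rows.append(
                        {
                            "pathway_id": pw.pathway_id,
                            "ligand_gene": lg,
                            "receptor_gene": rg,
                            "matched_regions": ",".join(sorted(matched)),
                            "n_matched": len(matched),
                        }
                    )
    df = pd.DataFrame(
        rows,
        columns=["pathway_id", "ligand_gene", "receptor_gene",
                 "matched_regions", "n_matched"],
    )
    return df.sort_values(
        ["n_matched", "pathway_id", "ligand_gene", "receptor_gene"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def edges_to_graph(edges: ConnectionEdges):
    """Directed graph of the inferred connections (networkx DiGraph)."""
    import networkx as nx

    g = nx.DiGraph()
    for row in edges.edges.itertuples():
        g.add_edge(row.source, row.target, count=int(row.count),
                   adjusted_p=float(row.adjusted_p))
    return g
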