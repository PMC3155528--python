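"""Expression-matrix data model, file I/O, replicate QC, region clustering.

The pipeline consumes an already-summarized (RMA-style) log2 expression
matrix of probes x samples, where each sample is one replicate of one CNS
region.  This module holds the core containers (:class:`ExpressionMatrix`,
:class:`RegionProfile`), the TSV / GEO-series-matrix readers, replicate
concordance QC, hierarchical clustering of regions, and grouped comparison
against an external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

#: Affymetrix control probe sets are conventionally prefixed "AFFX".
AFFX_CONTROL_PREFIX = "AFFX"

#: Unit-width log2 intensity bins [k, k+1) used for the fold-change /
#: dynamic-range profile; covers the 2^0..2^16 range of the arrays.
INTENSITY_BIN_LOWER_EDGES = tuple(range(16))


class ExpressionLoadError(ValueError):
    """Malformed expression input (bad header, duplicates, metadata mismatch)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleInfo:
    """One array: a single replicate of a single region."""

    sample_id: str
    region_id: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >=1, got {self.replicate}")


@dataclass
class ProbeAnnotation:
    """Per-probe annotation: gene symbol, control flag, category labels.

    ``frame`` is indexed by probe_id with columns ``gene_symbol`` (object,
    may be missing) and ``is_control`` (bool).  ``categories`` maps a
    category label (e.g. a GO-derived class) to the set of gene symbols it
    contains, as read from a GMT file.
    """

    frame: pd.DataFrame
    categories: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frame.index.is_unique:
            dups = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ExpressionLoadError(f"duplicate probe IDs in annotation: {dups[:5]}")
        for col in ("gene_symbol", "is_control"):
            if col not in self.frame.columns:
                raise ExpressionLoadError(f"annotation missing column {col!r}")

    @classmethod
    def from_probe_ids(
        cls,
        probe_ids: Iterable[str],
        gene_symbols: Mapping[str, str] | None = None,
        control_prefix: str = AFFX_CONTROL_PREFIX,
        categories: Mapping[str, frozenset[str]] | None = None,
    ) -> "ProbeAnnotation":
        """Build an annotation, flagging controls by ID prefix (default AFFX)."""
        probe_ids = list(probe_ids)
        gene_symbols = gene_symbols or {}
        frame = pd.DataFrame(
            {
                "gene_symbol": [gene_symbols.get(p) for p in probe_ids],
                "is_control": [p.startswith(control_prefix) for p in probe_ids],
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
        return cls(frame, dict(categories or {}))

    def gene_of(self, probe_id: str) -> str | None:
        sym = self.frame.at[probe_id, "gene_symbol"]
        return None if pd.isna(sym) else str(sym)

    @property
    def control_probes(self) -> pd.Index:
        return self.frame.index[self.frame["is_control"].to_numpy(bool)]

    def gene_map(self) -> pd.Series:
        """probe_id -> gene symbol for annotated, non-control probes."""
        sub = self.frame.loc[~self.frame["is_control"].to_numpy(bool), "gene_symbol"]
        return sub.dropna().astype(str)


@dataclass
class ExpressionMatrix:
    """Log2 expression values (probe x sample) with sample metadata.

    Invariants: all values finite, probe IDs unique, the value columns are
    exactly the metadata sample IDs in order.  Missing values are rejected —
    summarized arrays are complete by construction.
    """

    values: pd.DataFrame
    samples: list[SampleInfo]
    annotation: ProbeAnnotation | None = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ExpressionLoadError("duplicate sample IDs in metadata")
        if list(self.values.columns) != ids:
            missing = sorted(set(self.values.columns) - set(ids))
            if missing:
                raise ExpressionLoadError(
                    f"samples absent from metadata: {missing}"
                )
            raise ExpressionLoadError("sample metadata/column order mismatch")
        pairs = [(s.region_id, s.replicate) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ExpressionLoadError("duplicate (region, replicate) pairs")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionLoadError(
                f"duplicate probe IDs: {list(dups[:5])}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            bad = self.values.index[~np.isfinite(self.values.to_numpy(float)).all(axis=1)]
            raise ExpressionLoadError(
                f"non-finite or missing expression values in probes {list(bad[:5])}"
            )

    # -- accessors ----------------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def region_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.region_id, None)
        return list(seen)

    def samples_of_region(self, region_id: str) -> list[SampleInfo]:
        return sorted(
            (s for s in self.samples if s.region_id == region_id),
            key=lambda s: s.replicate,
        )

    def drop_controls(self) -> "ExpressionMatrix":
        """Remove control probe sets (requires an annotation)."""
        if self.annotation is None:
            raise ValueError("no annotation attached; cannot identify controls")
        keep = self.values.index.difference(self.annotation.control_probes)
        keep = self.values.index[self.values.index.isin(keep)]  # preserve order
        return ExpressionMatrix(self.values.loc[keep], list(self.samples), self.annotation)

    def subset_regions(self, region_ids: Sequence[str]) -> "ExpressionMatrix":
        wanted = set(region_ids)
        samples = [s for s in self.samples if s.region_id in wanted]
        cols = [s.sample_id for s in samples]
        return ExpressionMatrix(self.values[cols], samples, self.annotation)

    # -- writers ------------------------------------------------------------

    def write_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            out = self.values.copy()
            out.index.name = "probe_id"
            out.to_csv(fh, sep="\t")

    def write_metadata_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(s.sample_id, s.region_id, s.replicate) for s in self.samples],
            columns=["sample_id", "region_id", "replicate"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class RegionProfile:
    """Per-region replicate means and error variances.

    ``region_means`` and ``error_variances`` are probe x region frames;
    ``median_error_variance`` is the per-probe median over regions of the
    replicate variance (n-1 denominator), which calibrates the precision
    prior of the mixture model.  Regions with a single replicate contribute
    no variance (NaN) and are excluded from the median.
    """

    region_means: pd.DataFrame
    error_variances: pd.DataFrame
    median_error_variance: pd.Series

    @property
    def probe_ids(self) -> pd.Index:
        return self.region_means.index

    @property
    def region_ids(self) -> list[str]:
        return list(self.region_means.columns)

    def subset_probes(self, probe_ids: Sequence[str]) -> "RegionProfile":
        idx = pd.Index(probe_ids)
        return RegionProfile(
            self.region_means.loc[idx],
            self.error_variances.loc[idx],
            self.median_error_variance.loc[idx],
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_sample_metadata(path: str | Path) -> list[SampleInfo]:
    """Read sample metadata TSV with columns sample_id, region_id, replicate."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "region_id", "replicate"}
    if not required.issubset(df.columns):
        raise ExpressionLoadError(
            f"metadata must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return [
        SampleInfo(r.sample_id, r.region_id, int(r.replicate))
        for r in df.itertuples()
    ]


def _read_series_matrix_table(path: Path) -> pd.DataFrame:
    """Extract the !series_matrix_table block of a GEO series-matrix file."""
    lines: list[str] = []
    in_table = False
    with path.open() as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                in_table = False
                break
            if in_table:
                lines.append(stripped)
    if not lines:
        raise ExpressionLoadError(f"no !series_matrix_table block found in {path}")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t")
    df.columns = [str(c).strip('"') for c in df.columns]
    first = df.columns[0]
    df[first] = df[first].astype(str).str.strip('"')
    return df.set_index(first)


def read_expression(
    path: str | Path,
    metadata: str | Path | Sequence[SampleInfo],
    fmt: str = "tsv",
    annotation: ProbeAnnotation | None = None,
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Load a probe x sample expression table.

    ``fmt`` is "tsv" (first column probe ID, remaining columns sample IDs)
    or "geo-series-matrix".  Values are assumed log2 already; pass
    ``log2_transform=True`` for linear-scale input.  Control probes are
    flagged through ``annotation`` (default heuristic: AFFX prefix).
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionLoadError(f"no such file: {path}")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    elif fmt == "geo-series-matrix":
        df = _read_series_matrix_table(path)
    else:
        raise ExpressionLoadError(f"unknown format {fmt!r}")
    df.index = df.index.astype(str)
    if not df.index.is_unique:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ExpressionLoadError(f"duplicate probe IDs in {path}: {dups[:5]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ExpressionLoadError(f"non-numeric expression values in {path}: {exc}")
    if df.isna().any().any():
        bad_cols = df.columns[df.isna().any()].tolist()
        raise ExpressionLoadError(f"missing values in columns {bad_cols[:5]}")
    if log2_transform:
        if (df.to_numpy() <= 0).any():
            raise ExpressionLoadError("non-positive values cannot be log2-transformed")
        df = np.log2(df)

    if not isinstance(metadata, (str, Path)):
        samples = list(metadata)
    else:
        samples = read_sample_metadata(metadata)
    by_id = {s.sample_id for s in samples}
    missing = [c for c in df.columns if c not in by_id]
    if missing:
        raise ExpressionLoadError(f"samples absent from metadata: {missing}")
    samples = [s for s in samples if s.sample_id in set(df.columns)]
    ordered = sorted(samples, key=lambda s: list(df.columns).index(s.sample_id))
    if annotation is None:
        annotation = ProbeAnnotation.from_probe_ids(df.index)
    return ExpressionMatrix(df, ordered, annotation)


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ExpressionLoadError(f"{path}:{lineno}: GMT line has <3 fields")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Replicate collapse and QC
# ---------------------------------------------------------------------------


def collapse_replicates(matrix: ExpressionMatrix) -> RegionProfile:
    """Average replicates per region; keep the replicate error variance.

    The error variance uses the unbiased (n-1) estimator — for duplicate
    arrays this is twice the squared half-difference.  Regions with a single
    replicate get NaN variance and are excluded from the per-probe median.
    """
    means: dict[str, np.ndarray] = {}
    variances: dict[str, np.ndarray] = {}
    for region in matrix.region_ids:
        cols = [s.sample_id for s in matrix.samples_of_region(region)]
        if not cols:
            raise ValueError(f"region {region!r} has no samples")
        block = matrix.values[cols].to_numpy(float)
        means[region] = block.mean(axis=1)
        variances[region] = (
            block.var(axis=1, ddof=1) if block.shape[1] >= 2 else np.full(block.shape[0], np.nan)
        )
    regions = matrix.region_ids
    region_means = pd.DataFrame(means, index=matrix.probe_ids, columns=regions)
    error_variances = pd.DataFrame(variances, index=matrix.probe_ids, columns=regions)
    med = error_variances.median(axis=1, skipna=True)
    return RegionProfile(region_means, error_variances, med)


@dataclass
class ReplicateConcordance:
    """Replicate agreement summary: correlations and fold-change profile."""

    global_r: float
    per_region_r: pd.Series
    fold_change_profile: pd.DataFrame
    dynamic_range: tuple[float, float] | None


def replicate_concordance(matrix: ExpressionMatrix) -> ReplicateConcordance:
    """Pearson concordance of replicate pairs and within-2-fold profile.

    Requires exactly two replicates per region.  Data points are binned by
    pair-mean intensity into unit log2 bins [k, k+1); a pair is "within
    2-fold" when |log2 ratio| < 1.  The dynamic range is the widest
    contiguous run of bins whose within-2-fold proportion exceeds 0.5,
    reported as (lowest bin lower edge, highest bin upper edge).
    """
    rep1_cols, rep2_cols = [], []
    for region in matrix.region_ids:
        reps = matrix.samples_of_region(region)
        if len(reps) != 2:
            raise ValueError(
                f"region {region!r} has {len(reps)} replicates; need exactly 2"
            )
        rep1_cols.append(reps[0].sample_id)
        rep2_cols.append(reps[1].sample_id)
    v1 = matrix.values[rep1_cols].to_numpy(float)
    v2 = matrix.values[rep2_cols].to_numpy(float)

    def _r(a: np.ndarray, b: np.ndarray) -> float:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return float("nan")
        return float(pearsonr(a, b).statistic)

    global_r = _r(v1.ravel(), v2.ravel())
    per_region = pd.Series(
        {reg: _r(v1[:, j], v2[:, j]) for j, reg in enumerate(matrix.region_ids)},
        name="pearson_r",
    )

    intensity = (v1 + v2) / 2.0
    within = np.abs(v1 - v2) < 1.0
    rows = []
    for k in INTENSITY_BIN_LOWER_EDGES:
        mask = (intensity >= k) & (intensity < k + 1)
        n = int(mask.sum())
        prop = float(within[mask].mean()) if n else float("nan")
        rows.append({"bin_low": float(k), "bin_high": float(k + 1), "n_pairs": n,
                     "prop_within_2fold": prop})
    profile = pd.DataFrame(rows)

    passing = (profile["prop_within_2fold"] > 0.5).fillna(False).to_numpy()
    best: tuple[int, int] | None = None  # (start, stop) inclusive bins
    start = None
    for i, ok in enumerate(list(passing) + [False]):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    dynamic_range = None
    if best is not None:
        dynamic_range = (float(profile.loc[best[0], "bin_low"]),
                         float(profile.loc[best[1], "bin_high"]))
    return ReplicateConcordance(global_r, per_region, profile, dynamic_range)


# ---------------------------------------------------------------------------
# Region clustering
# ---------------------------------------------------------------------------


@dataclass
class RegionDendrogram:
    """Complete-linkage dendrogram over regions (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]
    metric: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def top_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """The two clusters separated by the final (highest) merge."""
        assignments = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        a = frozenset(l for l, c in zip(self.labels, assignments) if c == 1)
        b = frozenset(l for l, c in zip(self.labels, assignments) if c == 2)
        return a, b

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist if node.count > 1 else parent_height
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.10g}"
            left = walk(node.get_left(), node.dist)
            right = walk(node.get_right(), node.dist)
            return f"({left},{right}):{length:.10g}"

        left = walk(tree.get_left(), tree.dist)
        right = walk(tree.get_right(), tree.dist)
        return f"({left},{right});"


def region_distance_matrix(
    profile: RegionProfile,
    metric: str = "correlation",
    zero_variance: str = "raise",
) -> pd.DataFrame:
    """Pairwise region distances: 1 - Pearson r, or Euclidean.

    A zero-variance (constant-profile) region makes the correlation
    undefined; by default this raises, or with ``zero_variance="max"``
    assigns the maximal correlation distance 2.0.
    """
    regions = sorted(profile.region_ids)
    X = profile.region_means[regions].to_numpy(float).T  # region x probe
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    elif metric == "correlation":
        sd = X.std(axis=1)
        degenerate = sd == 0
        if degenerate.any():
            if zero_variance == "raise":
                bad = [regions[i] for i in np.flatnonzero(degenerate)]
                raise ValueError(
                    f"constant profile region(s) {bad} under correlation metric"
                )
            if zero_variance != "max":
                raise ValueError(f"unknown zero_variance policy {zero_variance!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X)
        D = 1.0 - C
        if degenerate.any():
            D[degenerate, :] = 2.0
            D[:, degenerate] = 2.0
        np.fill_diagonal(D, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(D, index=regions, columns=regions)


def cluster_regions(
    profile: RegionProfile,
    metric: str = "correlation",
    zero_variance: str = "raise",
) -> RegionDendrogram:
    """Complete-linkage hierarchical clustering of regions.

    Regions are ordered lexicographically before linkage so that exact
    distance ties resolve to the lowest region-ID pair, making the
    dendrogram deterministic.
    """
    D = region_distance_matrix(profile, metric, zero_variance)
    if D.shape[0] < 2:
        raise ValueError("need >=2 regions to cluster")
    condensed = squareform(D.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    return RegionDendrogram(Z, list(D.index), metric)


# ---------------------------------------------------------------------------
# Cross-dataset comparison
# ---------------------------------------------------------------------------


def grouped_means(
    profile: RegionProfile,
    grouping_map: Mapping[str, Sequence[str]],
    annotation: ProbeAnnotation,
) -> pd.DataFrame:
    """Gene x group means, one probe per gene (largest overall mean)."""
    gene_map = annotation.gene_map()
    gene_map = gene_map[gene_map.index.isin(profile.probe_ids)]
    if gene_map.empty:
        raise ValueError("no annotated probes in profile")
    overall = profile.region_means.loc[gene_map.index].mean(axis=1)
    best = (
        pd.DataFrame({"gene": gene_map, "mean": overall})
        .sort_values(["gene", "mean", ], kind="mergesort")
        .groupby("gene")
        .tail(1)
    )
    chosen = profile.region_means.loc[best.index]
    out = {}
    for group, regions in grouping_map.items():
        missing = [r for r in regions if r not in profile.region_ids]
        if missing:
            raise ValueError(f"grouping_map regions not in profile: {missing}")
        out[group] = chosen[list(regions)].mean(axis=1)
    grid = pd.DataFrame(out)
    grid.index = best["gene"].to_numpy()
    return grid


def compare_grouped(
    profile: RegionProfile,
    other_table: pd.DataFrame,
    grouping_map: Mapping[str, Sequence[str]],
    annotation: ProbeAnnotation,
) -> float:
    """Pearson r between grouped local means and an external gene x group table.

    Groups are matched by name, genes by symbol; (gene, group) cells missing
    on either side are dropped.  Raises if no genes are shared.
    """
    local = grouped_means(profile, grouping_map, annotation)
    shared_genes = local.index.intersection(other_table.index)
    if len(shared_genes) == 0:
        raise ValueError("no genes shared with the external table")
    shared_groups = [g for g in local.columns if g in other_table.columns]
    if not shared_groups:
        raise ValueError("no groups shared with the external table")
    a = local.loc[shared_genes, shared_groups].to_numpy(float).ravel()
    b = other_table.loc[shared_genes, shared_groups].to_numpy(float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 finite value pairs to correlate")
    return float(pearsonr(a[ok], b[ok]).statistic)
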