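"""Synthetic expression datasets with planted ground truth.

The generator emulates the study design the pipeline targets: 48 CNS
regions profiled in duplicate on the log2 scale, a majority of "one-state"
genes following a log-normal (Gaussian on log2) law of small or large
variance, K-state genes (K = 2..6) whose region means fall into K Gaussian
components separated by a configurable gap, replicate noise with per-probe
variances drawn from a right-skewed (Gamma) distribution, planted
single-region markers, and neurohormone/neurotransmitter pathway catalogs
whose ligand and receptor genes carry up states in designated regions.

Every quantity is recorded in a :class:`TruthTable` so that each pipeline
stage can be scored against the planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ProbeAnnotation, SampleInfo, write_gmt

ONE_STATE_STABLE = "one_state_stable"
ONE_STATE_VARIABLE = "one_state_variable"
PATHWAY_LIGAND = "pathway_ligand"
PATHWAY_RECEPTOR = "pathway_receptor"
CONTROL = "control"

#: Classes whose counts are driven directly by :attr:`SyntheticSpec.class_counts`.
SPEC_CLASSES = (ONE_STATE_STABLE, ONE_STATE_VARIABLE, "k2", "k3", "k4", "k5", "k6")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the generated dataset.

    Defaults mirror the profiled design: 48 regions x 2 replicates, a
    3.0-log2 separation between adjacent states, 0.3 log2 within-state
    spread across regions, and replicate error variances drawn from a
    Gamma distribution with mean 0.04 (shape 2, scale 0.02), matching the
    right-skewed distribution of duplicate error variances on the arrays.
    Expression is centred near 8 with full range about [2, 14] log2 units.
    """

    n_regions: int = 48
    replicates: int = 2
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            ONE_STATE_STABLE: 350,
            ONE_STATE_VARIABLE: 150,
            "k2": 200,
            "k3": 120,
            "k4": 80,
            "k5": 60,
            "k6": 40,
        }
    )
    state_separation: float = 3.0
    within_state_sd: float = 0.3
    one_state_stable_sd: float = 0.1
    one_state_variable_sd: float = 1.2
    replicate_noise_shape: float = 2.0
    replicate_noise_scale: float = 0.02
    marker_fraction: float = 0.2
    min_regions_per_state: int = 2
    up_fraction: float | None = None
    n_pathways: int = 118
    intrinsic_fraction: float = 0.1
    pathway_extra_up: int = 2
    n_hub_pairs: int = 1
    n_controls: int = 10
    n_categories: int = 5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    expr_low: float = 2.0
    expr_high: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.replicates < 1:
            raise ValueError("need >=2 regions and >=1 replicate")
        if self.state_separation <= 0:
            raise ValueError("state_separation must be > 0")
        for cls, n in self.class_counts.items():
            if cls not in SPEC_CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            if n < 0:
                raise ValueError(f"negative count for {cls!r}")
        for k in range(2, 7):
            count = self.class_counts.get(f"k{k}", 0)
            need = 1 + (k - 1) * self.min_regions_per_state
            if count > 0 and need > self.n_regions:
                raise ValueError(
                    f"{k} states need >= {need} regions, have {self.n_regions}"
                )

    def scaled(self, factor: float) -> "SyntheticSpec":
        """Same conditions with class counts scaled (for larger runs)."""
        counts = {c: int(round(n * factor)) for c, n in self.class_counts.items()}
        return replace(self, class_counts=counts)

    @property
    def region_ids(self) -> list[str]:
        return [f"R{i+1:02d}" for i in range(self.n_regions)]


@dataclass
class TruthTable:
    """Planted ground truth: per-probe class/K/states, markers, pathways."""

    probes: pd.DataFrame  # index probe_id: class, true_k, marker_region, gene
    state_assignments: pd.DataFrame  # probe x region true state index
    pathways: pd.DataFrame  # pathway_id, class, ligand/receptor genes, regions

    def probes_of_class(self, cls: str) -> pd.Index:
        return self.probes.index[self.probes["class"] == cls]

    @property
    def planted_markers(self) -> pd.DataFrame:
        mask = self.probes["marker_region"].notna()
        return self.probes[mask]

    @property
    def spec_class_probes(self) -> pd.Index:
        return self.probes.index[self.probes["class"].isin(SPEC_CLASSES)]


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    annotation: ProbeAnnotation
    catalog: pd.DataFrame  # pathway_id, class, role, gene_symbol (one row per gene-role)
    truth: TruthTable
    categories: dict[str, frozenset[str]]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.write_tsv(outdir / "expression.tsv")
        self.expression.write_metadata_tsv(outdir / "samples.tsv")
        ann = self.annotation.frame.copy()
        ann.index.name = "probe_id"
        ann.to_csv(outdir / "annotation.tsv", sep="\t")
        self.catalog.to_csv(outdir / "pathways.tsv", sep="\t", index=False)
        write_gmt(self.categories, outdir / "categories.gmt")
        truth = self.truth.probes.copy()
        truth.index.name = "probe_id"
        truth.to_csv(outdir / "truth_probes.tsv", sep="\t")
        self.truth.state_assignments.to_csv(outdir / "truth_states.tsv", sep="\t")
        self.truth.pathways.to_json(
            outdir / "truth_pathways.json", orient="records", indent=2
        )


def _partition_regions(
    rng: np.random.Generator,
    n_regions: int,
    k: int,
    singleton_top: bool,
    min_per_state: int,
    up_fraction: float | None = None,
) -> np.ndarray:
    """Random region -> state map; non-top states own >= min_per_state regions.

    By default the regions beyond the per-state minima are spread uniformly
    among the states.  With ``up_fraction`` set, the lowest state instead
    holds the bulk: the non-lowest ("up") states share about that fraction
    of the regions, emulating genes that are up in only a minority of
    regions at the cost of small, harder-to-resolve upper states.
    """
    if up_fraction is None:
        sizes = np.full(k, min_per_state)
        sizes[-1] = 1 if singleton_top else min_per_state
        spare = n_regions - sizes.sum()
        if spare < 0:
            raise ValueError("more states than regions permit")
        if spare:
            eligible = k - 1 if singleton_top else k
            extra = rng.multinomial(spare, np.full(eligible, 1.0 / eligible))
            sizes[:eligible] += extra
    else:
        mins = np.full(k, min_per_state)
        mins[0] = 1
        if singleton_top:
            mins[-1] = 1
        if mins.sum() > n_regions:
            raise ValueError("more states than regions permit")
        n_up_min = int(mins[1:].sum())
        n_up = max(n_up_min, int(round(up_fraction * n_regions)))
        n_up = min(n_up, n_regions - 1)
        sizes = mins.copy()
        spare_up = n_up - n_up_min
        if spare_up > 0:
            eligible = np.arange(1, k - 1) if singleton_top else np.arange(1, k)
            if eligible.size:
                extra = rng.multinomial(
                    spare_up, np.full(eligible.size, 1.0 / eligible.size)
                )
                sizes[eligible] += extra
        sizes[0] = n_regions - sizes[1:].sum()
    assign = np.repeat(np.arange(k), sizes)
    rng.shuffle(assign)
    return assign


def _state_means(
    rng: np.random.Generator, spec: SyntheticSpec, k: int
) -> np.ndarray:
    """K ascending means separated by the spec gap (shrunk if out of range)."""
    lo = spec.expr_low + 0.5
    hi = spec.expr_high - 0.5
    sep = spec.state_separation
    if k > 1:
        sep = min(sep, (hi - lo) / (k - 1))
    span = sep * (k - 1)
    base = rng.uniform(lo, hi - span)
    return base + sep * np.arange(k)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a dataset with planted states, markers and pathway wiring.

    The same spec and seed always produce byte-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    regions = spec.region_ids
    R = spec.n_regions

    probe_ids: list[str] = []
    genes: list[str] = []
    classes: list[str] = []
    true_k: list[int] = []
    marker_region: list[str | None] = []
    separations: list[float] = []
    region_mean_rows: list[np.ndarray] = []
    state_rows: list[np.ndarray] = []

    def add_probe(pid, gene, cls, k, marker, means, states, separation=np.nan):
        probe_ids.append(pid)
        genes.append(gene)
        classes.append(cls)
        true_k.append(k)
        marker_region.append(marker)
        separations.append(separation)
        region_mean_rows.append(means)
        state_rows.append(states)

    serial = 0

    def next_id() -> tuple[str, str]:
        nonlocal serial
        serial += 1
        return f"P{serial:06d}", f"G{serial:06d}"

    # ---- one-state probes -------------------------------------------------
    for cls, sd in ((ONE_STATE_STABLE, spec.one_state_stable_sd),
                    (ONE_STATE_VARIABLE, spec.one_state_variable_sd)):
        for _ in range(spec.class_counts.get(cls, 0)):
            pid, gene = next_id()
            mu = float(np.clip(rng.normal(spec.baseline_mean, spec.baseline_sd),
                               spec.expr_low + 1, spec.expr_high - 1))
            means = mu + rng.normal(0.0, sd, R)
            add_probe(pid, gene, cls, 1, None, means, np.zeros(R, int))

    # ---- multi-state probes ------------------------------------------------
    for k in range(2, 7):
        count = spec.class_counts.get(f"k{k}", 0)
        n_markers = int(round(spec.marker_fraction * count))
        for i in range(count):
            pid, gene = next_id()
            is_marker = i < n_markers
            smeans = _state_means(rng, spec, k)
            assign = _partition_regions(
                rng, R, k, is_marker, spec.min_regions_per_state,
                spec.up_fraction,
            )
            means = smeans[assign] + rng.normal(0.0, spec.within_state_sd, R)
            marker = None
            if is_marker:
                marker = regions[int(np.flatnonzero(assign == k - 1)[0])]
            sep = float(np.diff(smeans).min())
            add_probe(pid, gene, f"k{k}", k, marker, means, assign, sep)

    # ---- pathway probes -----------------------------------------------------
    n_intrinsic = int(round(spec.intrinsic_fraction * spec.n_pathways))
    hub_pairs: list[tuple[int, int]] = []
    while len(hub_pairs) < max(spec.n_hub_pairs, 1):
        a, b = rng.choice(R, size=2, replace=False)
        if (a, b) not in hub_pairs:
            hub_pairs.append((int(a), int(b)))
    pathway_classes = np.array(
        ["monoamine/ACh", "amino acid", "peptide", "gas", "other"]
    )
    pathway_recs = []
    for p in range(spec.n_pathways):
        intrinsic = p < n_intrinsic
        if intrinsic:
            src = dst = int(rng.integers(R))
        else:
            src, dst = hub_pairs[(p - n_intrinsic) % len(hub_pairs)]
        lig_pid, _ = next_id()
        rec_pid, _ = next_id()
        lig_gene = f"LIG{p+1:03d}"
        rec_gene = f"REC{p+1:03d}"

        def two_state(center: int) -> tuple[np.ndarray, np.ndarray, frozenset[str]]:
            ups = {center}
            others = [i for i in range(R) if i != center]
            ups |= set(
                int(x) for x in rng.choice(others, spec.pathway_extra_up, replace=False)
            )
            assign = np.zeros(R, int)
            assign[sorted(ups)] = 1
            smeans = _state_means(rng, spec, 2)
            means = smeans[assign] + rng.normal(0.0, spec.within_state_sd, R)
            return means, assign, frozenset(regions[i] for i in sorted(ups))

        lmeans, lassign, lups = two_state(src)
        rmeans, rassign, rups = two_state(dst)
        add_probe(lig_pid, lig_gene, PATHWAY_LIGAND, 2, None, lmeans, lassign,
                  spec.state_separation)
        add_probe(rec_pid, rec_gene, PATHWAY_RECEPTOR, 2, None, rmeans, rassign,
                  spec.state_separation)
        pathway_recs.append(
            {
                "pathway_id": f"PW{p+1:03d}",
                "class": str(pathway_classes[p % len(pathway_classes)]),
                "ligand_genes": [lig_gene],
                "receptor_genes": [rec_gene],
                "ligand_up_regions": sorted(lups),
                "receptor_up_regions": sorted(rups),
                "source_region": regions[src],
                "target_region": regions[dst],
                "intrinsic": intrinsic,
            }
        )

    # ---- control probes -----------------------------------------------------
    for c in range(spec.n_controls):
        pid = f"AFFX-CTRL{c+1:03d}"
        mu = float(rng.normal(spec.baseline_mean, 0.5))
        means = mu + rng.normal(0.0, 0.05, R)
        add_probe(pid, None, CONTROL, 1, None, means, np.zeros(R, int))

    # ---- replicate values ----------------------------------------------------
    P = len(probe_ids)
    region_means = np.vstack(region_mean_rows)
    noise_var = rng.gamma(spec.replicate_noise_shape, spec.replicate_noise_scale, P)
    samples = [
        SampleInfo(f"{reg}_rep{rep}", reg, rep)
        for reg in regions
        for rep in range(1, spec.replicates + 1)
    ]
    values = np.empty((P, len(samples)))
    for j, s in enumerate(samples):
        ridx = regions.index(s.region_id)
        values[:, j] = region_means[:, ridx] + rng.normal(0.0, np.sqrt(noise_var))
    values = np.clip(values, 0.0, 16.0)

    frame = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"),
        columns=[s.sample_id for s in samples],
    )
    gene_syms = {p: g for p, g in zip(probe_ids, genes) if g is not None}
    annotation = ProbeAnnotation.from_probe_ids(probe_ids, gene_syms)

    # ---- categories (random gene sets over non-control genes) ---------------
    all_genes = [g for g in genes if g is not None]
    categories: dict[str, frozenset[str]] = {}
    if all_genes:
        for c in range(spec.n_categories):
            size = min(len(all_genes), int(rng.integers(10, 31)))
            picked = rng.choice(len(all_genes), size, replace=False)
            categories[f"CAT{c+1:02d}"] = frozenset(all_genes[i] for i in picked)

    catalog_rows = []
    for rec in pathway_recs:
        for g in rec["ligand_genes"]:
            catalog_rows.append((rec["pathway_id"], rec["class"], "ligand", g))
        for g in rec["receptor_genes"]:
            catalog_rows.append((rec["pathway_id"], rec["class"], "receptor", g))
    catalog = pd.DataFrame(
        catalog_rows, columns=["pathway_id", "class", "role", "gene_symbol"]
    )

    truth = TruthTable(
        probes=pd.DataFrame(
            {
                "class": classes,
                "true_k": true_k,
                "marker_region": marker_region,
                "separation": separations,
                "gene": genes,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        ),
        state_assignments=pd.DataFrame(
            np.vstack(state_rows), index=pd.Index(probe_ids, name="probe_id"),
            columns=regions,
        ),
        pathways=pd.DataFrame(pathway_recs),
    )
    expression = ExpressionMatrix(frame, samples, annotation)
    return SyntheticDataset(expression, annotation, catalog, truth, categories)


# ---------------------------------------------------------------------------
# Truth-table scoring
# ---------------------------------------------------------------------------


def k_recovery_rate(truth: TruthTable, table) -> float:
    """Fraction of spec-class probes whose called state count equals true K."""
    probes = truth.spec_class_probes.intersection(table.probes.index)
    if probes.empty:
        raise ValueError("no scored probes present in the table")
    called = table.probes.loc[probes, "n_states"].to_numpy()
    planted = truth.probes.loc[probes, "true_k"].to_numpy()
    return float((called == planted).mean())


def one_state_false_call_rate(truth: TruthTable, table) -> float:
    """Fraction of planted one-state probes called multi-state."""
    ones = truth.probes.index[truth.probes["true_k"] == 1].intersection(
        table.probes.index
    )
    if ones.empty:
        raise ValueError("no one-state probes present in the table")
    return float((table.probes.loc[ones, "n_states"] >= 2).mean())


def marker_recovery(
    truth: TruthTable,
    marker_calls: pd.DataFrame,
    min_separation: float | None = None,
) -> dict:
    """Sensitivity and false-call proportion of high-direction marker calls.

    Sensitivity: planted markers recovered with the correct region,
    optionally restricted to markers whose gene realized at least
    ``min_separation`` between adjacent state means (genes with many states
    shrink their separation to stay inside the expression range).  The
    false rate is the proportion of high calls on spec-class probes that
    were not planted as markers (a false-discovery proportion) and always
    counts every call.
    """
    all_planted = truth.planted_markers
    planted = all_planted
    if min_separation is not None:
        planted = planted[planted["separation"] >= min_separation - 1e-9]
    high = marker_calls[marker_calls["direction"] == "high"]
    by_probe = dict(zip(high["probe_id"], high["region"]))
    hit = sum(
        1
        for pid, row in planted.iterrows()
        if by_probe.get(pid) == row["marker_region"]
    )
    sensitivity = hit / len(planted) if len(planted) else float("nan")
    scored = high[high["probe_id"].isin(truth.spec_class_probes)]
    false_calls = sum(
        1 for pid in scored["probe_id"] if pid not in all_planted.index
    )
    false_rate = false_calls / len(scored) if len(scored) else 0.0
    return {
        "sensitivity": sensitivity,
        "false_rate": false_rate,
        "n_planted": int(len(planted)),
        "n_called": int(len(scored)),
    }
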