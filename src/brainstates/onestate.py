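"""Internal-control discovery: presence filtering and variability scoring.

One-state probes (no multi-state structure) are screened for detectable
expression, then scored for cross-region variability.  The score of a
probe is log2 of its across-region standard deviation divided by the
running median of the standard deviations of probes with a similar mean —
removing the global mean-variance trend of the arrays.  Scores below -1
mark "stable" probes (internal-control candidates); above +1, "variable"
ones; the inequalities are strict, so the boundaries class as "neither".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, RegionProfile

STABLE_THRESHOLD = -1.0
VARIABLE_THRESHOLD = 1.0
DEFAULT_WINDOW = 501


@dataclass
class PresenceResult:
    kept: pd.Index
    filtered_out: pd.Index
    fallback_used: bool


def presence_filter(
    probe_ids: Sequence[str],
    matrix: ExpressionMatrix,
    detection_calls: pd.DataFrame | None = None,
    fallback_quantile: float = 0.25,
) -> PresenceResult:
    """Keep probes detected in at least one region.

    With a detection-call matrix (probe x sample, values P/M/A), a probe is
    "present" in a region when every replicate of that region is called P,
    and kept when present in >= 1 region.  Without calls, a documented
    proxy applies — keep probes whose best region mean exceeds the dataset
    quantile of all expression values — and the result is flagged.
    """
    idx = pd.Index(probe_ids)
    if detection_calls is not None:
        if list(detection_calls.columns) != matrix.sample_ids:
            raise ValueError(
                "detection-call columns do not match expression samples"
            )
        missing = idx.difference(detection_calls.index)
        if len(missing):
            raise ValueError(f"probes missing from detection calls: {list(missing[:5])}")
        calls = detection_calls.loc[idx]
        present_any = np.zeros(len(idx), bool)
        for region in matrix.region_ids:
            cols = [s.sample_id for s in matrix.samples_of_region(region)]
            present_any |= (calls[cols] == "P").all(axis=1).to_numpy()
        kept = idx[present_any]
        return PresenceResult(kept, idx[~present_any], fallback_used=False)

    threshold = float(np.quantile(matrix.values.to_numpy(float), fallback_quantile))
    from .io import collapse_replicates

    profile = collapse_replicates(matrix)
    best = profile.region_means.loc[idx].max(axis=1)
    keep_mask = (best > threshold).to_numpy()
    return PresenceResult(idx[keep_mask], idx[~keep_mask], fallback_used=True)


@dataclass
class VariabilityTable:
    """Per-probe mean, SD, running-median SD, score and class."""

    frame: pd.DataFrame  # index probe_id: mean, sd, running_median_sd, score, class
    window: int
    fallback_presence: bool = False

    @property
    def stable_probes(self) -> pd.Index:
        return self.frame.index[self.frame["class"] == "stable"]

    @property
    def variable_probes(self) -> pd.Index:
        return self.frame.index[self.frame["class"] == "variable"]


def variability_scores(
    profile: RegionProfile,
    probe_ids: Sequence[str],
    window: int = DEFAULT_WINDOW,
    fallback_presence: bool = False,
) -> VariabilityTable:
    """Score cross-region variability of one-state probes.

    SD is taken across the per-region means.  Probes are sorted by mean and
    the running median of SD uses a centred window of ``window`` probes,
    truncated at the edges; the score is log2(sd / running_median_sd).
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    idx = pd.Index(probe_ids)
    if len(idx) < window:
        window = max(3, (len(idx) // 2) * 2 + 1)
    means = profile.region_means.loc[idx].mean(axis=1)
    sds = profile.region_means.loc[idx].std(axis=1, ddof=1)
    order = means.sort_values(kind="mergesort").index
    runmed = (
        sds.loc[order]
        .rolling(window, center=True, min_periods=1)
        .median()
        .reindex(idx)
    )
    if (runmed <= 0).any():
        raise ValueError("running median SD is not positive everywhere")
    score = np.log2(sds / runmed)
    cls = pd.Series("neither", index=idx)
    cls[score < STABLE_THRESHOLD] = "stable"
    cls[score > VARIABLE_THRESHOLD] = "variable"
    frame = pd.DataFrame(
        {
            "mean": means,
            "sd": sds,
            "running_median_sd": runmed,
            "score": score,
            "class": cls,
        }
    )
    return VariabilityTable(frame, window, fallback_presence)
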