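"""Variational-Bayes Gaussian-mixture state calling per probe.

Each probe's profile of per-region mean expression (48 values on the log2
scale) is fit with univariate Gaussian mixtures of K = 1..6 components,
each component with its own variance, under conjugate priors:

    pi ~ Dirichlet(alpha0, ..., alpha0)
    lambda_k ~ Gamma(a0, b0)                    (component precision)
    mu_k | lambda_k ~ Normal(m0, 1/(beta0 * lambda_k))

The (a0, b0) precision prior is calibrated from the data by moment-matching
a Gamma distribution to the empirical distribution of 1 / (median replicate
error variance) across probes — replicate information enters the fit only
through this prior.  For each probe the K maximizing the final variational
lower bound (ELBO) is selected, empty components are pruned, overlapping or
nested components are merged, and the surviving states are ordered by mean.
Probes with >=2 states are "multi-state"; their non-lowest states binarize
to "up".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .io import ProbeAnnotation, RegionProfile

_LN2PI = float(np.log(2.0 * np.pi))

#: Floor applied to replicate error variances before taking reciprocals.
VARIANCE_FLOOR = 1e-6

#: Default maximum number of mixture components considered.
K_MAX = 6


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GmmPrior:
    """Hyper-parameters of the conjugate prior (all strictly positive)."""

    alpha0: float = 1.0
    m0: float = 8.0
    beta0: float = 0.01
    a0: float = 2.0
    b0: float = 0.08

    def __post_init__(self) -> None:
        for name in ("alpha0", "m0", "beta0", "a0", "b0"):
            val = getattr(self, name)
            if name != "m0" and not val > 0:
                raise ValueError(f"{name} must be > 0, got {val}")

    def with_alpha0(self, alpha0: float) -> "GmmPrior":
        return replace(self, alpha0=alpha0)


def determine_prior(
    profile: RegionProfile,
    alpha0: float = 1.0,
    beta0: float = 0.01,
    variance_floor: float = VARIANCE_FLOOR,
    default_shape: float = 2.0,
) -> GmmPrior:
    """Calibrate the precision prior from replicate error variances.

    (a0, b0) moment-match a Gamma distribution to the empirical precisions
    1/median_error_variance (population moments); m0 is the grand mean of
    the region means.  If the precisions have no spread (e.g. a synthetic
    matrix with identical noise), the shape falls back to ``default_shape``
    with the rate set to preserve the mean precision.
    """
    medvar = profile.median_error_variance.to_numpy(float)
    medvar = medvar[np.isfinite(medvar)]
    if medvar.size == 0 or np.all(medvar <= 0):
        raise ValueError(
            "all replicate error variances are zero or missing; "
            "supply an explicit GmmPrior instead of calibrating one"
        )
    prec = 1.0 / np.maximum(medvar, variance_floor)
    mean = float(prec.mean())
    var = float(prec.var())  # population variance
    if var < 1e-12 * max(mean**2, 1.0):
        a0, b0 = default_shape, default_shape / mean
    else:
        a0, b0 = mean**2 / var, mean / var
    m0 = float(profile.region_means.to_numpy(float).mean())
    return GmmPrior(alpha0=alpha0, m0=m0, beta0=beta0, a0=a0, b0=b0)


# ---------------------------------------------------------------------------
# Batched VB-EM core
# ---------------------------------------------------------------------------


def _quantile_init(X: np.ndarray, K: int) -> np.ndarray:
    """K-quantile seeding of component means from each sorted profile.

    Quantile levels span the full range (0..1 inclusive) so that extreme
    states — including a singleton marker region — receive a seed.
    """
    qs = np.linspace(0.0, 1.0, K) if K > 1 else np.array([0.5])
    return np.quantile(X, qs, axis=1).T  # (P, K)


def _init_resp(X: np.ndarray, init_means: np.ndarray) -> np.ndarray:
    """Soft nearest-mean assignment used to start the first M-step."""
    P, n = X.shape
    K = init_means.shape[1]
    scale2 = np.maximum(X.var(axis=1), 1e-4) / max(K, 1) ** 2  # (P,)
    d2 = (X[:, :, None] - init_means[:, None, :]) ** 2
    lnr = -0.5 * d2 / scale2[:, None, None]
    lnr -= logsumexp(lnr, axis=2, keepdims=True)
    return np.exp(lnr)


def _vb_gmm_batch(
    X: np.ndarray,
    prior: GmmPrior,
    K: int,
    init_means: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    track_trace: bool = False,
):
    """Run VB-EM to convergence on a batch of profiles.

    X: (P, n) profiles; init_means: (P, K).  Returns a dict with posterior
    parameter arrays of shape (P, K), responsibilities (P, n, K), final
    ``elbo`` (P,), ``converged`` (P,), ``n_iter`` (P,) and, when
    ``track_trace``, the per-profile ELBO trajectories.

    The bound is evaluated after each E-step, where its data-dependent part
    collapses to the sum of the responsibility normalizers (log-sum-exp of
    the unnormalized log responsibilities); the remaining terms are the
    KL divergences of the Dirichlet and Normal-Gamma factors from their
    priors.  Evaluating at (new responsibilities, parameters of the
    preceding M-step) makes the trajectory non-decreasing by construction.
    """
    X = np.asarray(X, float)
    P, n = X.shape
    a0, b0, beta0, m0, al0 = prior.a0, prior.b0, prior.beta0, prior.m0, prior.alpha0

    resp = _init_resp(X, np.asarray(init_means, float))
    alpha = np.empty((P, K))
    beta = np.empty((P, K))
    m = np.empty((P, K))
    a = np.empty((P, K))
    b = np.empty((P, K))
    elbo = np.full(P, -np.inf)
    n_iter = np.zeros(P, int)
    converged = np.zeros(P, bool)
    traces: list[list[float]] = [[] for _ in range(P)] if track_trace else []

    active = np.arange(P)
    # Dirichlet normalizer of the symmetric prior (constant per profile).
    ln_c_alpha0 = gammaln(K * al0) - K * gammaln(al0)
    X2 = X * X

    # sufficient statistics of the current responsibilities
    Nk = resp.sum(axis=1)
    Sx = np.einsum("pnk,pn->pk", resp, X)
    Sxx = np.einsum("pnk,pn->pk", resp, X2)

    for iteration in range(1, max_iter + 1):
        Xa = X[active]
        Nk_a, Sx_a, Sxx_a = Nk[active], Sx[active], Sxx[active]

        # ---- M-step -------------------------------------------------------
        safe = np.maximum(Nk_a, 1e-300)
        xbar = Sx_a / safe
        Sk = np.maximum(Sxx_a / safe - xbar**2, 0.0)
        al = al0 + Nk_a
        be = beta0 + Nk_a
        mm = (beta0 * m0 + Nk_a * xbar) / be
        aa = a0 + Nk_a / 2.0
        bb = b0 + 0.5 * (Nk_a * Sk + beta0 * Nk_a * (xbar - m0) ** 2 / be)

        # ---- E-step -------------------------------------------------------
        eln_pi = digamma(al) - digamma(al.sum(axis=1, keepdims=True))
        eln_lam = digamma(aa) - np.log(bb)
        e_lam = aa / bb
        lnrho = (Xa[:, :, None] - mm[:, None, :]) ** 2
        lnrho *= -0.5 * e_lam[:, None, :]
        lnrho += (
            eln_pi + 0.5 * eln_lam - 0.5 * (_LN2PI + 1.0 / be)
        )[:, None, :]
        lnZ = logsumexp(lnrho, axis=2, keepdims=True)
        r_new = np.exp(lnrho - lnZ)

        # ---- bound: sum of normalizers minus factor KL terms --------------
        # -KL[q(pi) || p(pi)]
        ln_c_al = gammaln(al.sum(axis=1)) - gammaln(al).sum(axis=1)
        kl_pi = (
            ln_c_al - ln_c_alpha0 + ((al - al0) * eln_pi).sum(axis=1)
        )
        # -KL[q(mu, lambda) || p(mu, lambda)] summed over components
        kl_ml = (
            0.5 * (np.log(be / beta0) - 1.0 + beta0 / be
                   + beta0 * e_lam * (mm - m0) ** 2)
            + a0 * np.log(bb / b0)
            + gammaln(a0)
            - gammaln(aa)
            + (aa - a0) * digamma(aa)
            - aa * (1.0 - b0 / bb)
        ).sum(axis=1)
        new_elbo = lnZ.sum(axis=(1, 2)) - kl_pi - kl_ml

        # ---- store and check convergence ---------------------------------
        resp[active] = r_new
        alpha[active], beta[active], m[active] = al, be, mm
        a[active], b[active] = aa, bb
        Nk[active] = r_new.sum(axis=1)
        Sx[active] = np.einsum("pnk,pn->pk", r_new, Xa)
        Sxx[active] = np.einsum("pnk,pn->pk", r_new, Xa * Xa)
        delta = new_elbo - elbo[active]
        elbo[active] = new_elbo
        n_iter[active] = iteration
        if track_trace:
            for idx, val in zip(active, new_elbo):
                traces[idx].append(float(val))
        done = np.abs(delta) < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break

    return {
        "alpha": alpha,
        "beta": beta,
        "m": m,
        "a": a,
        "b": b,
        "resp": resp,
        "elbo": elbo,
        "converged": converged,
        "n_iter": n_iter,
        "traces": traces,
    }


def _restart_inits(
    X: np.ndarray, K: int, n_restarts: int, seed: int
) -> np.ndarray:
    """Quantile init plus jittered restarts: (P * n_restarts, K) means."""
    P = X.shape[0]
    base = _quantile_init(X, K)  # (P, K)
    inits = np.repeat(base[:, None, :], n_restarts, axis=1)  # (P, R, K)
    if n_restarts > 1:
        rng = np.random.default_rng(seed)
        jitter_sd = np.maximum(X.std(axis=1), 1e-3) / 2.0
        noise = rng.normal(size=(P, n_restarts - 1, K)) * jitter_sd[:, None, None]
        inits[:, 1:, :] += noise
    return inits.reshape(P * n_restarts, K)


# ---------------------------------------------------------------------------
# Single-profile fit
# ---------------------------------------------------------------------------


@dataclass
class GmmFit:
    """Posterior of one VB-GMM fit at a requested K."""

    K_requested: int
    alpha: np.ndarray
    beta: np.ndarray
    m: np.ndarray
    a: np.ndarray
    b: np.ndarray
    resp: np.ndarray
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1])

    @property
    def weights(self) -> np.ndarray:
        """Posterior expectation of the mixing proportions."""
        return self.alpha / self.alpha.sum()

    @property
    def means(self) -> np.ndarray:
        return self.m

    @property
    def sigmas(self) -> np.ndarray:
        """Component scale sqrt(E[lambda]^-1)."""
        return np.sqrt(self.b / self.a)

    def assignments(self) -> np.ndarray:
        return self.resp.argmax(axis=1)


def fit_vb_gmm(
    profile: Sequence[float],
    prior: GmmPrior,
    K: int,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 500,
    init_means: Sequence[float] | None = None,
) -> GmmFit:
    """Fit one profile at a fixed K; best of ``n_restarts`` by final ELBO.

    Non-convergence within ``max_iter`` is flagged on the result, not
    raised.  ``init_means`` overrides the quantile initialization (single
    restart), which the tests use to probe initialization invariance.
    """
    x = np.asarray(profile, float)
    if x.ndim != 1:
        raise ValueError("profile must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError("profile contains non-finite values")
    if not 1 <= K <= K_MAX:
        raise ValueError(f"K must be in 1..{K_MAX}, got {K}")
    X = x[None, :]
    if init_means is not None:
        inits = np.asarray(init_means, float)[None, :]
        if inits.shape[1] != K:
            raise ValueError("init_means length must equal K")
        n_restarts = 1
    else:
        inits = _restart_inits(X, K, n_restarts, seed)
    Xrep = np.repeat(X, n_restarts, axis=0)
    out = _vb_gmm_batch(Xrep, prior, K, inits, tol, max_iter, track_trace=True)
    best = int(np.argmax(out["elbo"]))
    return GmmFit(
        K_requested=K,
        alpha=out["alpha"][best],
        beta=out["beta"][best],
        m=out["m"][best],
        a=out["a"][best],
        b=out["b"][best],
        resp=out["resp"][best],
        elbo_trace=np.asarray(out["traces"][best]),
        converged=bool(out["converged"][best]),
        n_iter=int(out["n_iter"][best]),
    )


# ---------------------------------------------------------------------------
# State models
# ---------------------------------------------------------------------------


@dataclass
class StateModel:
    """Effective expression states of one probe after pruning and merging."""

    region_ids: tuple[str, ...]
    state_means: tuple[float, ...]  # ascending
    assignment: np.ndarray  # per-region index into state_means

    def __post_init__(self) -> None:
        means = np.asarray(self.state_means)
        if means.size and np.any(np.diff(means) < 0):
            raise ValueError("state_means must be ascending")
        counts = np.bincount(self.assignment, minlength=len(self.state_means))
        if len(self.state_means) and counts.min() < 1:
            raise ValueError("every state must own at least one region")

    @property
    def n_states(self) -> int:
        return len(self.state_means)

    @property
    def labels(self) -> tuple[str, ...]:
        """State labels from lowest to highest mean."""
        k = self.n_states
        if k == 1:
            return ("one",)
        middles = tuple(f"middle{i}" if k > 3 else "middle" for i in range(1, k - 1))
        return ("low",) + middles + ("high",)

    def regions_of_state(self, state: int) -> frozenset[str]:
        return frozenset(
            r for r, s in zip(self.region_ids, self.assignment) if s == state
        )

    @property
    def expression_range(self) -> float:
        return float(self.state_means[-1] - self.state_means[0]) if self.state_means else 0.0


def binarize(model: StateModel) -> dict[str, str]:
    """Up/down labels per region: only the lowest-mean state is "down".

    Middle and high states are not distinguished.  One-state probes carry
    no up/down structure and raise.
    """
    if model.n_states < 2:
        raise ValueError("one-state model has no up/down binarization")
    return {
        r: ("down" if s == 0 else "up")
        for r, s in zip(model.region_ids, model.assignment)
    }


def up_regions(model: StateModel) -> frozenset[str]:
    if model.n_states < 2:
        return frozenset()
    return frozenset(
        r for r, s in zip(model.region_ids, model.assignment) if s > 0
    )


def merge_overlapping_states(
    means: Sequence[float],
    sigmas: Sequence[float],
    c: float = 2.0,
) -> list[list[int]]:
    """Group components whose means lie within ``c * max(sigma_i, sigma_j)``.

    The relation is applied transitively (union-find), capturing the case of
    one narrow component nested inside a broad one.  Returns groups of
    component indices.
    """
    means = np.asarray(means, float)
    sigmas = np.asarray(sigmas, float)
    k = means.size
    parent = list(range(k))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if abs(means[i] - means[j]) <= c * max(sigmas[i], sigmas[j]):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: means[g].min())


def _build_state_model(
    region_ids: Sequence[str],
    comp_means: np.ndarray,
    comp_sigmas: np.ndarray,
    hard_assign: np.ndarray,
    c_merge: float,
) -> StateModel:
    """Prune empty components, merge overlaps, order states by mean."""
    used = np.unique(hard_assign)
    means_u = comp_means[used]
    sigmas_u = comp_sigmas[used]
    counts = np.array([(hard_assign == u).sum() for u in used], float)
    groups = merge_overlapping_states(means_u, sigmas_u, c_merge)
    # merged state mean = occupancy-weighted mean of member components
    merged_means = np.array(
        [float((means_u[g] * counts[g]).sum() / counts[g].sum()) for g in groups]
    )
    order = np.argsort(merged_means, kind="stable")
    comp_to_state = np.empty(comp_means.size, int)
    for rank, gi in enumerate(order):
        for member in groups[gi]:
            comp_to_state[used[member]] = rank
    assignment = comp_to_state[hard_assign]
    return StateModel(
        region_ids=tuple(region_ids),
        state_means=tuple(merged_means[order]),
        assignment=assignment,
    )


def select_state_model(
    profile: Sequence[float],
    prior: GmmPrior,
    region_ids: Sequence[str] | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    k_max: int = K_MAX,
    c_merge: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> StateModel:
    """Fit K = 1..k_max, pick the best ELBO, prune and merge into states."""
    x = np.asarray(profile, float)
    if region_ids is None:
        region_ids = [f"r{i}" for i in range(x.size)]
    fits = [
        fit_vb_gmm(x, prior, K, seed=seed, n_restarts=n_restarts, tol=tol,
                   max_iter=max_iter)
        for K in range(1, k_max + 1)
    ]
    best = max(range(len(fits)), key=lambda i: fits[i].elbo)
    fit = fits[best]
    return _build_state_model(
        region_ids, fit.means, fit.sigmas, fit.assignments(), c_merge
    )


# ---------------------------------------------------------------------------
# Whole-dataset classification
# ---------------------------------------------------------------------------


@dataclass
class MultiStateTable:
    """Per-probe state models with gene-level aggregation and totals.

    A gene is multi-state when any of its probes has >=2 states; its up
    regions are the union over those probes.  G = number of unique
    multi-state genes, U = total up-state region assignments over those
    genes, R = number of regions.
    """

    probes: pd.DataFrame  # index probe_id: gene, n_states, up_regions
    models: dict[str, StateModel]
    region_ids: tuple[str, ...]
    genes: pd.DataFrame = field(init=False)  # index gene: multi_state, up_regions

    def __post_init__(self) -> None:
        recs = []
        for gene, grp in self.probes.groupby("gene", dropna=True, sort=True):
            multi = bool((grp["n_states"] >= 2).any())
            ups: frozenset[str] = frozenset()
            for u in grp.loc[grp["n_states"] >= 2, "up_regions"]:
                ups |= u
            recs.append((gene, multi, ups, len(grp)))
        self.genes = pd.DataFrame(
            recs, columns=["gene", "multi_state", "up_regions", "n_probes"]
        ).set_index("gene")

    @property
    def R(self) -> int:
        return len(self.region_ids)

    @property
    def G(self) -> int:
        return int(self.genes["multi_state"].sum())

    @property
    def U(self) -> int:
        multi = self.genes[self.genes["multi_state"]]
        return int(multi["up_regions"].map(len).sum())

    @property
    def multi_state_probes(self) -> pd.Index:
        return self.probes.index[self.probes["n_states"] >= 2]

    @property
    def multi_state_genes(self) -> frozenset[str]:
        return frozenset(self.genes.index[self.genes["multi_state"]])

    def gene_up_regions(self, gene: str) -> frozenset[str]:
        return self.genes.at[gene, "up_regions"]

    def state_histogram(self) -> pd.Series:
        """Number of probes per effective state count (Fig 2A analogue)."""
        return self.probes["n_states"].value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        out = self.probes.copy()
        out["up_regions"] = out["up_regions"].map(lambda s: ",".join(sorted(s)))
        out["states"] = [
            ";".join(str(s) for s in self.models[p].assignment)
            for p in out.index
        ]
        return out

    def summary(self) -> dict:
        return {
            "n_probes": int(len(self.probes)),
            "n_multi_state_probes": int((self.probes["n_states"] >= 2).sum()),
            "G": self.G,
            "U": self.U,
            "R": self.R,
            "state_histogram": {int(k): int(v) for k, v in self.state_histogram().items()},
        }


def classify_dataset(
    profile: RegionProfile,
    prior: GmmPrior,
    annotation: ProbeAnnotation | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    k_max: int = K_MAX,
    c_merge: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MultiStateTable:
    """State-call every probe (vectorized over the whole dataset).

    All probes are fit jointly at each K with jittered restarts; per probe
    the best restart and then the best K by final ELBO are kept (ties go to
    the smaller K).  Probe -> gene aggregation uses the annotation's gene
    symbols; unannotated probes aggregate under their own probe ID.
    """
    X = profile.region_means.to_numpy(float)
    P, n = X.shape
    regions = tuple(profile.region_ids)
    probe_ids = list(profile.probe_ids)

    best_elbo = np.full(P, -np.inf)
    best_K = np.zeros(P, int)
    best_params: list[tuple[np.ndarray, np.ndarray, np.ndarray] | None] = [None] * P

    for K in range(1, k_max + 1):
        restarts = 1 if K == 1 else n_restarts
        inits = _restart_inits(X, K, restarts, seed + K)
        Xrep = np.repeat(X, restarts, axis=0)
        out = _vb_gmm_batch(Xrep, prior, K, inits, tol, max_iter)
        elbo = out["elbo"].reshape(P, restarts)
        pick = elbo.argmax(axis=1)
        rows = np.arange(P) * restarts + pick
        elbo_K = elbo[np.arange(P), pick]
        m_K = out["m"][rows]
        sig_K = np.sqrt(out["b"][rows] / out["a"][rows])
        assign_K = out["resp"][rows].argmax(axis=2)
        improved = elbo_K > best_elbo + 1e-12  # strict: ties keep smaller K
        for i in np.flatnonzero(improved):
            best_params[i] = (m_K[i], sig_K[i], assign_K[i])
        best_elbo[improved] = elbo_K[improved]
        best_K[improved] = K

    gene_map = annotation.gene_map() if annotation is not None else pd.Series(dtype=str)
    models: dict[str, StateModel] = {}
    recs = []
    for i, pid in enumerate(probe_ids):
        m_i, sig_i, assign_i = best_params[i]
        model = _build_state_model(regions, m_i, sig_i, assign_i, c_merge)
        models[pid] = model
        gene = gene_map.get(pid, pid)
        recs.append((pid, gene, model.n_states, up_regions(model)))
    probes = pd.DataFrame(
        recs, columns=["probe_id", "gene", "n_states", "up_regions"]
    ).set_index("probe_id")
    return MultiStateTable(probes=probes, models=models, region_ids=regions)


# ---------------------------------------------------------------------------
# alpha0 tuning
# ---------------------------------------------------------------------------


def tune_alpha0(
    profile: RegionProfile,
    reference_true_set: Iterable[str],
    alpha_grid: Sequence[float],
    prior: GmmPrior,
    annotation: ProbeAnnotation | None = None,
    **classify_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Pick the Dirichlet concentration minimizing FPR + FNR on a reference.

    ``reference_true_set`` lists the probes regarded as truly multi-state
    (synthetic truth, or marker candidates at a chosen FDR).  Each grid
    value re-classifies the dataset; the full (alpha0, FPR, FNR) curve is
    returned alongside the argmin for plotting the trade-off.
    """
    alpha_grid = list(alpha_grid)
    truth = set(reference_true_set)
    if not alpha_grid:
        raise ValueError("alpha_grid is empty")
    if not truth:
        raise ValueError("reference_true_set is empty")
    all_probes = set(profile.probe_ids)
    positives = truth & all_probes
    negatives = all_probes - truth
    rows = []
    for alpha0 in alpha_grid:
        table = classify_dataset(
            profile, prior.with_alpha0(alpha0), annotation=annotation,
            **classify_kwargs,
        )
        called = set(table.multi_state_probes)
        fpr = len(called & negatives) / len(negatives) if negatives else 0.0
        fnr = len(positives - called) / len(positives) if positives else 0.0
        rows.append({"alpha0": alpha0, "fpr": fpr, "fnr": fnr, "sum": fpr + fnr})
    curve = pd.DataFrame(rows)
    best = int(curve["sum"].idxmin())
    return float(curve.loc[best, "alpha0"]), curve
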