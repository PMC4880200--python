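"""Univariate Gaussian-mixture modelling of fiber cross-sections.

Each cross-section of a bundle at one time-point yields a sample of metric
values (one per fiber).  Both time-points' samples are fitted independently
by maximum likelihood (EM), and a common component count is chosen by a
bi-objective rule: evaluate a model-fit score for each candidate n on both
time-points, keep the Pareto-nondominated counts, and select the smallest.

Fitting uses the raw sample values, not binned counts, so no bin width is
ever chosen.  The default per-time-point score is the negated BIC; the
``raw`` objective scores by in-sample log-likelihood instead, which is
(near-)monotone in n and therefore mainly useful for fidelity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "MixtureModel",
    "CrossSectionPair",
    "InsufficientSamplesError",
    "fit_gmm",
    "fit_gmm_nodes",
    "select_components",
    "select_components_nodes",
    "mixture_pdf",
    "mixture_cdf",
    "mixture_quantile",
]

#: lower bound on component variances (metric units squared); prevents EM
#: degeneracy on near-duplicate values
VARIANCE_FLOOR = 1e-6


class InsufficientSamplesError(ValueError):
    pass


@dataclass
class MixtureModel:
    """A fitted univariate Gaussian mixture."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    sample_count: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if not (len(self.weights) == len(self.means) == len(self.variances)):
            raise ValueError("weights, means, variances must share length")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if (self.variances < VARIANCE_FLOOR * (1 - 1e-12)).any():
            raise ValueError("variances below the variance floor")

    @property
    def n(self) -> int:
        return len(self.weights)


@dataclass
class CrossSectionPair:
    """The two time-points' metric samples at one cross-section (node)."""

    node_index: int
    values_ref: np.ndarray
    values_new: np.ndarray

    def __post_init__(self) -> None:
        self.values_ref = _clean(self.values_ref)
        self.values_new = _clean(self.values_new)
        if len(self.values_ref) == 0 or len(self.values_new) == 0:
            raise ValueError("both sample sets must be non-empty after "
                             "NaN filtering")


def _clean(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64).ravel()
    return values[~np.isnan(values)]


def _log_density(x: np.ndarray, weights: np.ndarray, means: np.ndarray,
                 variances: np.ndarray) -> np.ndarray:
    """Per-sample log density; parameter arrays may carry extra leading axes
    (e.g. one per EM restart) that broadcast against x[:, None, ...]."""
    comp = (-0.5 * np.log(2 * np.pi * variances)
            - 0.5 * (x[(...,) + (None,) * weights.ndim] - means) ** 2 / variances)
    return logsumexp(comp + np.log(weights), axis=-1)


def fit_gmm(values: np.ndarray, n: int, seed: int, restarts: int = 5,
            max_iter: int = 200, tol: float = 1e-6) -> MixtureModel:
    """EM fit of an n-component univariate Gaussian mixture.

    ``n=1`` uses the closed-form MLE (sample mean, biased sample variance).
    Otherwise EM runs from ``restarts`` random initialisations (component
    means drawn from the sample, weights uniform, variances at the sample
    variance) and the best final log-likelihood wins; its per-iteration
    log-likelihood trace is kept on the returned model.
    """
    x = _clean(values)
    m = len(x)
    if m < max(5 * n, 10):
        raise InsufficientSamplesError(
            f"insufficient samples for {n} components: have {m}, "
            f"need {max(5 * n, 10)}")
    if n == 1:
        mu = float(x.mean())
        var = max(float(x.var()), VARIANCE_FLOOR)
        ll = float(_log_density(x, np.ones(1), np.array([mu]),
                                np.array([var])).sum())
        return MixtureModel(np.ones(1), np.array([mu]), np.array([var]),
                            loglik=ll, sample_count=m,
                            loglik_trace=np.array([ll]))

    rng = np.random.default_rng(seed)
    R = restarts
    # init: means sampled from the data, jittered; shared variance
    means = rng.choice(x, size=(R, n), replace=True)
    means = means + rng.normal(0, max(x.std(), 1e-3) * 0.1, size=(R, n))
    variances = np.full((R, n), max(float(x.var()), VARIANCE_FLOOR))
    weights = np.full((R, n), 1.0 / n)

    traces = [[] for _ in range(R)]
    prev = np.full(R, -np.inf)
    active = np.ones(R, dtype=bool)
    for _ in range(max_iter):
        # E-step (all restarts at once): log responsibilities (m, R, n)
        comp = (-0.5 * np.log(2 * np.pi * variances)
                - 0.5 * (x[:, None, None] - means) ** 2 / variances
                + np.log(weights))
        norm = logsumexp(comp, axis=2, keepdims=True)
        resp = np.exp(comp - norm)
        ll = norm[:, :, 0].sum(axis=0)                       # (R,)
        for r in range(R):
            if active[r]:
                traces[r].append(ll[r])
        newly_done = active & (np.abs(ll - prev) < tol * m)
        active &= ~newly_done
        prev = ll
        if not active.any():
            break
        # M-step
        nk = resp.sum(axis=0)                                # (R, n)
        nk = np.maximum(nk, 1e-300)
        weights = nk / m
        means = (resp * x[:, None, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None, None] - means) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, VARIANCE_FLOOR)

    best = int(np.argmax(prev))
    return MixtureModel(weights[best], means[best], variances[best],
                        loglik=float(prev[best]), sample_count=m,
                        loglik_trace=np.asarray(traces[best]))


def fit_gmm_nodes(values: np.ndarray, n: int, seed: int, restarts: int = 5,
                  max_iter: int = 200, tol: float = 1e-6,
                  ) -> list[MixtureModel | None]:
    """Fit an n-component mixture to every column of an (m, C) sample matrix.

    One vectorised EM loop covers all C cross-sections and all restarts at
    once; NaN entries are masked out per column.  Columns with fewer than
    max(5n, 10) valid samples yield None.  Initialisation draws component
    means from N(column mean, column SD), so results are deterministic under
    ``seed`` but not bit-identical to per-column :func:`fit_gmm` calls
    (which initialise from the samples themselves).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("values must be (m, C)")
    valid = ~np.isnan(x)
    m_valid = valid.sum(axis=0)                               # (C,)
    fit_mask = m_valid >= max(5 * n, 10)
    out: list[MixtureModel | None] = [None] * x.shape[1]
    if not fit_mask.any():
        return out
    xs = np.where(valid, x, 0.0)[:, fit_mask]                 # (m, C')
    vmask = valid[:, fit_mask]
    mv = m_valid[fit_mask].astype(np.float64)                 # (C',)
    col_mean = xs.sum(axis=0) / mv
    col_var = ((xs - col_mean) ** 2 * vmask).sum(axis=0) / mv
    col_var = np.maximum(col_var, VARIANCE_FLOOR)

    if n == 1:
        cols = np.nonzero(fit_mask)[0]
        for k, c in enumerate(cols):
            ll = float(_log_density(xs[vmask[:, k], k], np.ones(1),
                                    col_mean[k:k + 1],
                                    col_var[k:k + 1]).sum())
            out[c] = MixtureModel(np.ones(1), col_mean[k:k + 1].copy(),
                                  col_var[k:k + 1].copy(), loglik=ll,
                                  sample_count=int(mv[k]),
                                  loglik_trace=np.array([ll]))
        return out

    rng = np.random.default_rng(seed)
    C, R = int(fit_mask.sum()), restarts
    sd = np.sqrt(col_var)
    means = (col_mean[:, None, None]
             + sd[:, None, None] * rng.standard_normal((C, R, n)))
    variances = np.broadcast_to(col_var[:, None, None], (C, R, n)).copy()
    weights = np.full((C, R, n), 1.0 / n)
    xb = xs.T[:, None, None, :]                               # (C,1,1,m)
    mb = vmask.T[:, None, None, :]
    prev = np.full((C, R), -np.inf)
    for _ in range(max_iter):
        comp = (-0.5 * np.log(2 * np.pi * variances[..., None])
                - 0.5 * (xb - means[..., None]) ** 2 / variances[..., None]
                + np.log(weights[..., None]))                 # (C,R,n,m)
        norm = logsumexp(comp, axis=2)                        # (C,R,m)
        ll = (norm * mb[:, :, 0, :]).sum(axis=2)              # (C,R)
        if np.all(np.abs(ll - prev) < tol * mv[:, None]):
            prev = ll
            break
        prev = ll
        resp = np.exp(comp - norm[:, :, None, :]) * mb        # (C,R,n,m)
        nk = np.maximum(resp.sum(axis=3), 1e-300)             # (C,R,n)
        weights = nk / mv[:, None, None]
        means = (resp * xb).sum(axis=3) / nk
        ex2 = (resp * xb ** 2).sum(axis=3) / nk
        variances = np.maximum(ex2 - means ** 2, VARIANCE_FLOOR)
    best = np.argmax(prev, axis=1)                            # (C,)
    cols = np.nonzero(fit_mask)[0]
    for k, c in enumerate(cols):
        r = best[k]
        w = weights[k, r]
        out[c] = MixtureModel(w / w.sum(), means[k, r].copy(),
                              variances[k, r].copy(),
                              loglik=float(prev[k, r]),
                              sample_count=int(mv[k]))
    return out


def _pareto_nondominated(points: np.ndarray) -> np.ndarray:
    """Indices of maximization-nondominated rows of an (n, 2) array."""
    keep = []
    for i, p in enumerate(points):
        dominated = any(
            (q[0] >= p[0] and q[1] >= p[1]) and (q[0] > p[0] or q[1] > p[1])
            for j, q in enumerate(points) if j != i)
        if not dominated:
            keep.append(i)
    return np.asarray(keep)


def select_components(pair: CrossSectionPair, n_max: int = 5, seed: int = 0,
                      objective: str = "bic", restarts: int = 5,
                      ) -> tuple[int, MixtureModel, MixtureModel]:
    """Choose a common component count for the two time-points' samples.

    For each n in 1..n_max (capped so both samples satisfy the 5n-sample
    rule), both samples are fitted and scored.  The component counts whose
    score pairs are Pareto-nondominated (both objectives maximized) are
    computed by exhaustive enumeration — exact on this one-integer search
    space.

    objective='bic' (default): score = -BIC = 2*loglik - (3n-1)*log(m);
    the selected n maximizes the combined (ref + new) score — always a
    member of the Pareto front — with ties broken toward the smaller n.
    A smallest-front-member rule would be blind to one-sided multimodality:
    whenever the reference is unimodal, n = 1 sits on the front regardless
    of the follow-up's shape.

    objective='raw': score = in-sample log-likelihood and the smallest
    member of the front is selected (literal bi-objective formulation;
    near-monotone in n, mainly for fidelity experiments).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if objective not in ("bic", "raw"):
        raise ValueError(f"unknown objective {objective!r}")
    m_min = min(len(pair.values_ref), len(pair.values_new))
    n_hi = max(1, min(n_max, m_min // 5))
    candidates = list(range(1, n_hi + 1))
    fits: list[tuple[MixtureModel, MixtureModel]] = []
    scores = np.empty((len(candidates), 2))
    for row, n in enumerate(candidates):
        mr = fit_gmm(pair.values_ref, n, seed=seed, restarts=restarts)
        mn = fit_gmm(pair.values_new, n, seed=seed + 1, restarts=restarts)
        fits.append((mr, mn))
        if objective == "bic":
            scores[row] = [_neg_bic(mr), _neg_bic(mn)]
        else:
            scores[row] = [mr.loglik, mn.loglik]
    front = _pareto_nondominated(scores)
    best_row = _select_from_front(scores, front, objective)
    n_star = candidates[best_row]
    return n_star, fits[best_row][0], fits[best_row][1]


def _select_from_front(scores: np.ndarray, front: np.ndarray,
                       objective: str) -> int:
    if objective == "raw":
        return int(front.min())
    totals = scores[front].sum(axis=1)
    return int(front[np.argmax(totals)])


def select_components_nodes(values_ref: np.ndarray, values_new: np.ndarray,
                            n_max: int = 5, seed: int = 0,
                            objective: str = "bic", restarts: int = 5,
                            ref_fits: dict[int, list[MixtureModel | None]]
                            | None = None,
                            ) -> tuple[np.ndarray,
                                       list[MixtureModel | None],
                                       list[MixtureModel | None]]:
    """Batched :func:`select_components` over all C cross-sections at once.

    ``values_ref`` and ``values_new`` are (m, C) matrices.  Returns the
    selected component count per node (0 where either sample set is too
    small) and the two fitted models per node.  ``ref_fits`` may carry
    reference-side fits from a previous call on the same reference samples
    (e.g. when replaying many follow-ups against one baseline); it is
    filled in place.
    """
    if objective not in ("bic", "raw"):
        raise ValueError(f"unknown objective {objective!r}")
    C = values_ref.shape[1]
    if values_new.shape[1] != C:
        raise ValueError("ref and new must share the node count")
    if ref_fits is None:
        ref_fits = {}
    fits_ref: dict[int, list[MixtureModel | None]] = ref_fits
    fits_new: dict[int, list[MixtureModel | None]] = {}
    for n in range(1, n_max + 1):
        if n not in fits_ref:
            fits_ref[n] = fit_gmm_nodes(values_ref, n, seed=seed + 2 * n,
                                        restarts=restarts)
        fits_new[n] = fit_gmm_nodes(values_new, n, seed=seed + 2 * n + 1,
                                    restarts=restarts)
    score = _neg_bic if objective == "bic" else (lambda mdl: mdl.loglik)
    n_star = np.zeros(C, dtype=int)
    out_ref: list[MixtureModel | None] = [None] * C
    out_new: list[MixtureModel | None] = [None] * C
    for i in range(C):
        cand = [n for n in range(1, n_max + 1)
                if fits_ref[n][i] is not None and fits_new[n][i] is not None]
        if not cand:
            continue
        pts = np.array([[score(fits_ref[n][i]), score(fits_new[n][i])]
                        for n in cand])
        front = _pareto_nondominated(pts)
        n_sel = cand[_select_from_front(pts, front, objective)]
        n_star[i] = n_sel
        out_ref[i] = fits_ref[n_sel][i]
        out_new[i] = fits_new[n_sel][i]
    return n_star, out_ref, out_new


def _neg_bic(model: MixtureModel) -> float:
    n_params = 3 * model.n - 1
    return 2.0 * model.loglik - n_params * np.log(model.sample_count)


def mixture_pdf(model: MixtureModel, x: np.ndarray | float) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    sd = np.sqrt(model.variances)
    return (model.weights * stats.norm.pdf(x[..., None], model.means, sd)
            ).sum(axis=-1)


def mixture_cdf(model: MixtureModel, x: np.ndarray | float) -> np.ndarray:
    """P(X <= x) under the mixture: sum_j w_j * Phi((x - mu_j) / sigma_j)."""
    x = np.asarray(x, dtype=np.float64)
    sd = np.sqrt(model.variances)
    return (model.weights * stats.norm.cdf(x[..., None], model.means, sd)
            ).sum(axis=-1)


def mixture_quantile(model: MixtureModel, q: float, xtol: float = 1e-12
                     ) -> float:
    """Inverse CDF by bracketed root finding (CDF is strictly increasing)."""
    if not 0.0 < q < 1.0:
        raise ValueError("quantile level must be in (0, 1)")
    sd = np.sqrt(model.variances)
    lo = float((model.means - 10 * sd).min())
    hi = float((model.means + 10 * sd).max())
    while mixture_cdf(model, lo) > q:
        lo -= (hi - lo)
    while mixture_cdf(model, hi) < q:
        hi += (hi - lo)
    return float(brentq(lambda v: mixture_cdf(model, v) - q, lo, hi,
                        xtol=xtol))
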