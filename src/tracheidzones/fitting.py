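"""Estimation of the 13 mixture parameters from indexed slope angles.

The pipeline mirrors a spreadsheet-solver-class workflow: a binned
least-squares fit on a 1.5-degree histogram provides a good starting
point, and maximum-likelihood refinement on the raw angles polishes it.
Both stages use a derivative-free simplex search on an unconstrained
13-vector; constraints (shapes > 1, ordered supports inside [0, 90]
degrees, amplitudes on the open simplex, generalized-normal shape >= 2)
are enforced through smooth parameter transforms.

Model adequacy is assessed with Pearson's chi-squared test on 50
equal-width bins over the observed range, merging bins with fewer than
``min_count`` observations inward from the two outskirts; degrees of
freedom are m - 13 - 1 for m final bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .distributions import (
    BetaZoneParams,
    GenNormParams,
    MixtureModel,
    mixture_cdf,
    mixture_pdf,
)
from .measurements import BinnedHistogram, bin_histogram

__all__ = [
    "FitResult",
    "ChiSquareResult",
    "initialize_parameters",
    "fit_least_squares",
    "fit_mle",
    "fit_min_chi2",
    "fit_pipeline",
    "chi_squared_test",
    "log_likelihood",
]

N_PARAMS = 13
_EPS = 1e-9


class ChiSquareResult(NamedTuple):
    chi2: float
    dof: int
    p_value: float
    n_bins_final: int


@dataclass
class FitResult:
    """A fitted mixture with goodness-of-fit and convergence diagnostics."""

    model: MixtureModel
    method: str  # "binned-LS" | "MLE" | "LS-then-MLE"
    objective: float
    converged: bool
    n_evaluations: int
    objective_trace: list[float] = field(default_factory=list, repr=False)
    chi2: float | None = None
    dof: int | None = None
    p_value: float | None = None
    n_bins_final: int | None = None

    @property
    def adequate(self) -> bool | None:
        """Model fits the data adequately iff the chi-squared p-value > 0.05."""
        return None if self.p_value is None else bool(self.p_value > 0.05)


# ---------------------------------------------------------------------------
# parameter transforms: R^13 <-> constrained model space

def _sigmoid(t):
    return 1.0 / (1.0 + np.exp(-t))


def _logit(u):
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return np.log(u / (1 - u))


def _beta_from_vec(t4) -> BetaZoneParams:
    al = 1.0 + np.exp(np.clip(t4[0], -30, 30))
    be = 1.0 + np.exp(np.clip(t4[1], -30, 30))
    a = 90.0 * _sigmoid(t4[2])
    b = a + (90.0 - a) * _sigmoid(t4[3])
    return BetaZoneParams(al, be, a, b)


def _beta_to_vec(p: BetaZoneParams) -> list[float]:
    a = np.clip(p.a, 1e-6, 89.999)
    b = np.clip(p.b, a + 1e-6, 89.9999)
    return [
        np.log(max(p.alpha - 1, 1e-9)),
        np.log(max(p.beta - 1, 1e-9)),
        _logit(a / 90.0),
        _logit((b - a) / (90.0 - a)),
    ]


def model_to_vector(m: MixtureModel) -> np.ndarray:
    tw = m.tw
    return np.array(
        [np.log(m.A_EW / m.A_TW), np.log(m.A_LW / m.A_TW)]
        + _beta_to_vec(m.ew)
        + _beta_to_vec(m.lw)
        + [tw.mu, np.log(tw.alpha_scale), _logit(np.clip((tw.beta_shape - 2.0) / 48.0, 1e-9, 1 - 1e-9))]
    )


def vector_to_model(t: Sequence[float]) -> MixtureModel:
    t = np.asarray(t, dtype=float)
    e0, e1 = np.exp(np.clip(t[0], -30, 30)), np.exp(np.clip(t[1], -30, 30))
    z = e0 + e1 + 1.0
    return MixtureModel(
        A_EW=e0 / z,
        A_LW=e1 / z,
        ew=_beta_from_vec(t[2:6]),
        lw=_beta_from_vec(t[6:10]),
        tw=GenNormParams(
            mu=t[10],
            alpha_scale=np.exp(np.clip(t[11], -30, 30)),
            # shape capped at 50: the density is numerically uniform beyond,
            # and an unbounded plateau can swallow neighboring zones
            beta_shape=2.0 + 48.0 * _sigmoid(t[12]),
        ),
    )


# ---------------------------------------------------------------------------
# initialization

def initialize_parameters(hist: BinnedHistogram) -> MixtureModel:
    """Heuristic deterministic start from a slope-angle histogram.

    Earlywood sits at the left end of the angle axis and latewood at the
    right, so the leftmost and rightmost prominent local maxima (at least
    30% of the global peak, well separated) seed the EW and LW modes;
    each side's moments (split at the density minimum between the peaks)
    moment-match the beta shapes; the transition-wood component starts
    midway with shape 4.  A unimodal histogram falls back to a
    quantile-based split.
    """
    if hist.lower_edges.size < 3:
        raise ValueError("need at least 3 bins to initialize")
    dens = hist.densities
    centers = hist.centers
    n = dens.size

    peaks = [i for i in range(n) if _is_local_max(dens, i) and dens[i] >= 0.3 * dens.max()]
    sep = max(3, int(round(5.0 / hist.width)))  # >= ~5 degrees apart
    second = None
    if peaks:
        lead, second = peaks[0], peaks[-1]
        if second - lead < sep:
            lead = int(np.argmax(dens))
            second = None

    if second is None:
        # unimodal: quantile-based split
        cum = np.cumsum(dens)
        i_lo = int(np.searchsorted(cum, 1 / 3))
        i_hi = int(np.searchsorted(cum, 2 / 3))
        i_ew, i_lw = min(i_lo, n - 2), max(i_hi, 1)
        if i_ew >= i_lw:
            i_ew, i_lw = 0, n - 1
        valley = (i_ew + i_lw) // 2
    else:
        i_ew, i_lw = sorted((lead, second))
        valley = i_ew + int(np.argmin(dens[i_ew : i_lw + 1]))

    split = centers[valley]
    ew = _peak_beta(centers, dens, i_ew, hist.width)
    lw = _peak_beta(centers, dens, i_lw, hist.width)
    mass_left = float(dens[centers <= split].sum())
    tw_share = 0.2
    a_ew = max(0.05, min(0.9, (1 - tw_share) * mass_left))
    a_lw = max(0.05, min(0.9, (1 - tw_share) * (1 - mass_left)))
    mu_tw = 0.5 * (centers[i_ew] + centers[i_lw])
    scale_tw = max(2.0, 0.25 * (centers[i_lw] - centers[i_ew]))
    return MixtureModel(
        A_EW=a_ew,
        A_LW=a_lw,
        ew=ew,
        lw=lw,
        tw=GenNormParams(mu=mu_tw, alpha_scale=scale_tw, beta_shape=4.0),
    )


def _is_local_max(d: np.ndarray, i: int) -> bool:
    left = d[i - 1] if i > 0 else -np.inf
    right = d[i + 1] if i < d.size - 1 else -np.inf
    return d[i] > left and d[i] >= right and d[i] > 0


def _peak_beta(centers, dens, i_peak, width) -> BetaZoneParams:
    """Seed a beta component from one histogram peak: the spread comes
    from the peak's half-width (robust to mass from neighboring zones),
    the support is mode +- 6 sd, and the shapes are mildly symmetric."""
    mode = centers[i_peak]
    half = 0.5 * dens[i_peak]
    lo = i_peak
    while lo > 0 and dens[lo - 1] >= half:
        lo -= 1
    hi = i_peak
    while hi < dens.size - 1 and dens[hi + 1] >= half:
        hi += 1
    fwhm = max((hi - lo + 1) * width, width)
    sd = fwhm / 2.355  # gaussian-equivalent spread
    a = max(0.5, mode - 6 * sd)
    b = min(89.5, mode + 6 * sd)
    # symmetric-ish shapes whose mode lands on the peak
    frac = np.clip((mode - a) / (b - a), 0.1, 0.9)
    s = 8.0  # alpha + beta - 2: moderately peaked start
    return BetaZoneParams(alpha=1 + s * frac, beta=1 + s * (1 - frac), a=a, b=b)


# ---------------------------------------------------------------------------
# objectives

def _support_variant(model: MixtureModel, scale: float, tw_shrink: float) -> MixtureModel:
    """Rebuild the heuristic start with beta supports at mode +- scale*sd
    and the transition-wood scale shrunk; the default +-6 sd start is
    deliberately wide, and tighter variants escape flat basins when the
    components are well separated."""

    def shrink(p: BetaZoneParams) -> BetaZoneParams:
        from .distributions import beta4_stats

        st = beta4_stats(p)
        a = max(0.5, st["mode"] - scale * st["sigma"])
        b = min(89.5, st["mode"] + scale * st["sigma"])
        frac = np.clip((st["mode"] - a) / (b - a), 0.1, 0.9)
        return BetaZoneParams(1 + 8 * frac, 1 + 8 * (1 - frac), a, b)

    tw = model.tw
    return MixtureModel(
        model.A_EW, model.A_LW, shrink(model.ew), shrink(model.lw),
        GenNormParams(tw.mu, tw.alpha_scale * tw_shrink, 4.0),
    )


def initial_starts(hist: BinnedHistogram) -> list[MixtureModel]:
    """Deterministic family of starting points for the binned-LS stage."""
    base = initialize_parameters(hist)
    return [base, _support_variant(base, 4.0, 0.5), _support_variant(base, 2.5, 0.5)]


def _bin_probabilities(model: MixtureModel, lower: np.ndarray, width: float) -> np.ndarray:
    edges = np.append(lower, lower[-1] + width)
    c = mixture_cdf(edges, model)
    return np.diff(c)


def log_likelihood(values: Sequence[float], model: MixtureModel) -> float:
    """Sum of log mixture densities over the observations."""
    dens = mixture_pdf(np.asarray(values, dtype=float), model)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def _simplex_minimize(fun, x0, max_evals: int, tol: float):
    """Nelder-Mead restarted from the incumbent until it stops improving.

    Restarting rebuilds the simplex at full size around the incumbent,
    which lets the search escape the collapsed-simplex stalls that a
    single 13-dimensional run is prone to."""
    trace: list[float] = []
    total = 0
    x = np.asarray(x0, dtype=float)
    best = np.inf
    success = False
    for _ in range(8):
        res = optimize.minimize(
            fun,
            x,
            method="Nelder-Mead",
            options={
                "maxfev": max(1, max_evals - total),
                "fatol": tol,
                "xatol": 1e-6,
                "adaptive": True,
            },
        )
        total += res.nfev
        trace.append(float(res.fun))
        x, success = res.x, bool(res.success)
        improved = res.fun < best - max(tol, 1e-12)
        best = min(best, float(res.fun))
        if total >= max_evals or (success and not improved):
            break
    return x, best, success, total, trace


def fit_least_squares(
    hist: BinnedHistogram,
    init: MixtureModel | None = None,
    *,
    max_evals: int = 40_000,
    tol: float = 1e-10,
) -> FitResult:
    """Binned least squares: minimize sum over bins of
    (observed bin density - model bin probability)^2."""
    if init is None:
        init = initialize_parameters(hist)
    obs = hist.densities
    lower, width = hist.lower_edges, hist.width

    def objective(t):
        try:
            m = vector_to_model(t)
        except (ValueError, FloatingPointError):
            return 1e6
        p = _bin_probabilities(m, lower, width)
        return float(np.sum((obs - p) ** 2))

    x, fun, ok, nev, trace = _simplex_minimize(objective, model_to_vector(init), max_evals, tol)
    return FitResult(
        model=vector_to_model(x),
        method="binned-LS",
        objective=fun,
        converged=ok,
        n_evaluations=nev,
        objective_trace=trace,
    )


def _ensure_support_coverage(values: np.ndarray, model: MixtureModel) -> MixtureModel:
    """Widen beta supports to the data range when observations fall outside
    both supports and carry negligible transition-wood density (avoids
    -inf log-likelihoods, a known finite-support pathology)."""
    dens = mixture_pdf(values, model)
    if np.all(dens > 0):
        return model
    lo = float(values.min()) - 1e-6
    hi = float(values.max()) + 1e-6
    def widen(p: BetaZoneParams) -> BetaZoneParams:
        return BetaZoneParams(p.alpha, p.beta, min(p.a, max(lo, 0.0)), max(p.b, min(hi, 90.0)))
    model = MixtureModel(model.A_EW, model.A_LW, widen(model.ew), widen(model.lw), model.tw)
    dens = mixture_pdf(values, model)
    if np.any(dens <= 0):
        bad = values[np.argmin(dens)]
        raise ValueError(f"observation {bad:.4g} has zero density even after support expansion")
    return model


def fit_mle(
    values: Sequence[float],
    init: MixtureModel,
    *,
    max_evals: int = 10_000,
    tol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood refinement on raw slope angles (degrees)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no observations")
    init = _ensure_support_coverage(v, init)
    scale = v.size  # work with mean NLL for a size-free tolerance

    def objective(t):
        try:
            m = vector_to_model(t)
        except (ValueError, FloatingPointError):
            return 1e6
        return -log_likelihood(v, m) / scale

    x, fun, ok, nev, trace = _simplex_minimize(objective, model_to_vector(init), max_evals, tol)
    # the simplex can stall uphill in pathological corners; never return
    # a model worse than the start
    if objective(model_to_vector(init)) < fun:
        x = model_to_vector(init)
        fun = objective(x)
    return FitResult(
        model=vector_to_model(x),
        method="MLE",
        objective=float(fun * scale),
        converged=ok,
        n_evaluations=nev,
        objective_trace=trace,
    )


def _merge_outskirts(obs: np.ndarray, exp: np.ndarray, min_count: int):
    """Merge bins with fewer than ``min_count`` observations inward from
    the two outskirts of the distribution."""
    obs_l, exp_l = list(np.asarray(obs, dtype=float)), list(np.asarray(exp, dtype=float))
    while len(obs_l) > 1 and obs_l[0] < min_count:
        obs_l[1] += obs_l[0]
        exp_l[1] += exp_l[0]
        del obs_l[0], exp_l[0]
    while len(obs_l) > 1 and obs_l[-1] < min_count:
        obs_l[-2] += obs_l[-1]
        exp_l[-2] += exp_l[-1]
        del obs_l[-1], exp_l[-1]
    return np.array(obs_l), np.array(exp_l)


def fit_min_chi2(
    values: Sequence[float],
    init: MixtureModel,
    *,
    n_bins: int = 50,
    min_count: int = 5,
    max_evals: int = 10_000,
    tol: float = 1e-6,
) -> FitResult:
    """Minimum-chi-square estimation: minimize the Pearson statistic of
    :func:`chi_squared_test` itself over the 13 parameters.

    When the statistic used for the adequacy test is also the fitting
    objective, the fitted statistic follows the chi-squared law with
    m - 13 - 1 degrees of freedom asymptotically, which makes this the
    estimator of choice for calibration studies of the test.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no observations")
    edges = np.linspace(v.min(), v.max(), n_bins + 1)
    obs, _ = np.histogram(v, bins=edges)

    def objective(t):
        try:
            m = vector_to_model(t)
        except (ValueError, FloatingPointError):
            return 1e9
        exp = np.diff(mixture_cdf(edges, m)) * v.size
        o, e = _merge_outskirts(obs, exp, min_count)
        return float(np.sum((o - np.maximum(e, 1e-12)) ** 2 / np.maximum(e, 1e-12)))

    x, fun, ok, nev, trace = _simplex_minimize(objective, model_to_vector(init), max_evals, tol)
    if objective(model_to_vector(init)) < fun:
        x = model_to_vector(init)
        fun = objective(x)
    result = FitResult(
        model=vector_to_model(x),
        method="min-chi2",
        objective=float(fun),
        converged=ok,
        n_evaluations=nev,
        objective_trace=trace,
    )
    chi = chi_squared_test(v, result.model, n_bins=n_bins, min_count=min_count)
    result.chi2, result.dof = chi.chi2, chi.dof
    result.p_value, result.n_bins_final = chi.p_value, chi.n_bins_final
    return result


def chi_squared_test(
    values: Sequence[float],
    model: MixtureModel,
    n_bins: int = 50,
    min_count: int = 5,
) -> ChiSquareResult:
    """Pearson chi-squared adequacy test on binned slope angles.

    Equal-width bins over the observed range; bins with fewer than
    ``min_count`` observations are merged inward from each outskirt.
    Expected counts come from the model cdf.  dof = m - 13 - 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no observations")
    edges = np.linspace(v.min(), v.max(), n_bins + 1)
    obs, edges = np.histogram(v, bins=edges)
    cdf = mixture_cdf(edges, model)
    exp = np.diff(cdf) * v.size
    o, e = _merge_outskirts(obs, exp, min_count)

    m = o.size
    dof = m - N_PARAMS - 1
    if dof < 1:
        raise ValueError(
            f"only {m} bins remain after merging; dof = {dof} < 1 — use fewer parameters or fewer/wider bins"
        )
    e = np.maximum(e, 1e-12)
    chi2 = float(np.sum((o - e) ** 2 / e))
    p = float(stats.chi2.sf(chi2, dof))
    return ChiSquareResult(chi2=chi2, dof=dof, p_value=p, n_bins_final=m)


def fit_pipeline(
    values: Sequence[float],
    *,
    bin_width: float = 1.5,
    method: str = "ls+mle",
    init: MixtureModel | None = None,
    max_evals: int = 10_000,
    chi2_bins: int = 50,
    chi2_min_count: int = 5,
) -> FitResult:
    """Full estimation workflow on raw indexed slope angles (degrees):
    histogram (1.5 degrees) -> heuristic init -> binned LS -> optional MLE
    refinement -> chi-squared adequacy test."""
    if method not in {"ls+mle", "ls-only", "mle-only"}:
        raise ValueError(f"unknown method {method!r}")
    v = np.asarray(values, dtype=float)
    hist = bin_histogram(v, width=bin_width)
    starts = [init] if init is not None else initial_starts(hist)

    if method == "mle-only":
        result = min(
            (fit_mle(v, s, max_evals=max_evals) for s in starts),
            key=lambda r: r.objective,
        )
    else:
        ls = min(
            (fit_least_squares(hist, s, max_evals=max_evals) for s in starts),
            key=lambda r: r.objective,
        )
        if method == "ls-only":
            result = ls
        else:
            result = fit_mle(v, ls.model, max_evals=max_evals)
            result.method = "LS-then-MLE"
            result.objective_trace = ls.objective_trace + result.objective_trace

    chi = chi_squared_test(v, result.model, n_bins=chi2_bins, min_count=chi2_min_count)
    result.chi2, result.dof = chi.chi2, chi.dof
    result.p_value, result.n_bins_final = chi.p_value, chi.n_bins_final
    return result
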