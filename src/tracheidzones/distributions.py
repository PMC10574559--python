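"""Zone component densities and the 13-parameter mixture model.

Earlywood (EW) and latewood (LW) tracheid slope angles are each modeled by
a four-parameter beta distribution on a finite support (a, b) with shape
parameters alpha, beta > 1 (unimodal, possibly skewed).  Transition wood
(TW) is modeled by a generalized normal (exponential-power) distribution,
which interpolates between the normal law (shape 2) and a uniform shift on
(mu - alpha, mu + alpha) as the shape grows — the signature of a gradual
drift of cell proportions superposed on normal noise.

The ring-level model is the convex mixture

    f(phi) = A_EW * beta4(phi; EW) + A_TW * gennorm(phi; TW) + A_LW * beta4(phi; LW)

with A_TW = 1 - A_EW - A_LW, for 13 free parameters in total
(2 amplitudes + 2 x 4 beta + 3 generalized-normal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
from scipy import special, stats

__all__ = [
    "BetaZoneParams",
    "GenNormParams",
    "MixtureModel",
    "beta4_pdf",
    "beta4_cdf",
    "beta4_stats",
    "beta4_from_stats",
    "gennorm_pdf",
    "gennorm_cdf",
    "gennorm_stats",
    "mixture_pdf",
    "mixture_cdf",
    "mixture_ppf",
]


@dataclass(frozen=True)
class BetaZoneParams:
    """Four-parameter beta: shapes alpha, beta > 1; support (a, b) in degrees."""

    alpha: float
    beta: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.alpha > 1 and self.beta > 1):
            raise ValueError(f"shape parameters must exceed 1 for a unimodal curve, got {self}")
        if not self.a < self.b:
            raise ValueError(f"support requires a < b, got a={self.a}, b={self.b}")

    @property
    def frozen(self) -> stats.rv_continuous:
        return stats.beta(self.alpha, self.beta, loc=self.a, scale=self.b - self.a)


@dataclass(frozen=True)
class GenNormParams:
    """Generalized normal: center mu, scale alpha > 0, shape beta >= 2.

    Shape 2 is the normal limit (std = alpha/sqrt(2)); large shapes tend to
    the uniform distribution on (mu - alpha, mu + alpha).
    """

    mu: float
    alpha_scale: float
    beta_shape: float

    def __post_init__(self) -> None:
        if not self.alpha_scale > 0:
            raise ValueError(f"scale must be positive, got {self.alpha_scale}")
        if not self.beta_shape >= 2:
            raise ValueError(f"shape must be >= 2 (normal limit), got {self.beta_shape}")

    @property
    def frozen(self) -> stats.rv_continuous:
        return stats.gennorm(self.beta_shape, loc=self.mu, scale=self.alpha_scale)


@dataclass(frozen=True)
class MixtureModel:
    """EW/TW/LW mixture over slope angles; amplitudes on the open simplex."""

    A_EW: float
    A_LW: float
    ew: BetaZoneParams
    lw: BetaZoneParams
    tw: GenNormParams

    def __post_init__(self) -> None:
        if not (0 < self.A_EW < 1 and 0 < self.A_LW < 1 and self.A_EW + self.A_LW < 1):
            raise ValueError(
                f"amplitudes must lie in the open simplex: A_EW={self.A_EW}, A_LW={self.A_LW}"
            )

    @property
    def A_TW(self) -> float:
        return 1.0 - self.A_EW - self.A_LW

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        """(A_EW, A_TW, A_LW)."""
        return self.A_EW, self.A_TW, self.A_LW

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "A_EW": self.A_EW,
            "A_LW": self.A_LW,
            "ew": asdict(self.ew),
            "lw": asdict(self.lw),
            "tw": asdict(self.tw),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MixtureModel":
        return cls(
            A_EW=float(d["A_EW"]),
            A_LW=float(d["A_LW"]),
            ew=BetaZoneParams(**d["ew"]),
            lw=BetaZoneParams(**d["lw"]),
            tw=GenNormParams(**d["tw"]),
        )

    def save(self, path: str | Path, metadata: dict[str, Any] | None = None) -> None:
        doc = {"model": self.to_dict()}
        if metadata:
            doc["metadata"] = metadata
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MixtureModel":
        doc = json.loads(Path(path).read_text())
        return cls.from_dict(doc["model"] if "model" in doc else doc)


# ---------------------------------------------------------------------------
# densities and closed-form statistics

def beta4_pdf(x, p: BetaZoneParams):
    """Density of the four-parameter beta; zero outside (a, b):

    f(x) = (x-a)^(alpha-1) (b-x)^(beta-1) / [B(alpha, beta) (b-a)^(alpha+beta-1)]
    """
    x = np.asarray(x, dtype=float)
    al, be, a, b = p.alpha, p.beta, p.a, p.b
    inside = (x > a) & (x < b)
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = (
            (al - 1) * np.log(x - a)
            + (be - 1) * np.log(b - x)
            - special.betaln(al, be)
            - (al + be - 1) * np.log(b - a)
        )
        out = np.where(inside, np.exp(logf), 0.0)
    return out if out.ndim else float(out)


def beta4_cdf(x, p: BetaZoneParams):
    x = np.asarray(x, dtype=float)
    z = np.clip((x - p.a) / (p.b - p.a), 0.0, 1.0)
    out = special.betainc(p.alpha, p.beta, z)
    return out if out.ndim else float(out)


def beta4_stats(p: BetaZoneParams) -> dict[str, float]:
    """Closed-form mean, mode, approximate median, and sigma.

    mean   = a + (b-a) * alpha/(alpha+beta)
    mode   = a + (b-a) * (alpha-1)/(alpha+beta-2)
    median ~ a + (b-a) * (alpha-1/3)/(alpha+beta-2/3)   (standard approximation)
    sigma  = (b-a) * sqrt(alpha*beta / ((alpha+beta)^2 (alpha+beta+1)))

    ``median_exact`` is the numeric root of cdf = 1/2; zone reports print
    the approximation.
    """
    al, be, a, b = p.alpha, p.beta, p.a, p.b
    rng = b - a
    s = al + be
    return {
        "mean": a + rng * al / s,
        "mode": a + rng * (al - 1) / (s - 2),
        "median": a + rng * (al - 1 / 3) / (s - 2 / 3),
        "median_exact": a + rng * float(special.betaincinv(al, be, 0.5)),
        "sigma": rng * np.sqrt(al * be / (s ** 2 * (s + 1))),
    }


def beta4_from_stats(
    mean: float, median: float, mode: float, sigma: float
) -> BetaZoneParams:
    """Recover (alpha, beta, a, b) from the four closed-form statistics.

    Solves the system {mean, mode, median-approximation, sigma} for the
    four parameters by least squares; useful for reconstructing a model
    from a published table of per-zone statistics.
    """
    from scipy.optimize import least_squares

    def unpack(t):
        al = 1.0 + np.exp(t[0])
        be = 1.0 + np.exp(t[1])
        a = t[2]
        b = a + np.exp(t[3])
        return BetaZoneParams(al, be, a, b)

    def resid(t):
        st = beta4_stats(unpack(t))
        return [
            st["mean"] - mean,
            st["mode"] - mode,
            st["median"] - median,
            st["sigma"] - sigma,
        ]

    skew = mean - mode  # rough asymmetry scale to seed the solver
    x0 = [np.log(3.0), np.log(3.0), mean - 5 * sigma - skew, np.log(10 * sigma)]
    sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14)
    p = unpack(sol.x)
    if not np.allclose(resid(sol.x), 0, atol=1e-4):
        raise ValueError(
            f"no four-parameter beta matches mean={mean}, median={median}, "
            f"mode={mode}, sigma={sigma} (residual {resid(sol.x)})"
        )
    return p


def gennorm_pdf(x, p: GenNormParams):
    """Generalized normal density beta/(2 alpha Gamma(1/beta)) exp(-(|x-mu|/alpha)^beta)."""
    x = np.asarray(x, dtype=float)
    be, al = p.beta_shape, p.alpha_scale
    with np.errstate(over="ignore"):  # far tails overflow the power, exp -> 0
        out = be / (2.0 * al) * np.exp(
            -np.abs((x - p.mu) / al) ** be - special.gammaln(1.0 / be)
        )
    return out if out.ndim else float(out)


def gennorm_cdf(x, p: GenNormParams):
    """Distribution function via the regularized lower incomplete gamma."""
    x = np.asarray(x, dtype=float)
    be, al = p.beta_shape, p.alpha_scale
    with np.errstate(over="ignore"):
        z = np.abs((x - p.mu) / al) ** be
        out = 0.5 + 0.5 * np.sign(x - p.mu) * special.gammainc(1.0 / be, z)
    return out if out.ndim else float(out)


def gennorm_stats(p: GenNormParams) -> dict[str, float]:
    """mean = median = mode = mu; sigma = alpha*sqrt(Gamma(3/beta)/Gamma(1/beta))."""
    from scipy.special import gammaln

    sigma = p.alpha_scale * np.exp(0.5 * (gammaln(3.0 / p.beta_shape) - gammaln(1.0 / p.beta_shape)))
    return {"mean": p.mu, "median": p.mu, "mode": p.mu, "sigma": float(sigma)}


def mixture_pdf(x, m: MixtureModel):
    """Mixture density A_EW*f_EW + A_TW*f_TW + A_LW*f_LW (per degree)."""
    return (
        m.A_EW * beta4_pdf(x, m.ew)
        + m.A_TW * gennorm_pdf(x, m.tw)
        + m.A_LW * beta4_pdf(x, m.lw)
    )


def mixture_cdf(x, m: MixtureModel):
    """Mixture distribution function from closed-form component cdfs."""
    return (
        m.A_EW * beta4_cdf(x, m.ew)
        + m.A_TW * gennorm_cdf(x, m.tw)
        + m.A_LW * beta4_cdf(x, m.lw)
    )


def mixture_ppf(q: float, m: MixtureModel, tol: float = 1e-10) -> float:
    """Inverse of :func:`mixture_cdf` by bisection."""
    if not 0 < q < 1:
        raise ValueError("quantile level must be in (0, 1)")
    sig = gennorm_stats(m.tw)["sigma"]
    lo = min(m.ew.a, m.lw.a, m.tw.mu - 20 * sig)
    hi = max(m.ew.b, m.lw.b, m.tw.mu + 20 * sig)
    from scipy.optimize import brentq

    return float(brentq(lambda x: mixture_cdf(x, m) - q, lo, hi, xtol=tol))
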