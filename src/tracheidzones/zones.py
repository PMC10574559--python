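"""Zonation thresholds, Mork criteria, cell classification, zone reports.

The classical Mork criterion labels a tracheid latewood when wall
thickness is large relative to lumen L = D - 2*CWT; its two historical
forms (4*CWT > L and 2*CWT > L) correspond to fixed CWT/D thresholds 1/6
and 1/4.  The model-based alternative derives species-specific thresholds
from the fitted slope-angle mixture: the transition-wood center for a
two-zone split, or curve intersections / mixture percentiles for a
three-zone split.  Angle statistics back-transform to CWT/D units via
CWT/D = (CWT_mean / D_mean) * tan(phi_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .distributions import (
    MixtureModel,
    beta4_pdf,
    beta4_stats,
    gennorm_pdf,
    gennorm_stats,
    mixture_ppf,
)
from .measurements import Tracheidogram

__all__ = [
    "ZoneThresholds",
    "ZoneReport",
    "mork_threshold",
    "back_transform",
    "two_zone_threshold",
    "two_zone_proportions",
    "three_zone_boundaries",
    "classify_ring",
    "zone_report",
    "zone_ratio_means",
]

ZONES = ("EW", "TW", "LW")


@dataclass(frozen=True)
class ZoneThresholds:
    """Classification thresholds; angles are in indexed-angle degrees."""

    k_two_zone: float
    method: str  # "tw-center" | "intersection" | "percentile"
    phi_two_zone: float | None = None
    phi_ew_tw: float | None = None
    phi_tw_lw: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.k_two_zone < 0.5:
            raise ValueError(f"two-zone threshold must lie in (0, 0.5), got {self.k_two_zone}")
        if self.phi_ew_tw is not None and self.phi_tw_lw is not None:
            if not self.phi_ew_tw < self.phi_tw_lw:
                raise ValueError("EW-TW boundary must precede TW-LW boundary")


def mork_threshold(form: str = "eq1") -> float:
    """CWT/D threshold implied by a Mork-criterion form.

    ``eq1``: 4*CWT > L, i.e. CWT/D > 1/6; ``eq2``: 2*CWT > L, i.e. CWT/D > 1/4.
    """
    if form == "eq1":
        return float(Fraction(1, 6))
    if form == "eq2":
        return float(Fraction(1, 4))
    raise ValueError(f"unknown Mork form {form!r}; expected 'eq1' or 'eq2'")


def back_transform(phi: float, d_mean: float, cwt_mean: float) -> float:
    """Inverse transformation from an indexed slope angle to raw CWT/D:
    CWT/D = (CWT_mean / D_mean) * tan(phi)."""
    if not 0 < phi < 90:
        raise ValueError(f"phi must lie in (0, 90) degrees, got {phi}")
    if d_mean <= 0 or cwt_mean <= 0:
        raise ValueError("trait means must be positive")
    return (cwt_mean / d_mean) * np.tan(np.radians(phi))


def two_zone_threshold(model: MixtureModel, d_mean: float, cwt_mean: float) -> ZoneThresholds:
    """Two-zone (EW vs LW) CWT/D threshold from the center of the
    symmetric transition-wood distribution, so that the more EW-like half
    of TW joins earlywood and the other half joins latewood."""
    if model.A_TW >= 1e-6:
        phi = model.tw.mu
        method = "tw-center"
    else:
        phi = _intersection(model, "EW", "LW")
        method = "intersection"
    return ZoneThresholds(
        k_two_zone=back_transform(phi, d_mean, cwt_mean),
        phi_two_zone=float(phi),
        method=method,
    )


def two_zone_proportions(model: MixtureModel) -> tuple[float, float]:
    """(EW%, LW%) of the ring under the two-zone split: half the
    transition-wood mass joins each side."""
    ew = 100.0 * (model.A_EW + model.A_TW / 2.0)
    return ew, 100.0 - ew


def _weighted_pdf(model: MixtureModel, zone: str):
    if zone == "EW":
        return lambda x: model.A_EW * beta4_pdf(x, model.ew)
    if zone == "LW":
        return lambda x: model.A_LW * beta4_pdf(x, model.lw)
    return lambda x: model.A_TW * gennorm_pdf(x, model.tw)


def _zone_center(model: MixtureModel, zone: str) -> float:
    if zone == "EW":
        return beta4_stats(model.ew)["mode"]
    if zone == "LW":
        return beta4_stats(model.lw)["mode"]
    return model.tw.mu


def _intersection(model: MixtureModel, lo_zone: str, hi_zone: str, tol: float = 1e-10) -> float:
    """Angle where the weighted densities of two neighboring zones are
    equal, bracketed between their centers."""
    f_lo, f_hi = _weighted_pdf(model, lo_zone), _weighted_pdf(model, hi_zone)
    x_lo, x_hi = _zone_center(model, lo_zone), _zone_center(model, hi_zone)
    if x_lo >= x_hi:
        raise ValueError(f"{lo_zone} center {x_lo:.3g} is not left of {hi_zone} center {x_hi:.3g}")
    g = lambda x: f_lo(x) - f_hi(x)
    if g(x_lo) <= 0 or g(x_hi) >= 0:
        raise ValueError(
            f"no sign change between {lo_zone} and {hi_zone} centers — densities do not cross"
        )
    return float(brentq(g, x_lo, x_hi, xtol=tol))


def three_zone_boundaries(
    model: MixtureModel,
    d_mean: float,
    cwt_mean: float,
    method: str = "intersection",
) -> ZoneThresholds:
    """EW-TW and TW-LW angle boundaries.

    ``intersection``: angles where neighboring weighted densities cross.
    ``percentile``: angles where the mixture cdf equals A_EW and A_EW + A_TW,
    so classified zone fractions match the model amplitudes.
    """
    if method == "intersection":
        phi_et = _intersection(model, "EW", "TW")
        phi_tl = _intersection(model, "TW", "LW")
    elif method == "percentile":
        phi_et = mixture_ppf(model.A_EW, model)
        phi_tl = mixture_ppf(model.A_EW + model.A_TW, model)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'intersection' or 'percentile'")
    return ZoneThresholds(
        k_two_zone=back_transform(model.tw.mu, d_mean, cwt_mean),
        phi_two_zone=float(model.tw.mu),
        phi_ew_tw=float(phi_et),
        phi_tw_lw=float(phi_tl),
        method=method,
    )


def classify_ring(
    tg: Tracheidogram,
    thresholds: ZoneThresholds,
    d_mean: float,
    cwt_mean: float,
    enforce_order: bool = False,
) -> list[str]:
    """Per-cell zone labels along one ring.

    Cells are compared in indexed-angle space: phi_i is computed from the
    supplied standardization means (which must match those the thresholds
    were derived with).  Cells exactly at a boundary go to the later zone.
    With ``enforce_order`` the transition is made irreversible: the first
    cell is earlywood by definition, and labels are monotone
    EW -> TW -> LW along the ring.
    """
    if tg.n_cells < 1:
        raise ValueError("empty tracheidogram")
    ratio_i = (tg.CWT_seq / cwt_mean) / (tg.D_seq / d_mean)
    phi_i = np.degrees(np.arctan(ratio_i))
    three_zone = thresholds.phi_ew_tw is not None and thresholds.phi_tw_lw is not None
    if three_zone:
        codes = np.where(phi_i >= thresholds.phi_tw_lw, 2, np.where(phi_i >= thresholds.phi_ew_tw, 1, 0))
    else:
        boundary = thresholds.phi_two_zone
        if boundary is None:
            boundary = np.degrees(np.arctan(thresholds.k_two_zone * d_mean / cwt_mean))
        codes = np.where(phi_i >= boundary, 2, 0)
    if enforce_order:
        codes = codes.copy()
        codes[0] = 0  # the ring's first-formed cell is earlywood by definition
        codes = np.maximum.accumulate(codes)
    return [ZONES[c] for c in codes]


@dataclass
class ZoneReport:
    """Per-zone distribution characteristics in angle space and in
    back-transformed CWT/D units, plus two-zone proportions."""

    table: pd.DataFrame
    ew_percent_two_zone: float
    lw_percent_two_zone: float
    thresholds: ZoneThresholds

    def to_text(self) -> str:
        lines = [self.table.to_string(float_format=lambda v: f"{v:.3f}")]
        lines.append("")
        lines.append(
            f"two-zone split at CWT/D = {self.thresholds.k_two_zone:.3f} "
            f"({self.thresholds.method}): EW {self.ew_percent_two_zone:.1f}% / "
            f"LW {self.lw_percent_two_zone:.1f}%"
        )
        return "\n".join(lines)


def zone_report(model: MixtureModel, d_mean: float, cwt_mean: float) -> ZoneReport:
    """Table of per-zone amplitude, angle statistics, and back-transformed
    CWT/D statistics (each CWT/D statistic is the back-transform of the
    corresponding angle statistic)."""
    rows = {}
    stats_by_zone = {
        "EW": beta4_stats(model.ew),
        "TW": gennorm_stats(model.tw),
        "LW": beta4_stats(model.lw),
    }
    amps = dict(zip(ZONES, model.amplitudes))
    for zone in ZONES:
        st = stats_by_zone[zone]
        rows[zone] = {
            "A_percent": 100.0 * amps[zone],
            "mu_deg": st["mean"],
            "median_deg": st["median"],
            "mode_deg": st["mode"],
            "sigma_deg": st["sigma"],
            "cwt_d_mean": back_transform(st["mean"], d_mean, cwt_mean),
            "cwt_d_median": back_transform(st["median"], d_mean, cwt_mean),
            "cwt_d_mode": back_transform(st["mode"], d_mean, cwt_mean),
        }
    ew_pct, lw_pct = two_zone_proportions(model)
    return ZoneReport(
        table=pd.DataFrame(rows).T,
        ew_percent_two_zone=ew_pct,
        lw_percent_two_zone=lw_pct,
        thresholds=two_zone_threshold(model, d_mean, cwt_mean),
    )


def zone_ratio_means(ratios: np.ndarray, labels: list[str] | np.ndarray) -> dict[str, float]:
    """Raw per-zone arithmetic means of CWT/D over classified cells — an
    alternative to back-transforming the angle means; the two differ
    because tan is nonlinear."""
    s = pd.Series(np.asarray(ratios, dtype=float))
    lab = pd.Series(list(labels))
    return {z: float(s[lab == z].mean()) for z in ZONES if (lab == z).any()}
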