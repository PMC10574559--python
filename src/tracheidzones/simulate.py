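"""Synthetic tracheid datasets with the statistical structure the mixture
model assumes.

The generator draws each cell's zone from the mixture amplitudes and its
indexed slope angle from the zone's distribution, orders cells within a
ring EW -> TW -> LW (within zone by angle) to emulate intra-ring anatomy,
attaches zone-dependent cell diameters, and de-standardizes by
species-level trait means.  Rings are replicated into several radial rows
with multiplicative jitter representing random row-to-row differences.

Species presets reconstruct published per-zone distribution statistics
for three Siberian conifers (*Picea obovata*, *Pinus sibirica*,
*Pinus sylvestris*); the joint (diameter, angle) structure and the
transition-wood shape parameter are synthetic conventions, not measured
values (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distributions import (
    BetaZoneParams,
    GenNormParams,
    MixtureModel,
    beta4_from_stats,
    gennorm_stats,
)
from .measurements import COLUMNS

__all__ = [
    "SpeciesProfile",
    "species_profile",
    "PRESET_NAMES",
    "sample_angles",
    "build_dataset",
]

_ZONES = ("EW", "TW", "LW")

#: synthetic convention: zone-dependent relative diameter D_i ~ truncated
#: normal (earlywood cells large, latewood small)
_D_I_MEANS = {"EW": 1.25, "TW": 0.9, "LW": 0.55}
_D_I_SIGMA = 0.12

#: transition-wood shape used when reconstructing a model from published
#: per-zone statistics (the shape itself is not published)
_TW_SHAPE = 4.0


@dataclass(frozen=True)
class SpeciesProfile:
    """Generator configuration for one species-like dataset."""

    label: str
    d_mean: float  # target mean radial diameter, um
    cwt_mean: float  # target mean wall thickness, um
    model: MixtureModel  # mixture of indexed slope angles
    cells_per_row_mean: float = 20.0
    cells_per_row_sd: float = 4.0
    rings_per_tree: int = 50
    n_trees: int = 5
    rows_per_ring: int = 5
    row_jitter: float = 0.05  # lognormal sigma of multiplicative row noise
    first_year: int = 1968

    def __post_init__(self) -> None:
        if min(self.d_mean, self.cwt_mean, self.cells_per_row_mean) <= 0:
            raise ValueError("trait means and cell counts must be positive")
        if min(self.rings_per_tree, self.n_trees, self.rows_per_ring) < 1:
            raise ValueError("counts must be >= 1")
        if self.row_jitter < 0:
            raise ValueError("row_jitter must be >= 0")


def _gennorm_scale(sigma: float, shape: float) -> float:
    unit = gennorm_stats(GenNormParams(0.0, 1.0, shape))["sigma"]
    return sigma / unit


# Published per-zone statistics used to reconstruct the preset mixtures:
# amplitudes (%), then EW/LW (mean, median, mode, sigma) in degrees and
# TW (mu, sigma).
_PRESETS: dict[str, dict] = {
    "picea_obovata": dict(
        d_mean=28.6, cwt_mean=2.6,
        A_EW=0.492, A_LW=0.287,
        ew=(30.57, 29.98, 28.70, 4.80),
        lw=(68.67, 69.01, 70.29, 4.38),
        tw=(49.00, 7.35),
        cells_per_row_mean=19.6, first_year=1965,
    ),
    "pinus_sibirica": dict(
        d_mean=35.3, cwt_mean=2.9,
        A_EW=0.774, A_LW=0.084,
        ew=(40.52, 40.00, 38.86, 4.97),
        lw=(73.13, 73.42, 74.11, 2.61),
        tw=(59.00, 5.26),
        cells_per_row_mean=19.7, first_year=1968,
    ),
    "pinus_sylvestris": dict(
        d_mean=34.5, cwt_mean=3.3,
        A_EW=0.620, A_LW=0.296,
        ew=(34.60, 34.24, 33.48, 4.12),
        lw=(65.86, 66.37, 67.48, 4.44),
        tw=(48.81, 5.13),
        cells_per_row_mean=25.3, first_year=1968,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def species_profile(name: str, **overrides) -> SpeciesProfile:
    """Build a preset :class:`SpeciesProfile` by species name.

    The beta parameters are recovered numerically from the published
    per-zone mean/median/mode/sigma; keyword overrides replace any
    profile field.
    """
    try:
        cfg = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}") from None
    model = MixtureModel(
        A_EW=cfg["A_EW"],
        A_LW=cfg["A_LW"],
        ew=beta4_from_stats(*cfg["ew"]),
        lw=beta4_from_stats(*cfg["lw"]),
        tw=GenNormParams(
            mu=cfg["tw"][0],
            alpha_scale=_gennorm_scale(cfg["tw"][1], _TW_SHAPE),
            beta_shape=_TW_SHAPE,
        ),
    )
    profile = SpeciesProfile(
        label=name,
        d_mean=cfg["d_mean"],
        cwt_mean=cfg["cwt_mean"],
        model=model,
        cells_per_row_mean=cfg["cells_per_row_mean"],
        first_year=cfg["first_year"],
    )
    return replace(profile, **overrides) if overrides else profile


# ---------------------------------------------------------------------------
# sampling

def sample_angles(
    model: MixtureModel, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` indexed slope angles (degrees) with their true zone labels.

    Ancestral sampling: the zone comes from the amplitudes, the angle from
    the zone's distribution.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    zones = rng.choice(3, size=n, p=list(model.amplitudes))
    phi = np.empty(n)
    for code, p in ((0, model.ew), (2, model.lw)):
        mask = zones == code
        k = int(mask.sum())
        if k:
            phi[mask] = p.a + (p.b - p.a) * rng.beta(p.alpha, p.beta, size=k)
    mask = zones == 1
    k = int(mask.sum())
    if k:
        phi[mask] = sps.gennorm.rvs(
            model.tw.beta_shape, loc=model.tw.mu, scale=model.tw.alpha_scale,
            size=k, random_state=rng,
        )
    labels = np.array(_ZONES)[np.where(zones == 1, 1, np.where(zones == 2, 2, 0))]
    return phi, labels


def _sample_ring(model: MixtureModel, n_cells: int, rng: np.random.Generator,
                 max_tries: int = 200) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One master ring: ordered (phi_i, D_i, labels) with 0 < phi < 90
    and CWT_i/D_i consistent by construction."""
    for _ in range(max_tries):
        phi, labels = sample_angles(model, n_cells, rng)
        if np.all((phi > 1.0) & (phi < 89.0)):
            break
    else:
        raise RuntimeError("could not draw a ring with angles inside (1, 89) degrees")
    zone_rank = np.array([{"EW": 0, "TW": 1, "LW": 2}[z] for z in labels])
    order = np.lexsort((phi, zone_rank))  # EW -> TW -> LW, by angle within zone
    phi, labels, zone_rank = phi[order], labels[order], zone_rank[order]
    d_i = np.empty(n_cells)
    for code, zone in enumerate(_ZONES):
        mask = zone_rank == code
        k = int(mask.sum())
        if k:
            lo = (0.1 - _D_I_MEANS[zone]) / _D_I_SIGMA  # keep diameters positive
            d_i[mask] = sps.truncnorm.rvs(
                lo, np.inf, loc=_D_I_MEANS[zone], scale=_D_I_SIGMA,
                size=k, random_state=rng,
            )
    return phi, d_i, labels


def build_dataset(
    profile: SpeciesProfile, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full measurement table for one species profile.

    Returns ``(measurements, truth)``: the standard measurement CSV frame
    (tree_id, year, row_id, rank, D_um, CWT_um) and a truth frame with the
    generating zone and indexed angle per cell.  All cells satisfy
    CWT/D < 1/2 by rejection; rows within a ring are jittered replicates
    of a master ring.
    """
    rng = np.random.default_rng(seed)
    ratio_scale = profile.cwt_mean / profile.d_mean
    meas, truth = [], []
    for t in range(profile.n_trees):
        tree_id = f"{profile.label}_t{t + 1}"
        # independent per-tree stream so trees can be generated in isolation
        tree_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        for r in range(profile.rings_per_tree):
            year = profile.first_year + r
            n_cells = max(3, int(round(tree_rng.normal(
                profile.cells_per_row_mean, profile.cells_per_row_sd))))
            phi, d_i, labels = _sample_ring(profile.model, n_cells, tree_rng)
            cwt_i = d_i * np.tan(np.radians(phi))
            d_master = d_i * profile.d_mean
            cwt_master = cwt_i * profile.cwt_mean
            # master ratio < 0.5 by construction when ratio_scale*tan(phi) < 0.5
            bad = cwt_master / d_master >= 0.499
            for _ in range(200):
                if not bad.any():
                    break
                k = int(bad.sum())
                phi_new, lab_new = sample_angles(profile.model, k, tree_rng)
                ok = (phi_new > 1.0) & (phi_new < 89.0)
                idx = np.flatnonzero(bad)[ok]
                phi[idx] = phi_new[ok]
                labels[idx] = lab_new[ok]
                cwt_i = d_i * np.tan(np.radians(phi))
                cwt_master = cwt_i * profile.cwt_mean
                bad = cwt_master / d_master >= 0.499
            if bad.any():
                raise RuntimeError(
                    f"profile {profile.label!r} implies CWT/D >= 0.5 too often; "
                    "reduce cwt_mean/d_mean or the latewood angles"
                )
            for row in range(1, profile.rows_per_ring + 1):
                for attempt in range(100):
                    jd = tree_rng.lognormal(0.0, profile.row_jitter, n_cells)
                    jw = tree_rng.lognormal(0.0, profile.row_jitter, n_cells)
                    d_row = d_master * jd
                    cwt_row = cwt_master * jw
                    if np.all(cwt_row / d_row < 0.4999):
                        break
                else:
                    # fall back to the un-jittered master ring for this row
                    d_row, cwt_row = d_master.copy(), cwt_master.copy()
                for rank in range(n_cells):
                    meas.append((tree_id, year, row, rank + 1,
                                 float(d_row[rank]), float(cwt_row[rank])))
                    truth.append((tree_id, year, row, rank + 1,
                                  labels[rank], float(phi[rank])))
    measurements = pd.DataFrame(meas, columns=COLUMNS)
    truth_df = pd.DataFrame(
        truth, columns=["tree_id", "year", "row_id", "rank", "zone", "phi_i_true"]
    )
    return measurements, truth_df
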