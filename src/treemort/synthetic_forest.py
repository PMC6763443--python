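"""Seeded synthetic forest landscapes with known mortality ground truth.

Generates everything the downstream pipeline consumes — conical-crown
canopy height models, 4-band imagery with sunlit/shaded x live/dead
spectral classes, smooth correlated environmental rasters, and per-tree
death years drawn from a configurable hazard — so crown detection,
classification, temporal tracking, and the driver models can all be tested
against exact ground truth without any external data.

Coordinate convention: map x increases eastward with column index, map y
increases southward with row index; the origin is the top-left (NW) corner
and raster values are sampled at pixel centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .scenario import ENV_VARS, IMAGE_CLASSES, HazardModel, SyntheticScenario

logger = logging.getLogger(__name__)


@dataclass
class Landscape:
    """A realized synthetic study area.

    ``trees`` has one row per tree: id, x, y, height, crown_radius, one
    column per environmental variable sampled at the stem location, and
    ``death_year`` (NaN while mortality has not been simulated; otherwise
    the first acquisition year at which the tree is observed dead).
    """

    scenario: SyntheticScenario
    trees: pd.DataFrame
    env_fields: dict
    placement_shortfall: int = 0
    log: dict = field(default_factory=dict)

    @property
    def resolution_m(self) -> float:
        return self.scenario.resolution_m

    @property
    def shape(self) -> tuple:
        return self.scenario.shape


def _truncated_lognormal(rng, n, mu, sigma, lo, hi):
    """i.i.d. log-normal heights restricted to [lo, hi] by rejection."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=max(n - filled, 16) * 2)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _place_trees(rng, n, width, height, min_spacing, max_attempts_per_tree=200):
    """Sequential random placement with hard-core inhibition.

    Uses a cell grid (cell size = min_spacing) so each candidate only checks
    its 3x3 neighborhood. Returns (xs, ys, shortfall)."""
    if n == 0:
        return np.empty(0), np.empty(0), 0
    cell = max(min_spacing, 1e-9)
    grid: dict = {}
    xs, ys = [], []
    attempts_left = max_attempts_per_tree * n
    while len(xs) < n and attempts_left > 0:
        attempts_left -= 1
        x = rng.uniform(0.0, width)
        y = rng.uniform(0.0, height)
        cx, cy = int(x / cell), int(y / cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for (px, py) in grid.get((cx + dx, cy + dy), ()):
                    if (x - px) ** 2 + (y - py) ** 2 < min_spacing ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((cx, cy), []).append((x, y))
            xs.append(x)
            ys.append(y)
    shortfall = n - len(xs)
    if shortfall:
        logger.warning("placed %d of %d trees before exhausting attempts "
                       "(min_spacing=%.2f m)", len(xs), n, min_spacing)
    return np.asarray(xs), np.asarray(ys), shortfall


def _smooth_noise(rng, shape, sd, scale_px):
    """Gaussian random field with marginal SD `sd`, correlation length `scale_px`."""
    if sd <= 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if scale_px > 0:
        sm = ndimage.gaussian_filter(white, sigma=scale_px, mode="reflect")
        s = sm.std()
        sm = sm / s if s > 0 else sm
    else:
        sm = white
    return sm * sd


def _ramp(shape, base, ramp, axis):
    rows, cols = shape
    if axis == "x":
        t = (np.arange(cols) + 0.5) / cols
        return base + ramp * t[None, :] * np.ones((rows, 1))
    t = (np.arange(rows) + 0.5) / rows
    return base + ramp * t[:, None] * np.ones((1, cols))


def build_env_fields(scenario: SyntheticScenario, rng) -> dict:
    """Realize the environmental rasters.

    The temperature and precipitation anomaly fields are affine functions of
    the VPD field plus independent smooth noise, sized analytically so the
    realized correlations hit `vpd_t_corr` / `vpd_ppt_corr`: for
    T = a*V + e with e independent of V, corr(V, T) = a*sd(V) /
    sqrt(a^2 var(V) + var(e)), so var(e) = a^2 var(V) (1/r^2 - 1).
    """
    shape = scenario.shape
    res = scenario.resolution_m
    specs = scenario.env_gradients
    fields = {}

    vspec = specs["vpd_max"]
    vpd = _ramp(shape, vspec.base, vspec.ramp, vspec.axis) + _smooth_noise(
        rng, shape, vspec.noise_sd, vspec.noise_scale_m / res)
    if vspec.clip_min is not None:
        vpd = np.maximum(vpd, vspec.clip_min)
    fields["vpd_max"] = vpd

    vsd = vpd.std()
    for name, r in (("dt_pct", scenario.vpd_t_corr), ("dppt_pct", scenario.vpd_ppt_corr)):
        spec = specs[name]
        # affine map of VPD onto the spec's target range, then calibrated noise
        a = spec.ramp / vspec.ramp if vspec.ramp else np.sign(r)
        if np.sign(a) != np.sign(r):
            a = -a
        b = spec.base - a * vspec.base
        noise_var = (a * vsd) ** 2 * (1.0 / r ** 2 - 1.0) if abs(r) < 1 else 0.0
        field_ = a * vpd + b + _smooth_noise(rng, shape, np.sqrt(noise_var),
                                             spec.noise_scale_m / res)
        if spec.clip_min is not None:
            field_ = np.maximum(field_, spec.clip_min)
        fields[name] = field_

    for name in ("soil_awc", "cover_pct", "slope_pct"):
        spec = specs[name]
        field_ = _ramp(shape, spec.base, spec.ramp, spec.axis) + _smooth_noise(
            rng, shape, spec.noise_sd, spec.noise_scale_m / res)
        if spec.clip_min is not None:
            field_ = np.maximum(field_, spec.clip_min)
        fields[name] = field_
    return fields


def sample_env_at(env_fields: dict, xs, ys, resolution_m: float) -> pd.DataFrame:
    """Nearest-pixel environmental lookup at map coordinates."""
    out = {}
    any_field = next(iter(env_fields.values()))
    rows = np.clip((np.asarray(ys) / resolution_m).astype(int), 0, any_field.shape[0] - 1)
    cols = np.clip((np.asarray(xs) / resolution_m).astype(int), 0, any_field.shape[1] - 1)
    for name, f in env_fields.items():
        out[name] = f[rows, cols]
    return pd.DataFrame(out)


def generate_landscape(scenario: SyntheticScenario) -> Landscape:
    """Place trees, draw heights, and realize environmental rasters.

    Fully reproducible from ``scenario.seed``. Tree placement is sequential
    random with rejection below ``min_spacing_m``; if the requested density
    is infeasible scenario validation raises, and if placement stalls short
    of ``n_trees`` the shortfall is recorded on the landscape.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    width, height = scenario.domain_size_m

    env_fields = build_env_fields(scenario, rng)

    xs, ys, shortfall = _place_trees(rng, scenario.n_trees, width, height,
                                     scenario.min_spacing_m)
    n = len(xs)
    lo, hi = scenario.height_range_m
    heights = _truncated_lognormal(rng, n, scenario.height_lognormal_mu,
                                   scenario.height_lognormal_sigma, lo, hi)
    trees = pd.DataFrame({
        "tree_id": np.arange(1, n + 1),
        "x": xs,
        "y": ys,
        "height": heights,
        "crown_radius": scenario.crown_radius_coef * heights,
    })
    env_at_trees = sample_env_at(env_fields, xs, ys, scenario.resolution_m)
    trees = pd.concat([trees, env_at_trees.reset_index(drop=True)], axis=1)
    trees["death_year"] = np.nan
    return Landscape(scenario=scenario, trees=trees, env_fields=env_fields,
                     placement_shortfall=shortfall)


def simulate_mortality(landscape: Landscape, hazard: HazardModel | None = None,
                       seed: int | None = None) -> Landscape:
    """Draw each tree's death year from annual hazard draws.

    Simulation steps annually from the first acquisition year; a death in
    calendar year t is observed at the first acquisition year >= t+1 (status
    is assessed at acquisition). Dead is absorbing. The returned landscape
    is the same object with ``death_year`` filled.
    """
    scen = landscape.scenario
    hazard = hazard if hazard is not None else scen.hazard
    hazard.validate()
    rng = np.random.default_rng(scen.seed + 1 if seed is None else seed)
    trees = landscape.trees
    n = len(trees)
    years = list(scen.acquisition_years)
    death_year = np.full(n, np.nan)
    if n == 0:
        trees["death_year"] = death_year
        return landscape
    env = {v: trees[v].to_numpy() for v in ENV_VARS if v in trees.columns}
    heights = trees["height"].to_numpy()
    p = hazard.annual_death_prob(heights, env)
    if hazard.form == "linear-rate":
        raw = hazard.b0 + hazard.b_height * heights
        for v, b in hazard.b_env.items():
            raw = raw + b * env[v]
        for v, b in hazard.b_interaction.items():
            raw = raw + b * heights * env[v]
        n_out = int(np.sum((raw < 0) | (raw > 1)))
        if n_out:
            logger.warning("linear-rate hazard produced %d probabilities outside "
                           "[0,1] before clamping", n_out)
            landscape.log["hazard_clamped"] = n_out
    alive = np.ones(n, dtype=bool)
    for year in range(years[0], years[-1]):
        u = rng.random(n)
        died = alive & (u < p)
        if died.any():
            # observed at the first acquisition after the death year
            obs = next(y for y in years if y >= year + 1)
            death_year[died] = obs
            alive &= ~died
    trees["death_year"] = death_year
    return landscape


# ---------------------------------------------------------------------------
# rendering

def render_chm(landscape: Landscape, resolution_m: float | None = None,
               return_owner: bool = False):
    """Render the canopy height model from conical crowns.

    Each tree contributes a cone h*(1 - d/r) over its crown disk; a pixel
    takes the maximum over all trees, floored at 0, background exactly 0.
    With ``return_owner`` also returns the id of the tree attaining the max
    (0 = background), which is the generator's crown ground truth.
    """
    res = resolution_m if resolution_m is not None else landscape.resolution_m
    width, height = landscape.scenario.domain_size_m
    rows = int(round(height / res))
    cols = int(round(width / res))
    chm = np.zeros((rows, cols))
    owner = np.zeros((rows, cols), dtype=np.int32)
    for t in landscape.trees.itertuples():
        r = t.crown_radius
        if r <= 0:
            continue
        c0 = max(int((t.x - r) / res - 1), 0)
        c1 = min(int((t.x + r) / res + 2), cols)
        r0 = max(int((t.y - r) / res - 1), 0)
        r1 = min(int((t.y + r) / res + 2), rows)
        if c0 >= c1 or r0 >= r1:
            continue
        px = (np.arange(c0, c1) + 0.5) * res
        py = (np.arange(r0, r1) + 0.5) * res
        d = np.hypot(px[None, :] - t.x, py[:, None] - t.y)
        cone = t.height * (1.0 - d / r)
        cone[cone < 0] = 0.0
        patch = chm[r0:r1, c0:c1]
        better = cone > patch
        patch[better] = cone[better]
        owner[r0:r1, c0:c1][better] = t.tree_id
    if return_owner:
        return chm, owner
    return chm


def render_imagery(landscape: Landscape, year: int, spectral: dict | None = None,
                   seed: int | None = None, sun_azimuth_deg: float | None = None):
    """Render 4-band imagery for an acquisition year plus the truth raster.

    Crown pixels are labeled sunlit or shaded (the half-crown away from the
    sun azimuth, measured clockwise from north) crossed with live or dead
    (dead from the tree's death year onward, absorbing); band values are
    drawn from the class's 4-band Gaussian. Returns ``(imagery, truth)``
    where imagery is (4, rows, cols) and truth holds indices into
    :data:`treemort.scenario.IMAGE_CLASSES`.
    """
    scen = landscape.scenario
    spectral = spectral if spectral is not None else scen.spectral
    azimuth = scen.sun_azimuth_deg if sun_azimuth_deg is None else sun_azimuth_deg
    rng = np.random.default_rng((scen.seed + 104729 * int(year)) % (2 ** 31)
                                if seed is None else seed)
    _, owner = render_chm(landscape, return_owner=True)
    rows, cols = owner.shape
    res = landscape.resolution_m

    truth = np.zeros((rows, cols), dtype=np.int8)  # background = 0
    trees = landscape.trees.set_index("tree_id")
    if len(trees):
        # unit vector pointing toward the sun (azimuth clockwise from north;
        # map y grows southward, so north is -y)
        az = np.deg2rad(azimuth)
        sun = np.array([np.sin(az), -np.cos(az)])
        rr, cc = np.nonzero(owner)
        ids = owner[rr, cc]
        tx = trees.loc[ids, "x"].to_numpy()
        ty = trees.loc[ids, "y"].to_numpy()
        dy_ = trees.loc[ids, "death_year"].to_numpy()
        px = (cc + 0.5) * res
        py = (rr + 0.5) * res
        toward_sun = (px - tx) * sun[0] + (py - ty) * sun[1]
        sunlit = toward_sun >= 0.0  # ties count as sunlit
        dead = np.isfinite(dy_) & (dy_ <= year)
        code = np.where(dead, np.where(sunlit, 3, 4), np.where(sunlit, 1, 2))
        truth[rr, cc] = code

    imagery = np.zeros((4, rows, cols))
    for ci, cname in enumerate(IMAGE_CLASSES):
        mask = truth == ci
        npx = int(mask.sum())
        if npx == 0:
            continue
        spec = spectral[cname]
        cov = np.asarray(spec["cov"], dtype=float)
        mean = np.asarray(spec["mean"], dtype=float)
        if np.allclose(cov, 0):
            draws = np.tile(mean, (npx, 1))
        else:
            draws = rng.multivariate_normal(mean, cov, size=npx, method="cholesky")
        for b in range(4):
            imagery[b][mask] = draws[:, b]
    return imagery, truth


# ---------------------------------------------------------------------------
# tree-table simulation (no rasters) for the statistical driver analyses

def sample_tree_table(n: int, seed: int, *,
                      height_mu: float = 2.85, height_sigma: float = 0.45,
                      height_range=(5.0, 60.0),
                      vpd_range=(1.2, 2.6),
                      vpd_t_corr: float = 0.98, vpd_ppt_corr: float = -0.96,
                      t_scale: float = 7.0, ppt_scale: float = -14.0,
                      awc_mean: float = 60.0, awc_sd: float = 20.0,
                      cover_mean: float = 45.0, cover_sd: float = 15.0,
                      slope_mean: float = 15.0, slope_sd: float = 8.0,
                      hazard: HazardModel | None = None,
                      years: float = 1.0) -> pd.DataFrame:
    """Draw a tree-level covariate table with a binary death outcome.

    This is the raster-free generator used by the statistical recovery
    studies: heights are truncated log-normal, VPD uniform over `vpd_range`,
    temperature/precipitation anomalies affine in VPD with noise calibrated
    to the target correlations, and the death indicator is one Bernoulli
    draw per tree at probability ``1 - (1-p)^years`` where p is the hazard's
    annual probability.
    """
    rng = np.random.default_rng(seed)
    hazard = hazard if hazard is not None else HazardModel()
    heights = _truncated_lognormal(rng, n, height_mu, height_sigma, *height_range)
    vpd = rng.uniform(vpd_range[0], vpd_range[1], size=n)
    vsd = np.sqrt((vpd_range[1] - vpd_range[0]) ** 2 / 12.0)

    def _derived(scale, r):
        noise_sd = abs(scale) * vsd * np.sqrt(1.0 / r ** 2 - 1.0) if abs(r) < 1 else 0.0
        return scale * (vpd - np.mean(vpd_range)) + rng.normal(0, noise_sd, size=n)

    dt = _derived(t_scale if vpd_t_corr >= 0 else -t_scale, vpd_t_corr)
    dppt = _derived(ppt_scale if vpd_ppt_corr <= 0 else -ppt_scale, vpd_ppt_corr)
    awc = np.maximum(rng.normal(awc_mean, awc_sd, size=n), 0.0)
    cover = np.clip(rng.normal(cover_mean, cover_sd, size=n), 0.0, 100.0)
    slope = np.maximum(rng.normal(slope_mean, slope_sd, size=n), 0.0)
    env = {"vpd_max": vpd, "dt_pct": dt, "dppt_pct": dppt,
           "soil_awc": awc, "cover_pct": cover, "slope_pct": slope}
    p_annual = hazard.annual_death_prob(heights, env)
    p = 1.0 - (1.0 - p_annual) ** years
    dead = rng.random(n) < p
    return pd.DataFrame({"tree_id": np.arange(1, n + 1), "height": heights,
                         **env, "dead": dead})
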