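"""Scenario configuration for synthetic drought-mortality landscapes.

A :class:`SyntheticScenario` bundles everything needed to generate a
reproducible synthetic study area: stand structure (tree density, spacing,
height distribution, crown geometry), environmental gradients (vapor
pressure deficit, temperature and precipitation anomalies, soil available
water capacity, canopy cover, terrain slope), the mortality hazard, the
acquisition calendar, and the spectral model used to render 4-band imagery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

ENV_VARS = ("vpd_max", "dt_pct", "dppt_pct", "soil_awc", "cover_pct", "slope_pct")

#: imagery classes; index order is the classification label order
IMAGE_CLASSES = ("background", "sunlit-live", "shaded-live", "sunlit-dead", "shaded-dead")
DEAD_CLASSES = ("sunlit-dead", "shaded-dead")


def _is_spd(cov: np.ndarray, tol: float = 1e-10) -> bool:
    cov = np.asarray(cov, dtype=float)
    if cov.shape[0] != cov.shape[1] or not np.allclose(cov, cov.T, atol=1e-8):
        return False
    return bool(np.linalg.eigvalsh(cov).min() > tol * max(1.0, np.trace(cov)))


@dataclass
class HazardModel:
    """Annual per-tree death probability model.

    Two forms are supported:

    ``logistic-status``
        logit(p) = b0 + b_height*Z + sum_v b_env[v]*E_v + sum_v b_interaction[v]*Z*E_v

    ``linear-rate``
        p = b0 + b_height*Z + sum_v b_env[v]*E_v + sum_v b_interaction[v]*Z*E_v

    where ``Z`` is tree height (m) and ``E_v`` the local environment value.
    The interaction term carries the height x environment coupling
    (M = beta0 + beta1 * Z * dENV on the rate scale); ``linear-rate`` makes
    that coupling exact in probability, ``logistic-status`` in log-odds.
    Probabilities are clamped to ``[clamp_eps, 1 - clamp_eps]``; dead trees
    stay dead.
    """

    form: str = "logistic-status"
    b0: float = -3.7
    b_height: float = 0.0231
    b_env: dict = field(default_factory=dict)
    b_interaction: dict = field(default_factory=dict)
    clamp_eps: float = 1e-9

    def validate(self) -> None:
        if self.form not in ("logistic-status", "linear-rate"):
            raise ValueError(f"unknown hazard form {self.form!r}")
        if not 0 <= self.clamp_eps < 0.5:
            raise ValueError("clamp_eps must be in [0, 0.5)")
        for d in (self.b_env, self.b_interaction):
            for k in d:
                if k not in ENV_VARS:
                    raise ValueError(f"unknown environment variable {k!r}")

    def annual_death_prob(self, height, env: dict) -> np.ndarray:
        """Vectorized annual death probability for trees with `height` (m)
        and local environment `env` (mapping variable -> array)."""
        height = np.asarray(height, dtype=float)
        lin = self.b0 + self.b_height * height
        for v, b in self.b_env.items():
            lin = lin + b * np.asarray(env[v], dtype=float)
        for v, b in self.b_interaction.items():
            lin = lin + b * height * np.asarray(env[v], dtype=float)
        if self.form == "logistic-status":
            p = 1.0 / (1.0 + np.exp(-lin))
        else:
            p = lin
        return np.clip(p, self.clamp_eps, 1.0 - self.clamp_eps)


@dataclass
class EnvFieldSpec:
    """One environmental raster: linear ramp plus smoothed Gaussian noise.

    ``base`` is the value at the west edge, ``ramp`` the total increase across
    the domain (west to east for ``axis='x'``, north to south for ``'y'``),
    ``noise_sd`` the marginal SD of the smooth noise and ``noise_scale_m``
    its correlation length.
    """

    base: float
    ramp: float = 0.0
    axis: str = "x"
    noise_sd: float = 0.0
    noise_scale_m: float = 50.0
    clip_min: float | None = None


def default_env_gradients() -> dict:
    # VPD_MAX spans ~1.2-2.6 kPa across the domain; dT/dPPT are derived from
    # VPD downstream (see vpd_t_corr / vpd_ppt_corr), so their specs here
    # only set the affine target range and residual noise.
    return {
        "vpd_max": EnvFieldSpec(base=1.2, ramp=1.4, axis="x", noise_sd=0.08, clip_min=0.05),
        "dt_pct": EnvFieldSpec(base=0.0, ramp=10.0, axis="x", noise_sd=0.4),
        "dppt_pct": EnvFieldSpec(base=0.0, ramp=-20.0, axis="x", noise_sd=1.0),
        "soil_awc": EnvFieldSpec(base=30.0, ramp=60.0, axis="y", noise_sd=4.0, clip_min=0.0),
        "cover_pct": EnvFieldSpec(base=20.0, ramp=50.0, axis="y", noise_sd=8.0, clip_min=0.0),
        "slope_pct": EnvFieldSpec(base=5.0, ramp=20.0, axis="y", noise_sd=5.0, clip_min=0.0),
    }


def default_spectra() -> dict:
    """4-band (R, G, B, NIR) class means and covariances, 0-255 scale.

    Dead crowns are red-shifted with depressed NIR; shading scales radiance
    down. Diagonal covariances keep classes well separated for the
    maximum-likelihood classifier under default conditions.
    """
    means = {
        "background": [120.0, 110.0, 100.0, 95.0],
        "sunlit-live": [50.0, 95.0, 45.0, 185.0],
        "shaded-live": [25.0, 48.0, 22.0, 95.0],
        "sunlit-dead": [150.0, 95.0, 60.0, 110.0],
        "shaded-dead": [75.0, 48.0, 30.0, 55.0],
    }
    return {
        name: {"mean": np.array(mu, dtype=float), "cov": np.eye(4) * 36.0}
        for name, mu in means.items()
    }


@dataclass
class SyntheticScenario:
    domain_size_m: tuple = (300.0, 300.0)  # (width E-W, height N-S)
    resolution_m: float = 0.6
    n_trees: int = 1500
    min_spacing_m: float = 4.0
    height_lognormal_mu: float = 2.85
    height_lognormal_sigma: float = 0.45
    height_range_m: tuple = (5.0, 60.0)
    crown_radius_coef: float = 0.10
    env_gradients: dict = field(default_factory=default_env_gradients)
    vpd_t_corr: float = 0.98
    vpd_ppt_corr: float = -0.96
    hazard: HazardModel = field(default_factory=HazardModel)
    acquisition_years: tuple = (2009, 2010, 2012, 2014, 2016)
    sun_azimuth_deg: float = 180.0
    spectral: dict = field(default_factory=default_spectra)
    seed: int = 0

    def validate(self) -> None:
        w, h = self.domain_size_m
        if w <= 0 or h <= 0:
            raise ValueError("domain_size_m must be positive")
        if self.resolution_m <= 0:
            raise ValueError("resolution_m must be positive")
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        lo, hi = self.height_range_m
        if not (5.0 <= lo < hi <= 120.0):
            raise ValueError("height_range_m must satisfy 5 <= min < max <= 120")
        years = list(self.acquisition_years)
        if years != sorted(set(years)):
            raise ValueError("acquisition_years must be strictly increasing")
        for name, spec in self.spectral.items():
            if not _is_spd(spec["cov"]) and not np.allclose(spec["cov"], 0):
                raise ValueError(f"spectral covariance for class {name!r} is not "
                                 "symmetric positive (semi-)definite")
        self.hazard.validate()
        # feasibility of the requested stand density under hard-core spacing:
        # a packing denser than ~ one tree per (0.5*min_spacing)^2 * pi circle
        # cannot be realized by inhibition sampling.
        if self.n_trees > 0 and self.min_spacing_m > 0:
            packing_limit = (w * h) / (math.pi * (self.min_spacing_m / 2.0) ** 2)
            if self.n_trees > packing_limit:
                raise ValueError(
                    f"min_spacing_m={self.min_spacing_m} cannot accommodate "
                    f"{self.n_trees} trees in {w}x{h} m; at most about "
                    f"{int(packing_limit)} trees are achievable"
                )

    @property
    def shape(self) -> tuple:
        """Raster shape (rows, cols): rows index north->south."""
        w, h = self.domain_size_m
        return (int(round(h / self.resolution_m)), int(round(w / self.resolution_m)))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["spectral"] = {
            k: {"mean": np.asarray(v["mean"]).tolist(), "cov": np.asarray(v["cov"]).tolist()}
            for k, v in self.spectral.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "hazard" in d:
            d["hazard"] = HazardModel(**d["hazard"])
        if "env_gradients" in d:
            d["env_gradients"] = {k: EnvFieldSpec(**v) if isinstance(v, dict) else v
                                  for k, v in d["env_gradients"].items()}
        if "spectral" in d:
            d["spectral"] = {
                k: {"mean": np.asarray(v["mean"], dtype=float),
                    "cov": np.asarray(v["cov"], dtype=float)}
                for k, v in d["spectral"].items()
            }
        for key in ("domain_size_m", "height_range_m", "acquisition_years"):
            if key in d:
                d[key] = tuple(d[key])
        scen = cls(**d)
        scen.validate()
        return scen
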