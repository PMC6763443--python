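"""Per-crown status tracking across acquisitions and mortality rates.

Dead is treated as an absorbing state: any classifier flicker back to live
is coerced to dead (and counted). Mortality rates follow the survivor-pool
convention — trees identified as dead are removed from subsequent
susceptible pools so repeated observation of a standing dead crown never
inflates the rate. Rate over an interval is percent mortality of the
susceptible pool divided by the interval length in years (% yr^-1), and
cumulative mortality is referenced to the initial population.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synthetic_forest import sample_env_at

logger = logging.getLogger(__name__)

HEIGHT_CLASSES = ("small", "medium", "large")
_CLASS_EDGES = (5.0, 15.0, 30.0)


def assign_height_class(height):
    """Height class: small [5, 15), medium [15, 30), large [30, inf) metres.

    The class bounds are half-open so every height >= 5 m falls in exactly
    one class; heights below the 5 m analysis floor are an error.
    """
    h = np.asarray(height, dtype=float)
    if (h < 5.0).any():
        raise ValueError("height below the 5 m analysis floor")
    out = np.where(h >= 30.0, "large", np.where(h >= 15.0, "medium", "small"))
    if np.isscalar(height) or out.ndim == 0:
        return str(out)
    return out


def build_records(statuses: dict, crowns: pd.DataFrame, env_fields: dict,
                  resolution_m: float) -> pd.DataFrame:
    """Assemble one row per tree from per-year crown statuses.

    `statuses` maps acquisition year -> boolean Series (True = dead) indexed
    by crown_id; years must share a common crown index (a crown missing from
    any year is an error). `crowns` provides max_height and centroid; the
    environmental covariates are sampled at the crown centroid by
    nearest-pixel lookup. dead -> live transitions are coerced to dead with
    a logged count. ``first_dead_year`` is the first acquisition at which
    the (coerced) status is dead, NaN if never.
    """
    years = sorted(statuses)
    ids = crowns["crown_id"].to_numpy()
    status_mat = np.zeros((len(ids), len(years)), dtype=bool)
    for j, y in enumerate(years):
        s = statuses[y]
        missing = set(ids) - set(s.index)
        if missing:
            raise ValueError(f"crowns missing from year {y}: {sorted(missing)[:10]}")
        status_mat[:, j] = s.loc[ids].to_numpy()
    coerced = np.maximum.accumulate(status_mat, axis=1)
    n_flicker = int((coerced & ~status_mat).sum())
    if n_flicker:
        logger.warning("coerced %d dead->live flickers to dead (absorbing state)",
                       n_flicker)
    first_dead = np.full(len(ids), np.nan)
    any_dead = coerced.any(axis=1)
    first_dead[any_dead] = np.asarray(years)[np.argmax(coerced[any_dead], axis=1)]

    env = sample_env_at(env_fields, crowns["centroid_x"].to_numpy(),
                        crowns["centroid_y"].to_numpy(), resolution_m)
    rec = pd.DataFrame({
        "tree_id": ids,
        "height": crowns["max_height"].to_numpy(),
    })
    rec["height_class"] = assign_height_class(rec["height"])
    rec = pd.concat([rec, env.reset_index(drop=True)], axis=1)
    for j, y in enumerate(years):
        rec[f"dead_{y}"] = coerced[:, j]
    rec["first_dead_year"] = first_dead
    rec.attrs["years"] = years
    rec.attrs["n_flicker_coerced"] = n_flicker
    return rec


def records_from_truth(landscape) -> pd.DataFrame:
    """Tree records straight from generator ground truth (no imagery step)."""
    trees = landscape.trees
    years = list(landscape.scenario.acquisition_years)
    rec = trees.rename(columns={"death_year": "first_dead_year"}).copy()
    rec = rec[rec["height"] >= 5.0].reset_index(drop=True)
    rec["height_class"] = assign_height_class(rec["height"])
    for y in years:
        rec[f"dead_{y}"] = np.isfinite(rec["first_dead_year"]) & (rec["first_dead_year"] <= y)
    rec.attrs["years"] = years
    return rec


def _grouping_key(records: pd.DataFrame, grouping):
    if grouping == "class":
        return records["height_class"], list(HEIGHT_CLASSES)
    if grouping == "bin":
        edges = np.floor(records["height"] / 5.0) * 5.0
        key = edges.astype(float)
        return key, sorted(key.unique())
    raise ValueError("grouping must be 'class' or 'bin'")


def mortality_summary(records: pd.DataFrame, years=None,
                      grouping: str = "class") -> pd.DataFrame:
    """Interval mortality percent, annualized rate, and cumulative mortality
    per height group.

    For each interval (y0, y1]: susceptible = trees not yet dead at y0;
    newly dead = susceptible trees dead at y1; percent = newly_dead /
    susceptible x 100; rate = percent / (y1 - y0) in % yr^-1 with a
    normal-approximation 95% CI; cumulative at y1 = total dead by y1 /
    initial population x 100. Groups with an empty susceptible pool get NaN
    rate and an ``undefined`` flag rather than 0.
    """
    if len(records) == 0:
        raise ValueError("no records")
    years = years if years is not None else records.attrs.get("years")
    if years is None:
        raise ValueError("acquisition years not provided")
    years = list(years)
    if years != sorted(set(years)):
        raise ValueError("years must be strictly increasing")
    key, groups = _grouping_key(records, grouping)
    fd = records["first_dead_year"].to_numpy()
    rows = []
    for g in groups:
        sel = (key == g).to_numpy()
        n0 = int(sel.sum())
        fdg = fd[sel]
        for y0, y1 in zip(years[:-1], years[1:]):
            susceptible = int((~(np.isfinite(fdg) & (fdg <= y0))).sum())
            newly = int((np.isfinite(fdg) & (fdg > y0) & (fdg <= y1)).sum())
            cum_dead = int((np.isfinite(fdg) & (fdg <= y1)).sum())
            dt = y1 - y0
            if susceptible == 0:
                pct = rate = ci = np.nan
                undefined = True
            else:
                p = newly / susceptible
                pct = p * 100.0
                rate = pct / dt
                ci = 1.96 * np.sqrt(p * (1 - p) / susceptible) * 100.0 / dt
                undefined = False
            rows.append({"group": g, "interval_start": y0, "interval_end": y1,
                         "n_susceptible": susceptible, "n_newly_dead": newly,
                         "percent_mortality": pct, "rate_pct_yr": rate,
                         "rate_ci95": ci,
                         "cumulative_pct": cum_dead / n0 * 100.0 if n0 else np.nan,
                         "n_initial": n0, "undefined": undefined})
    return pd.DataFrame(rows)
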