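"""Density-independent predictors: stage-windowed climate and topography.

Each generation of a bivoltine butterfly experiences climate through three
life-stage windows (egg, larvae/pupae, adult flight).  For the spring
generation these are overwinter (Dec-Mar), spring (Apr-May) and June; for
the summer generation June, July and August.  Four monthly climate
variables (mean/max/min temperature MT/AT/IT and precipitation PT) averaged
over each window give 12 climate predictors; elevation, slope, the
topographic solar-radiation index (trasp) and tree-canopy cover complete
the 16 density-independent candidates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLIMATE_VARS = ("MT", "AT", "IT", "PT")

#: life-stage windows per generation: label -> (list of months, december-from-previous-year?)
WINDOWS = {
    1: {"OW": ([12, 1, 2, 3], True), "SP": ([4, 5], False), "JN": ([6], False)},
    2: {"JN": ([6], False), "JL": ([7], False), "AG": ([8], False)},
}

#: lagged-density predictor labels: (lag1, lag2) per generation.
#: gen 1 of year y: lag1 = previous-year second generation (PS),
#: lag2 = previous-year first generation (PF).  gen 2 of year y:
#: lag1 = current-year first generation (CF), lag2 = previous-year second (PS).
LAG_LABELS = {1: ("PS", "PF"), 2: ("CF", "PS")}

TOPO_COLUMNS = ("Canopy", "Elevation", "Slope", "Trasp")


def climate_column_names(generation: int) -> list[str]:
    """The 12 stage-windowed climate predictor labels for a generation."""
    wins = WINDOWS[generation]
    return [f"{v}_{w}" for v in CLIMATE_VARS for w in wins]


def design_column_names(generation: int) -> list[str]:
    """The 18 candidate predictor labels, in report order."""
    return list(LAG_LABELS[generation]) + climate_column_names(generation) + list(TOPO_COLUMNS)


def trasp(aspect_deg):
    """Topographic solar-radiation index of a terrain aspect.

    A [0, 1] rescaling of the circular aspect (degrees clockwise from
    north): ``(1 - cos(pi/180 * (aspect - 30))) / 2``.  North-oriented
    slopes (30°) map to 0, south-oriented slopes (210°) to 1.  Flat cells
    (NaN aspect) get the neutral value 0.5.

    Parameters
    ----------
    aspect_deg : float or array-like
        Aspect in degrees; periodic with period 360.

    Returns
    -------
    float or ndarray in [0, 1].
    """
    a = np.asarray(aspect_deg, dtype=float)
    out = (1.0 - np.cos(np.pi / 180.0 * (a - 30.0))) / 2.0
    flat = np.isnan(a)
    if np.any(flat):
        logger.info("trasp: %d flat cells assigned neutral 0.5", int(np.sum(flat)))
        out = np.where(flat, 0.5, out)
    if np.ndim(aspect_deg) == 0:
        return float(out)
    return out


def window_means(climate: pd.DataFrame, generation: int,
                 pt_agg: str = "mean") -> pd.DataFrame:
    """Stage-windowed climate per site and year for one generation.

    Parameters
    ----------
    climate : DataFrame with columns site, year, month, MT, AT, IT, PT.
    generation : 1 or 2.
    pt_agg : "mean" (default) or "sum" — how precipitation is aggregated
        over multi-month windows; temperatures are always averaged.

    Returns
    -------
    DataFrame indexed by (site, year) with the 12 ``{var}_{window}``
    columns.  The overwinter window of generation 1 takes December from
    the *previous* calendar year, so year y requires Dec of y-1.  A window
    missing any constituent month is NaN (the row is excluded later).
    """
    if pt_agg not in ("mean", "sum"):
        raise ValueError(f"pt_agg must be 'mean' or 'sum', got {pt_agg!r}")
    clim = climate.copy()
    pieces = {}
    for wname, (months, dec_prev) in WINDOWS[generation].items():
        sub = clim[clim["month"].isin(months)].copy()
        if dec_prev:
            # December belongs to the following survey year's overwinter
            sub.loc[sub["month"] == 12, "year"] += 1
        grouped = sub.groupby(["site", "year"])
        n_months = grouped["month"].count()
        for var in CLIMATE_VARS:
            agg = "sum" if (var == "PT" and pt_agg == "sum") else "mean"
            vals = grouped[var].agg(agg)
            vals = vals.where(n_months == len(months))  # incomplete window -> NaN
            pieces[f"{var}_{wname}"] = vals
    out = pd.DataFrame(pieces)
    out.index.names = ["site", "year"]
    return out


def site_covariates(topo: pd.DataFrame) -> pd.DataFrame:
    """Per-site topographic/canopy predictors from a raw topo table.

    Expects columns site, elevation_m, slope_deg, aspect_deg, canopy_pct;
    returns site-indexed Canopy, Elevation, Slope, Trasp with aspect run
    through :func:`trasp`.
    """
    out = pd.DataFrame({
        "Canopy": topo["canopy_pct"].to_numpy(float),
        "Elevation": topo["elevation_m"].to_numpy(float),
        "Slope": topo["slope_deg"].to_numpy(float),
        "Trasp": trasp(topo["aspect_deg"].to_numpy(float)),
    }, index=pd.Index(topo["site"], name="site"))
    return out


def assemble_design(densities: pd.DataFrame, windowed: pd.DataFrame,
                    topo: pd.DataFrame, population: str | None,
                    generation: int):
    """Build the candidate design matrix for one population x generation.

    Parameters
    ----------
    densities : output of :func:`kbb_endoexo.surveys.process_surveys` —
        site/population/year/generation rows with lam, lag1/lag2 densities
        and an ``excluded`` flag.
    windowed : output of :func:`window_means` for this generation.
    topo : raw per-site topo table (see :func:`site_covariates`).
    population : population label to filter on, or None to pool every
        population ("All" model).
    generation : 1 or 2.

    Returns
    -------
    (ModelDataset, drop_log) where the dataset holds the raw (unstandardized)
     18-column design and the λ response, and ``drop_log`` is a dict of
    row-exclusion counts by reason.  Row conservation: eligible rows +
    dropped rows = candidate rows.
    """
    from .model import ModelDataset  # local import to avoid cycle

    lag1_label, lag2_label = LAG_LABELS[generation]
    cand = densities[densities["generation"] == generation].copy()
    if population is not None:
        cand = cand[cand["population"] == population]
    n_candidates = len(cand)
    drop_log = {"candidate_rows": n_candidates}

    n0 = len(cand)
    cand = cand[~cand["excluded"]]
    drop_log["missing_lag_or_lambda"] = n0 - len(cand)

    sc = site_covariates(topo)
    rows = cand.set_index(["site", "year"])
    X = pd.DataFrame(index=rows.index)
    X[lag1_label] = rows["lag1_density"]
    X[lag2_label] = rows["lag2_density"]
    X = X.join(windowed)
    X = X.join(sc, on="site")
    X = X[design_column_names(generation)]
    y = rows["lam"].rename("lambda")

    complete = X.notna().all(axis=1) & y.notna()
    drop_log["missing_covariate"] = int((~complete).sum())
    X, y = X[complete], y[complete]
    pops = rows.loc[complete, "population"]
    drop_log["eligible_rows"] = len(X)
    if len(X) == 0:
        first = ("missing_lag_or_lambda" if drop_log["missing_lag_or_lambda"] == n_candidates
                 else "missing_covariate")
        raise ValueError(f"no eligible rows for population={population!r} "
                         f"generation={generation}; first blocking filter: {first}")
    label = "All" if population is None else str(population)
    ds = ModelDataset(population=label, generation=generation, X=X, y=y,
                      population_labels=pops, drop_log=drop_log)
    return ds, drop_log


def sample_raster_at_sites(raster_path: str, lons, lats, band: int = 1):
    """Nearest-pixel values of a single-band georeferenced grid at site
    coordinates (coordinates in the grid's CRS).  Optional helper; requires
    :mod:`rasterio`, which is not a package dependency.
    """
    try:
        import rasterio
    except ImportError as exc:  # pragma: no cover
        raise ImportError("raster sampling requires the optional 'rasterio' package") from exc
    with rasterio.open(raster_path) as src:  # pragma: no cover
        return np.array([v[band - 1] for v in src.sample(zip(lons, lats))], dtype=float)
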