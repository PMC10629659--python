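"""Transect-count processing: counts -> densities -> growth rates -> lags.

Adults are counted on repeated transect walks during each of the two
flight periods.  Because survey effort (walks per flight period, transect
length) varies across sites and years, counts are first reduced to a mean
count per kilometer of transect per site x year x generation, then to a
density per hectare assuming one transect kilometer samples a 2.5-ha belt.
The per-generation growth rate λ is the density ratio between consecutive
generations, and the lagged densities PF/PS/CF become the two
density-dependent predictors of each generation's model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: hectares represented by one kilometer of transect
HA_PER_KM = 2.5

# Rough flight-period calendars used only for consistency warnings.
_FLIGHT_MONTHS = {1: (5, 6), 2: (7, 8)}


def mean_count_per_km(records: pd.DataFrame) -> float:
    """Mean over surveys of count per transect kilometer.

    ``records`` must hold the surveys of a single site x year x generation
    with columns ``count`` and ``transect_m``.  Empty input yields NaN
    (logged); the mean is order-independent.
    """
    if len(records) == 0:
        logger.warning("mean_count_per_km: empty survey list -> missing")
        return float("nan")
    if (records["transect_m"] <= 0).any():
        raise ValueError("transect_m must be positive")
    per_km = records["count"].to_numpy(float) / (records["transect_m"].to_numpy(float) / 1000.0)
    return float(per_km.mean())


def density_from_count(mean_per_km: float) -> float:
    """Adults per hectare implied by a mean transect count per km.

    One kilometer of transect is assumed to sample a 2.5-ha belt, so the
    density is ``mean_per_km / 2.5``.
    """
    arr = np.asarray(mean_per_km, dtype=float)
    if np.any(arr < 0):
        raise ValueError("mean count per km must be non-negative")
    out = arr / HA_PER_KM
    return float(out) if np.ndim(mean_per_km) == 0 else out


def growth_rate(current_density: float, previous_density: float,
                mode: str = "ratio") -> float:
    """Per-generation growth rate λ.

    ``mode="ratio"`` (default) gives current/previous, undefined (NaN)
    when the previous generation's density is zero or missing.
    ``mode="difference"`` gives current - previous (NaN only on missing
    input); kept as an explicit toggle since "density change" admits both
    readings.
    """
    if previous_density is None or np.isnan(previous_density):
        return float("nan")
    if current_density < 0 or previous_density < 0:
        raise ValueError("densities must be non-negative")
    if mode == "difference":
        return float(current_density - previous_density)
    if mode != "ratio":
        raise ValueError(f"unknown growth-rate mode {mode!r}")
    if previous_density == 0:
        return float("nan")
    return float(current_density / previous_density)


def _generation_sequence(df: pd.DataFrame) -> pd.DataFrame:
    """Order site rows by (year, generation) and index consecutively."""
    out = df.sort_values(["site", "year", "generation"]).reset_index(drop=True)
    dup = out.duplicated(["site", "year", "generation"])
    if dup.any():
        bad = out.loc[dup, ["site", "year", "generation"]].iloc[0]
        raise ValueError(f"duplicate site-year-generation row: {tuple(bad)}")
    return out


def attach_lags(densities: pd.DataFrame, lambda_mode: str = "ratio") -> pd.DataFrame:
    """Fill λ and the two lagged-density predictors per row.

    For a generation-1 row of year y: lag1 = previous-year second
    generation (PS), lag2 = previous-year first generation (PF), and λ is
    the growth from PS.  For a generation-2 row of year y: lag1 =
    current-year first generation (CF), lag2 = previous-year second
    generation (PS), and λ is the growth from CF.  Rows whose lags or λ
    cannot be formed (first year, gap years, zero previous density) are
    flagged ``excluded`` — models start from the second year.
    """
    df = _generation_sequence(densities)
    dens = df.set_index(["site", "year", "generation"])["density_per_ha"]

    def look(site, year, gen):
        return dens.get((site, year, gen), float("nan"))

    lag1 = np.empty(len(df))
    lag2 = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        if row.generation == 1:
            lag1[i] = look(row.site, row.year - 1, 2)   # PS
            lag2[i] = look(row.site, row.year - 1, 1)   # PF
        else:
            lag1[i] = look(row.site, row.year, 1)       # CF
            lag2[i] = look(row.site, row.year - 1, 2)   # PS
    df["lag1_density"] = lag1
    df["lag2_density"] = lag2
    df["lam"] = [growth_rate(d, p, mode=lambda_mode) if not np.isnan(p) else float("nan")
                 for d, p in zip(df["density_per_ha"], lag1)]
    df["excluded"] = df[["lag1_density", "lag2_density", "lam"]].isna().any(axis=1)
    n_exc = int(df["excluded"].sum())
    if n_exc:
        logger.info("attach_lags: %d of %d rows flagged (missing lag chain or zero "
                    "previous density)", n_exc, len(df))
    return df


def process_surveys(surveys: pd.DataFrame, lambda_mode: str = "ratio") -> pd.DataFrame:
    """Raw survey records -> per site x year x generation density table.

    ``surveys`` columns: site, population, date (ISO-8601 or datetime),
    generation (1|2), count, transect_m.  Returns one row per site x year x
    generation with mean_count_per_km, density_per_ha, lam, lag1_density,
    lag2_density and the ``excluded`` flag from :func:`attach_lags`.
    """
    df = surveys.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if (df["transect_m"] <= 0).any():
        raise ValueError("transect_m must be positive")
    _warn_generation_dates(df)

    per_km = df["count"] / (df["transect_m"] / 1000.0)
    g = df.assign(per_km=per_km).groupby(
        ["site", "population", "year", "generation"], as_index=False
    )["per_km"].mean()
    g = g.rename(columns={"per_km": "mean_count_per_km"})
    g["density_per_ha"] = density_from_count(g["mean_count_per_km"].to_numpy())
    return attach_lags(g, lambda_mode=lambda_mode)


def _warn_generation_dates(df: pd.DataFrame) -> None:
    months = df["date"].dt.month
    for gen, (lo, hi) in _FLIGHT_MONTHS.items():
        off = (df["generation"] == gen) & ~months.between(lo, hi)
        if off.any():
            logger.warning("%d generation-%d surveys dated outside the usual "
                           "flight months %d-%d", int(off.sum()), gen, lo, hi)


def read_supplementary_table(path: str) -> pd.DataFrame:
    """Read a pre-aggregated site-level table (XLSX or CSV).

    For datasets shipped as per-site-year densities rather than raw counts
    (population, site, year, generation, density columns), mapping straight
    onto the density table and bypassing count processing.  Column names
    are matched case-insensitively; a ``density`` column is required.
    """
    if str(path).endswith((".xlsx", ".xls")):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in raw.columns}
    required = ["population", "site", "year", "generation", "density"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"supplementary table missing columns: {missing}")
    out = pd.DataFrame({
        "site": raw[cols["site"]],
        "population": raw[cols["population"]],
        "year": raw[cols["year"]].astype(int),
        "generation": raw[cols["generation"]].astype(int),
        "density_per_ha": raw[cols["density"]].astype(float),
    })
    out["mean_count_per_km"] = out["density_per_ha"] * HA_PER_KM
    return attach_lags(out)
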