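"""Synthetic study-shaped data with known ground-truth parameters.

Emulates a multi-population transect-count survey of a bivoltine
butterfly: five populations, 48 permanent sites, 8-29 year spans, two
flight periods per year.  Monthly climate follows an upper-Midwest
seasonal cycle with site offsets and year-to-year noise; topography and
canopy are fixed per site.  Latent densities evolve by the same
endo-exogenous growth-rate equation the fitting module estimates,

    λ_t = β0 + β_lag1·(Y_{t-1}/s) + β_lag2·(Y_{t-2}/s) + Σ β_env·z(x) + N(0, σ),
    D_t = λ_t · Y_{t-1},

with environmental covariates standardized over the whole bundle (so
recovery tests compare like with like) and lag densities entering through
a fixed density scale s.  Observed counts are Poisson draws around the
expected number of adults on each transect walk, which makes the
count-to-density inversion unbiased.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import (TOPO_COLUMNS, climate_column_names, design_column_names,
                         site_covariates, window_means)
from .surveys import HA_PER_KM

logger = logging.getLogger(__name__)

N_ENV = 16  # climate (12) + topography/canopy (4) candidate predictors


@dataclass
class PopulationSpec:
    name: str
    n_sites: int
    first_year: int
    last_year: int


@dataclass
class StudyConfig:
    """Shape of a synthetic survey campaign.

    The default mirrors the real study configuration: central Wisconsin
    (CW) 14 sites 1990-2018, northwest Wisconsin (NW) 8 sites 2005-2013,
    Fort McCoy (FM) 12 sites 1997-2018, Indiana Dunes National Park
    (IDNP) 6 sites 1994-2011 and Albany Pine Bush Preserve (APBP) 8 sites
    2007-2018 — 48 sites total.
    """
    populations: list = field(default_factory=lambda: [
        PopulationSpec("CW", 14, 1990, 2018),
        PopulationSpec("NW", 8, 2005, 2013),
        PopulationSpec("FM", 12, 1997, 2018),
        PopulationSpec("IDNP", 6, 1994, 2011),
        PopulationSpec("APBP", 8, 2007, 2018),
    ])
    surveys_per_flight: int = 4
    transect_length_km_range: tuple = (0.3, 1.2)
    seed: int = 0

    def __post_init__(self):
        for p in self.populations:
            if p.n_sites < 1:
                raise ValueError(f"{p.name}: need >= 1 site")
            if p.last_year < p.first_year + 2:
                raise ValueError(f"{p.name}: span must cover >= 3 years (lags)")

    @property
    def n_sites(self) -> int:
        return sum(p.n_sites for p in self.populations)

    def site_table(self) -> pd.DataFrame:
        rows = [{"site": f"{p.name}-{i+1:02d}", "population": p.name,
                 "first_year": p.first_year, "last_year": p.last_year}
                for p in self.populations for i in range(p.n_sites)]
        return pd.DataFrame(rows)


@dataclass
class TruthParams:
    """Ground-truth coefficients of the generative growth-rate equation.

    ``beta_env`` aligns positionally with a generation's 16 environmental
    design columns (12 stage-windowed climate values then Canopy,
    Elevation, Slope, Trasp); zeros mark inactive variables.  Lag
    densities enter scaled by ``density_scale`` (individuals/ha), giving a
    stable equilibrium near density_scale·(beta0-1)/-(beta_lag1+beta_lag2).
    """
    beta0: float = 1.3
    beta_lag1: float = -0.25
    beta_lag2: float = -0.05
    beta_env: np.ndarray = field(default_factory=lambda: _default_beta_env())
    noise_sd: float = 0.15
    initial_density_range: tuple = (4.0, 25.0)
    density_scale: float = 10.0
    density_cap: float = 500.0

    def __post_init__(self):
        self.beta_env = np.asarray(self.beta_env, dtype=float)
        if self.beta_env.shape != (N_ENV,):
            raise ValueError(f"beta_env must have {N_ENV} entries")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def env_coef(self, generation: int) -> pd.Series:
        labels = climate_column_names(generation) + list(TOPO_COLUMNS)
        return pd.Series(self.beta_env, index=labels)

    def active_labels(self, generation: int) -> list:
        env = self.env_coef(generation)
        lag = design_column_names(generation)[:2]
        out = [l for l, b in zip(lag, (self.beta_lag1, self.beta_lag2)) if b != 0]
        return out + list(env.index[env != 0])

    def to_dict(self) -> dict:
        return {"beta0": self.beta0, "beta_lag1": self.beta_lag1,
                "beta_lag2": self.beta_lag2, "beta_env": list(map(float, self.beta_env)),
                "noise_sd": self.noise_sd,
                "initial_density_range": list(self.initial_density_range),
                "density_scale": self.density_scale, "density_cap": self.density_cap}


def _default_beta_env() -> np.ndarray:
    # a few active exogenous drivers: egg-window mean temperature (-),
    # larval-window precipitation (-), canopy (+)
    b = np.zeros(N_ENV)
    b[0] = -0.15   # MT over the egg window (OW for gen 1, JN for gen 2)
    b[10] = -0.10  # PT over the larval/pupal window
    b[12] = 0.08   # Canopy
    return b


@dataclass
class SyntheticBundle:
    """Everything one synthetic campaign produced, truth included."""
    surveys: pd.DataFrame
    climate: pd.DataFrame
    topo: pd.DataFrame
    truth: TruthParams
    latent: pd.DataFrame      # site x year x generation latent density and λ
    n_capped: int = 0

    def write(self, outdir) -> None:
        """surveys.csv, climate.csv, topo.csv, latent.csv + truth.json."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.surveys.to_csv(out / "surveys.csv", index=False)
        self.climate.to_csv(out / "climate.csv", index=False)
        self.topo.to_csv(out / "topo.csv", index=False)
        self.latent.to_csv(out / "latent.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=1)


def generate_monthly_climate(config: StudyConfig, seed: int | None = None) -> pd.DataFrame:
    """Monthly MT/AT/IT (°C) and PT (mm) per site.

    Seasonal cosine around an upper-Midwest annual cycle (July ≈ 22 °C,
    January ≈ -10 °C) plus a persistent site offset and year-month noise;
    the diurnal spread keeps IT < MT < AT by construction.  Precipitation
    is log-normal around ~65 mm/month.  Coverage runs from December of the
    year before each population's first survey year through August of its
    last year.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sites = config.site_table()
    rows = []
    for s in sites.itertuples(index=False):
        offset = rng.normal(0.0, 1.2)
        spread = rng.uniform(4.0, 7.0)
        for year, month in _month_span(s.first_year, s.last_year):
            base = 6.5 + 16.0 * np.cos(2.0 * np.pi * (month - 7) / 12.0)
            mt = base + offset + rng.normal(0.0, 1.8)
            half = spread + abs(rng.normal(0.0, 0.7))
            pt = float(np.exp(rng.normal(np.log(65.0), 0.45)))
            rows.append((s.site, year, month, mt, mt + half, mt - half, pt))
    return pd.DataFrame(rows, columns=["site", "year", "month", "MT", "AT", "IT", "PT"])


def _month_span(first_year: int, last_year: int):
    yield (first_year - 1, 12)
    for y in range(first_year, last_year):
        for m in range(1, 13):
            yield (y, m)
    for m in range(1, 9):
        yield (last_year, m)


def generate_topography(config: StudyConfig, seed: int | None = None) -> pd.DataFrame:
    """Fixed per-site elevation (150-500 m), slope (0-30°), aspect
    (0-360°) and canopy cover (0-100 %)."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    sites = config.site_table()
    n = len(sites)
    return pd.DataFrame({
        "site": sites["site"],
        "elevation_m": rng.uniform(150.0, 500.0, n),
        "slope_deg": rng.uniform(0.0, 30.0, n),
        "aspect_deg": rng.uniform(0.0, 360.0, n),
        "canopy_pct": rng.uniform(0.0, 100.0, n),
    })


def _standardized_env(climate: pd.DataFrame, topo: pd.DataFrame,
                      generation: int) -> pd.DataFrame:
    """Bundle-wide standardized environmental design, (site, year) indexed."""
    w = window_means(climate, generation)
    env = w.join(site_covariates(topo), on="site")
    env = env[climate_column_names(generation) + list(TOPO_COLUMNS)]
    env = env.dropna()
    sd = env.std(ddof=1)
    sd = sd.where(sd > 0, 1.0)
    return (env - env.mean()) / sd


def simulate_counts(config: StudyConfig, truth: TruthParams,
                    climate: pd.DataFrame | None = None,
                    topo: pd.DataFrame | None = None,
                    seed: int | None = None) -> SyntheticBundle:
    """Run the generative growth-rate model and observe it with transect counts.

    Both generations of each site's first year draw initial densities
    uniformly from ``truth.initial_density_range``; every later generation
    applies the λ equation (floored at 0, capped at ``truth.density_cap``
    with a log entry).  Each site gets ``surveys_per_flight`` walks per
    flight period on a per-site transect length; walk counts are
    Poisson(density × 2.5 ha/km × transect km).
    """
    master = config.seed if seed is None else seed
    if climate is None:
        climate = generate_monthly_climate(config, master)
    if topo is None:
        topo = generate_topography(config, master)
    rng = np.random.default_rng(np.random.SeedSequence([master, 2]))
    sites = config.site_table()
    env = {g: _standardized_env(climate, topo, g) for g in (1, 2)}
    beta_env = {g: truth.env_coef(g).to_numpy() for g in (1, 2)}
    lo, hi = config.transect_length_km_range
    s = truth.density_scale

    latent_rows, survey_rows = [], []
    n_capped = 0
    for st in sites.itertuples(index=False):
        transect_km = rng.uniform(lo, hi)
        dens = {}  # (year, generation) -> density
        d_init = rng.uniform(*truth.initial_density_range)
        for year in range(st.first_year, st.last_year + 1):
            for gen in (1, 2):
                if year == st.first_year:
                    # both first-year generations share one seed density
                    d = d_init
                    lam = np.nan
                else:
                    prev1 = dens[(year - 1, 2)] if gen == 1 else dens[(year, 1)]
                    prev2 = dens[(year - 1, 1)] if gen == 1 else dens[(year - 1, 2)]
                    x = env[gen].loc[(st.site, year)].to_numpy()
                    lam = (truth.beta0 + truth.beta_lag1 * prev1 / s
                           + truth.beta_lag2 * prev2 / s
                           + beta_env[gen] @ x
                           + rng.normal(0.0, truth.noise_sd))
                    lam = max(lam, 0.0)
                    d = lam * prev1
                    if d > truth.density_cap:
                        d = truth.density_cap
                        n_capped += 1
                dens[(year, gen)] = d
                latent_rows.append((st.site, st.population, year, gen, d, lam))
                month, day0 = (6, 5) if gen == 1 else (7, 18)
                nsurv = config.surveys_per_flight
                for k in range(nsurv):
                    # walks spread over a <=14-day window inside the flight period
                    offset = (14 * k) // nsurv if nsurv > 1 else 0
                    date = pd.Timestamp(year, month, day0) + pd.Timedelta(days=offset)
                    count = rng.poisson(d * HA_PER_KM * transect_km)
                    survey_rows.append((st.site, st.population, date.date().isoformat(),
                                        gen, int(count), round(transect_km * 1000.0, 1)))
    if n_capped:
        logger.warning("simulate_counts: %d site-generations hit the density cap "
                       "of %.0f/ha", n_capped, truth.density_cap)
    surveys = pd.DataFrame(survey_rows, columns=["site", "population", "date",
                                                 "generation", "count", "transect_m"])
    latent = pd.DataFrame(latent_rows, columns=["site", "population", "year",
                                                "generation", "density", "lam"])
    return SyntheticBundle(surveys=surveys, climate=climate, topo=topo,
                           truth=truth, latent=latent, n_capped=n_capped)


def make_design_dataset(n: int, generation: int = 1,
                        active: dict | None = None, beta0: float = 1.0,
                        noise_sd: float = 0.3, seed: int | None = None):
    """Directly simulate a standardized 18-column design with known betas.

    A design-level shortcut for estimator calibration: predictors are iid
    standard normal, the response is ``beta0 + Z @ beta + N(0, noise_sd)``
    with Z the sample-standardized design — so the returned truth is exact
    on the scale the fitting module estimates.

    Parameters
    ----------
    active : mapping of predictor label -> true standardized coefficient;
        default six active predictors of alternating sign.

    Returns
    -------
    (ModelDataset, truth) where truth is a Series over all 18 labels
    (zeros for inactive predictors).
    """
    from .model import ModelDataset
    labels = design_column_names(generation)
    if active is None:
        active = {"PS": -0.5, labels[1]: 0.5, "MT_OW" if generation == 1 else "MT_JN": -0.4,
                  "PT_SP" if generation == 1 else "PT_JL": 0.4,
                  "Canopy": 0.3, "Slope": -0.3}
    unknown = set(active) - set(labels)
    if unknown:
        raise ValueError(f"unknown predictor labels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, len(labels))), columns=labels)
    Z = (X - X.mean()) / X.std(ddof=1)
    truth = pd.Series(0.0, index=labels)
    for k, v in active.items():
        truth[k] = v
    y = beta0 + Z.to_numpy() @ truth.to_numpy() + rng.normal(0.0, noise_sd, n)
    ds = ModelDataset(population="SYN", generation=generation, X=X,
                      y=pd.Series(y, name="lambda"))
    return ds, truth
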