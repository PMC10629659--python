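"""Endo-exogenous growth-rate model: Model / Results objects.

The model regresses the per-generation growth rate λ on up to 18
standardized candidate predictors — two lagged densities (endogenous,
density-dependent) and 16 climate/topography covariates (exogenous,
density-independent):

    λ_t = β0 + β1·Y_{t-1} + β2·Y_{t-2} + β3·X1_t + ... + β17·X16_t + ε_t

Fitting proceeds in the pipeline order: a random-forest regression as a
robustness/importance baseline, genetic-algorithm subset selection by OLS
AIC, then jack-knife PLS on the selected subset for coefficients, standard
errors and p-values.  :class:`EndoExoModel` is built from data and its
``fit`` returns an :class:`EndoExoResults` carrying estimates,
uncertainties, diagnostics and a ``summary()`` table.  Pooled "All" models
across populations of very different series lengths are fitted with
stratified balanced bootstrapping (:func:`bootstrap_balanced_fit`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .pls import choose_components, jackknife_inference, pls_fit, star_code
from .selection import GAConfig, aic_of_subset, ga_select

logger = logging.getLogger(__name__)


@dataclass
class ModelDataset:
    """Design matrix and λ response for one population x generation.

    ``X`` holds the raw (unstandardized) candidate predictors with their
    report labels; ``population_labels`` (for pooled "All" datasets) maps
    each row to its source population.
    """
    population: str
    generation: int
    X: pd.DataFrame
    y: pd.Series
    population_labels: pd.Series | None = None
    drop_log: dict = field(default_factory=dict)

    @property
    def nobs(self) -> int:
        return len(self.y)


def standardize(X: pd.DataFrame):
    """Column z-scores with sample (n-1) standard deviations.

    Constant columns are dropped with a warning and recorded in the stats
    frame (sd = 0); an all-constant design is an error.

    Returns
    -------
    (Z, stats) : standardized DataFrame and a DataFrame with ``mean`` and
    ``sd`` per original column.
    """
    mean = X.mean()
    sd = X.std(ddof=1)
    stat = pd.DataFrame({"mean": mean, "sd": sd})
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are constant; nothing to standardize")
    dropped = list(X.columns[~keep])
    if dropped:
        logger.warning("standardize: dropped constant column(s) %s", dropped)
    Z = (X.loc[:, keep] - mean[keep]) / sd[keep]
    return Z, stat


def unstandardize(Z: pd.DataFrame, stat: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`standardize` for the retained columns."""
    sd = stat.loc[Z.columns, "sd"]
    mean = stat.loc[Z.columns, "mean"]
    return Z * sd + mean


class EndoExoModel:
    """Endo-exogenous λ model for one population x generation.

    Parameters
    ----------
    endog : array-like of growth rates λ.
    exog : DataFrame of raw candidate predictors (labels become report rows).
    population, generation : labels carried through to results.
    """

    def __init__(self, endog, exog: pd.DataFrame, population: str = "?",
                 generation: int = 1, population_labels=None):
        self.endog = pd.Series(np.asarray(endog, dtype=float), name="lambda")
        self.exog = pd.DataFrame(exog).reset_index(drop=True)
        self.endog.index = self.exog.index
        self.population = population
        self.generation = generation
        self.population_labels = (None if population_labels is None
                                  else pd.Series(list(population_labels), index=self.exog.index))
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")

    @classmethod
    def from_dataset(cls, ds: ModelDataset) -> "EndoExoModel":
        return cls(ds.y.to_numpy(), ds.X, population=ds.population,
                   generation=ds.generation, population_labels=ds.population_labels)

    def fit(self, ga_config: GAConfig | None = None, seed: int | None = None,
            rf_trees: int = 500, run_rf: bool = True,
            max_components: int = 10) -> "EndoExoResults":
        """Run RF baseline, GA-AIC selection and jack-knife PLS.

        Deterministic given ``seed``: one master seed fans out to the GA,
        the random forest and the component-selection folds through a
        ``numpy.random.SeedSequence`` spawn.
        """
        y = self.endog.to_numpy()
        if np.std(y) == 0:
            raise ValueError("zero-variance response (constant λ)")
        ga_seed, rf_seed, cv_seed = _spawn_seeds(seed, 3)
        Z, stat = standardize(self.exog)
        labels = list(Z.columns)
        Zv = Z.to_numpy()
        n = len(y)

        rf_oob_r2, rf_imp = None, None
        if run_rf:
            rf = RandomForestRegressor(n_estimators=rf_trees, oob_score=True,
                                       random_state=rf_seed, n_jobs=1)
            rf.fit(Zv, y)
            rf_oob_r2 = float(rf.oob_score_)
            perm = permutation_importance(rf, Zv, y, n_repeats=5,
                                          random_state=rf_seed, n_jobs=1)
            rf_imp = pd.Series(perm.importances_mean, index=labels,
                               name="rf_importance")

        cfg = ga_config or GAConfig()
        if cfg.seed is None:
            cfg = GAConfig(cfg.population_size, cfg.generations, cfg.crossover_rate,
                           cfg.mutation_rate, cfg.elitism_count, seed=ga_seed)
        mask, trace = ga_select(Zv, y, cfg)
        selected = [l for l, m in zip(labels, mask) if m]

        if not selected:
            return self._intercept_only(y, labels, stat, trace, rf_oob_r2, rf_imp)

        Xsel = Z[selected].to_numpy()
        ncomp = choose_components(Xsel, y, max_components=max_components, seed=cv_seed)
        b0, coefs = pls_fit(Xsel, y, ncomp)
        inf = jackknife_inference(Xsel, y, ncomp, labels=selected)
        yhat = b0 + Xsel @ coefs
        rss = float(np.sum((y - yhat) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / tss
        k = len(selected)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else np.nan
        return EndoExoResults(
            model=self, intercept=b0, params=inf["coef"], bse=inf["se"],
            tvalues=inf["t"], pvalues=inf["p"], stars=inf["stars"],
            rsquared=r2, rsquared_adj=adj, n_components=ncomp,
            selected=selected, candidates=labels, standardization=stat,
            aic_trace=trace, aic=aic_of_subset(Zv, y, mask),
            rf_oob_r2=rf_oob_r2, rf_importances=rf_imp, nobs=n)

    def _intercept_only(self, y, labels, stat, trace, rf_oob_r2, rf_imp):
        logger.warning("GA selected the empty subset; intercept-only model")
        empty = pd.Series(dtype=float)
        return EndoExoResults(
            model=self, intercept=float(np.mean(y)), params=empty, bse=empty,
            tvalues=empty, pvalues=empty, stars=pd.Series(dtype=object),
            rsquared=0.0, rsquared_adj=0.0, n_components=0, selected=[],
            candidates=labels, standardization=stat, aic_trace=trace,
            aic=aic_of_subset(np.empty((len(y), 0)), y), rf_oob_r2=rf_oob_r2,
            rf_importances=rf_imp, nobs=len(y))


@dataclass
class EndoExoResults:
    """Fitted endo-exogenous model: estimates, uncertainties, diagnostics.

    Coefficients are on the standardized-predictor scale.  Candidates the
    GA removed carry no coefficient and render blank in report tables.
    """
    model: EndoExoModel | None
    intercept: float
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    stars: pd.Series
    rsquared: float
    rsquared_adj: float
    n_components: int
    selected: list
    candidates: list
    standardization: pd.DataFrame
    aic_trace: np.ndarray
    aic: float
    rf_oob_r2: float | None
    rf_importances: pd.Series | None
    nobs: int
    n_bootstrap: int | None = None
    selection_frequency: pd.Series | None = None

    @property
    def population(self) -> str:
        return self.model.population if self.model is not None else "?"

    @property
    def generation(self) -> int:
        return self.model.generation if self.model is not None else 0

    def predict(self, exog: pd.DataFrame) -> np.ndarray:
        """Predicted λ for raw (unstandardized) predictor rows."""
        stat = self.standardization
        z = (exog[self.selected] - stat.loc[self.selected, "mean"]) / stat.loc[self.selected, "sd"]
        return self.intercept + z.to_numpy() @ self.params.to_numpy()

    def coef_cell(self, variable: str, digits: int = 3) -> str:
        """Report-table cell: ``coef±SE stars``, or '' if GA-removed."""
        if variable not in self.params.index:
            return ""
        return (f"{self.params[variable]:.{digits}f}±{self.bse[variable]:.{digits}f} "
                f"{self.stars[variable]}")

    def summary(self) -> str:
        lines = [
            "Endo-exogenous growth-rate model (jack-knife PLS)",
            "=" * 58,
            f"population: {self.population:<12s} generation: {self.generation}",
            f"nobs: {self.nobs:<6d} candidates: {len(self.candidates):<4d} "
            f"selected: {len(self.selected)}",
            f"PLS components: {self.n_components}   "
            f"R2: {self.rsquared:.3f}   adj. R2: {self.rsquared_adj:.3f}",
        ]
        if self.rf_oob_r2 is not None:
            lines.append(f"random-forest OOB R2: {self.rf_oob_r2:.3f}")
        if self.n_bootstrap is not None:
            lines.append(f"balanced bootstrap replicates: {self.n_bootstrap}")
        lines.append("-" * 58)
        lines.append(f"{'variable':<10s} {'coef':>9s} {'se':>9s} {'t/z':>8s} "
                     f"{'p':>9s}  sig")
        for v in self.params.index:
            lines.append(f"{v:<10s} {self.params[v]:>9.4f} {self.bse[v]:>9.4f} "
                         f"{self.tvalues[v]:>8.2f} {self.pvalues[v]:>9.2g}  "
                         f"{self.stars[v]}")
        if len(self.params) == 0:
            lines.append("(intercept-only: GA removed every candidate)")
        lines.append("-" * 58)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable record of the fit."""
        return {
            "population": self.population,
            "generation": int(self.generation),
            "nobs": int(self.nobs),
            "intercept": float(self.intercept),
            "selected": list(self.selected),
            "candidates": list(self.candidates),
            "coef": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "p": {k: float(v) for k, v in self.pvalues.items()},
            "stars": {k: str(v) for k, v in self.stars.items()},
            "rsquared": float(self.rsquared),
            "rsquared_adj": float(self.rsquared_adj),
            "n_components": int(self.n_components),
            "aic": float(self.aic),
            "aic_trace": [float(a) for a in np.asarray(self.aic_trace)],
            "rf_oob_r2": None if self.rf_oob_r2 is None else float(self.rf_oob_r2),
            "rf_importances": (None if self.rf_importances is None
                               else {k: float(v) for k, v in self.rf_importances.items()}),
            "n_bootstrap": self.n_bootstrap,
            "selection_frequency": (None if self.selection_frequency is None
                                    else {k: float(v) for k, v in self.selection_frequency.items()}),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def plot_coefficients(self, ax=None):
        """Horizontal coefficient plot with ±1 jack-knife SE bars."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.4 * max(4, len(self.params))))
        ypos = np.arange(len(self.params))
        ax.errorbar(self.params.to_numpy(), ypos, xerr=self.bse.to_numpy(),
                    fmt="o", capsize=3)
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(ypos, self.params.index)
        ax.set_xlabel("standardized coefficient")
        ax.set_title(f"{self.population} gen {self.generation}")
        return ax


def fit_population(dataset: ModelDataset, ga_config: GAConfig | None = None,
                   seed: int | None = None, min_rows: int = 10,
                   **fit_kwargs) -> EndoExoResults:
    """Fit one population x generation model from a ModelDataset.

    Raises ValueError when fewer than ``min_rows`` eligible rows remain or
    λ has no variance (callers log and skip).
    """
    if dataset.nobs < min_rows:
        raise ValueError(f"{dataset.population} gen {dataset.generation}: only "
                         f"{dataset.nobs} rows after exclusions (need >= {min_rows})")
    return EndoExoModel.from_dataset(dataset).fit(ga_config=ga_config, seed=seed,
                                                  **fit_kwargs)


def balanced_indices(rng: np.random.Generator, labels: pd.Series,
                     quota: int) -> np.ndarray:
    """Positional indices drawing ``quota`` rows per population label with
    replacement — the stratified balanced-bootstrap resample."""
    pos = np.arange(len(labels))
    chunks = [rng.choice(pos[np.asarray(labels) == lab], size=quota, replace=True)
              for lab in pd.unique(labels)]
    return np.concatenate(chunks)


def bootstrap_balanced_fit(dataset: ModelDataset, ga_config: GAConfig | None = None,
                           B: int = 50, quota: int | None = None,
                           seed: int | None = None,
                           max_components: int = 10) -> EndoExoResults:
    """Pooled "All" model via stratified balanced bootstrapping.

    Populations contribute very unequal numbers of site-year rows, so a
    naive pooled fit is dominated by the longest series.  Each of the B
    replicates resamples ``quota`` rows per population with replacement
    (default quota = smallest population's row count), then reruns GA
    selection and PLS.  A variable selected in at least half the
    replicates is reported, with coefficient = mean and SE = SD over the
    replicates that selected it, and a normal-approximation p-value.
    """
    labels = dataset.population_labels
    if labels is None or labels.nunique() < 2:
        raise ValueError("balanced bootstrap needs >= 2 populations in the pooled dataset")
    if B < 20:
        logger.warning("bootstrap_balanced_fit: B=%d < 20 gives unstable SEs", B)
    counts = labels.value_counts()
    if quota is None:
        quota = int(counts.min())
    y_all = dataset.y.to_numpy()
    X_all = dataset.X.reset_index(drop=True)
    lab_arr = labels.reset_index(drop=True)
    cand = list(X_all.columns)
    rep_seeds = _spawn_seeds(seed, B + 2)
    cv_seed, final_seed = rep_seeds[-2], rep_seeds[-1]
    cfg = ga_config or GAConfig()

    coef_rows = []
    for b in range(B):
        rng = np.random.default_rng(rep_seeds[b])
        idx = balanced_indices(rng, lab_arr, quota)
        Xb, yb = X_all.iloc[idx], y_all[idx]
        if np.std(yb) == 0:
            continue
        Zb, _ = standardize(Xb)
        cfg_b = GAConfig(cfg.population_size, cfg.generations, cfg.crossover_rate,
                         cfg.mutation_rate, cfg.elitism_count,
                         seed=int(rng.integers(2**31)))
        mask, _ = ga_select(Zb.to_numpy(), yb, cfg_b)
        sel = [l for l, m in zip(Zb.columns, mask) if m]
        row = pd.Series(np.nan, index=cand)
        if sel:
            Xsel = Zb[sel].to_numpy()
            a = choose_components(Xsel, yb, max_components=max_components,
                                  seed=int(rng.integers(2**31)))
            _, coefs = pls_fit(Xsel, yb, a)
            row[sel] = coefs
        coef_rows.append(row)
    reps = pd.DataFrame(coef_rows)
    freq = reps.notna().mean()
    keep = list(freq.index[freq >= 0.5])

    Z, stat = standardize(X_all)
    keep = [k for k in keep if k in Z.columns]
    if keep:
        coef = reps[keep].mean()
        se = reps[keep].std(ddof=1)
        z = coef / se
        p = pd.Series(2.0 * sps.norm.sf(np.abs(z)), index=keep)
        Xk = Z[keep].to_numpy()
        a = choose_components(Xk, y_all, max_components=max_components,
                              seed=int(cv_seed))
        b0, _ = pls_fit(Xk, y_all, a)
        yhat = b0 + Xk @ coef.to_numpy()
        rss = float(np.sum((y_all - yhat) ** 2))
        tss = float(np.sum((y_all - y_all.mean()) ** 2))
        r2 = 1.0 - rss / tss
        n, k = len(y_all), len(keep)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else np.nan
    else:
        coef = pd.Series(dtype=float)
        se = pd.Series(dtype=float)
        z = pd.Series(dtype=float)
        p = pd.Series(dtype=float)
        b0, a, r2, adj = float(np.mean(y_all)), 0, 0.0, 0.0

    mdl = EndoExoModel(y_all, X_all, population=dataset.population,
                       generation=dataset.generation, population_labels=lab_arr)
    return EndoExoResults(
        model=mdl, intercept=b0, params=coef, bse=se, tvalues=z, pvalues=p,
        stars=pd.Series([star_code(v) for v in p], index=p.index, dtype=object),
        rsquared=r2, rsquared_adj=adj, n_components=a, selected=keep,
        candidates=cand, standardization=stat,
        aic_trace=np.array([]), aic=float("nan"), rf_oob_r2=None,
        rf_importances=None, nobs=len(y_all), n_bootstrap=len(reps),
        selection_frequency=freq)


def _spawn_seeds(seed, n: int) -> list[int]:
    """Fan a master seed out to n child integer seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]
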