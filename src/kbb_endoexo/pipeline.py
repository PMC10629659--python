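"""End-to-end orchestration: generate/load -> process -> covariates -> fit -> report.

A run consumes either a synthetic campaign (generated in place with known
truth) or user-supplied surveys/climate/topo CSV tables, fits one model
per population x generation plus the pooled bootstrap-balanced "All"
models, and leaves a run directory with densities, design matrices,
fits.json, a coefficient report table per generation and a manifest
recording seeds, toggles, versions and every excluded row.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import assemble_design, design_column_names, window_means
from .model import bootstrap_balanced_fit, fit_population
from .selection import GAConfig
from .surveys import process_surveys
from .synthetic import StudyConfig, TruthParams, simulate_counts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One run's inputs, toggles and seeds.

    Either ``synthetic=True`` (a campaign is generated from
    ``study_config``/``truth``) or the three input CSV paths — never both.
    """
    out_dir: str = "run"
    synthetic: bool = True
    study_config: StudyConfig | None = None
    truth: TruthParams | None = None
    surveys_path: str | None = None
    climate_path: str | None = None
    topo_path: str | None = None
    ga: GAConfig = field(default_factory=GAConfig)
    bootstrap_B: int = 50
    bootstrap_quota: int | None = None
    seed: int = 0
    lambda_mode: str = "ratio"   # or "difference"
    pt_agg: str = "mean"         # or "sum"
    min_rows: int = 10
    rf_trees: int = 500

    def __post_init__(self):
        paths = (self.surveys_path, self.climate_path, self.topo_path)
        if self.synthetic and any(p is not None for p in paths):
            raise ValueError("give either synthetic=True or input paths, not both")
        if not self.synthetic and any(p is None for p in paths):
            raise ValueError("file-input runs need surveys, climate and topo paths")


def run(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    if config.synthetic:
        sc = config.study_config or StudyConfig(seed=int(rng_seeds[0]))
        truth = config.truth or TruthParams()
        bundle = simulate_counts(sc, truth, seed=int(rng_seeds[0]))
        bundle.write(out)
        surveys, climate, topo = bundle.surveys, bundle.climate, bundle.topo
    else:
        surveys = _read_required(config.surveys_path, "surveys")
        climate = _read_required(config.climate_path, "climate")
        topo = _read_required(config.topo_path, "topo")

    densities = process_surveys(surveys, lambda_mode=config.lambda_mode)
    densities.to_csv(out / "densities.csv", index=False)
    populations = list(pd.unique(densities["population"]))

    fits, drop_logs = [], {}
    for gen in (1, 2):
        windowed = window_means(climate, gen, pt_agg=config.pt_agg)
        for pop in [None] + populations:
            label = "All" if pop is None else pop
            try:
                ds, drop_log = assemble_design(densities, windowed, topo, pop, gen)
            except ValueError as exc:
                logger.warning("skipping %s gen %d: %s", label, gen, exc)
                drop_logs[f"{label}_gen{gen}"] = {"error": str(exc)}
                continue
            drop_logs[f"{label}_gen{gen}"] = drop_log
            ds.X.assign(**{"lambda": ds.y}).to_csv(out / f"design_{label}_gen{gen}.csv")
            try:
                if pop is None:
                    res = bootstrap_balanced_fit(
                        ds, ga_config=config.ga, B=config.bootstrap_B,
                        quota=config.bootstrap_quota, seed=int(rng_seeds[1]) + gen)
                else:
                    model_seed = (int(rng_seeds[2])
                                  + zlib.crc32(f"{label}:{gen}".encode()) % 10000)
                    res = fit_population(ds, ga_config=config.ga,
                                         seed=model_seed,
                                         min_rows=config.min_rows,
                                         rf_trees=config.rf_trees)
            except ValueError as exc:
                logger.warning("skipping fit %s gen %d: %s", label, gen, exc)
                drop_logs[f"{label}_gen{gen}"]["fit_error"] = str(exc)
                continue
            fits.append(res)

    with open(out / "fits.json", "w") as fh:
        json.dump([r.to_dict() for r in fits], fh, indent=1)
    for gen in (1, 2):
        table = coefficient_table([r for r in fits if r.generation == gen], gen)
        table.to_csv(out / f"coefficients_gen{gen}.csv")
        (out / f"coefficients_gen{gen}.md").write_text(table.to_markdown())

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "toggles": {"lambda_mode": config.lambda_mode, "pt_agg": config.pt_agg,
                    "synthetic": config.synthetic,
                    "bootstrap_B": config.bootstrap_B,
                    "bootstrap_quota": config.bootstrap_quota},
        "ga": {"population_size": config.ga.population_size,
               "generations": config.ga.generations,
               "crossover_rate": config.ga.crossover_rate,
               "mutation_rate": config.ga.mutation_rate,
               "elitism_count": config.ga.elitism_count},
        "versions": _library_versions(),
        "input_rows": int(len(surveys)),
        "row_accounting": drop_logs,
        "n_models": len(fits),
        "checksums": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
                      + sorted(out.glob("*.json")) if p.name != "run_manifest.json"},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def coefficient_table(fits, generation: int) -> pd.DataFrame:
    """Report table: candidate variables x populations, cells 'coef±SE stars'.

    Blank cells mark variables the GA removed from that model; the last
    row carries each model's adjusted R².
    """
    rows = design_column_names(generation)
    cols = sorted({r.population for r in fits}, key=lambda p: (p != "All", p))
    table = pd.DataFrame("", index=rows + ["Adj-R2"], columns=cols)
    for r in fits:
        for v in rows:
            table.loc[v, r.population] = r.coef_cell(v)
        table.loc["Adj-R2", r.population] = f"{r.rsquared_adj:.3f}"
    table.index.name = "variable"
    return table


def recovery_report(run_dir) -> pd.DataFrame:
    """Compare fitted models in a synthetic run directory against truth.

    Per model: precision/recall of the selected variable set against the
    generative active set, sign agreement of recovered active
    coefficients, and the RMSE between fitted and generative environmental
    coefficients (unselected = 0).
    """
    run_dir = Path(run_dir)
    truth_path = run_dir / "truth.json"
    if not truth_path.exists():
        raise FileNotFoundError(f"no truth.json in {run_dir}: not a synthetic run")
    truth = TruthParams(**{k: v for k, v in json.load(open(truth_path)).items()})
    fits = json.load(open(run_dir / "fits.json"))
    rows = []
    for f in fits:
        gen = f["generation"]
        active = set(truth.active_labels(gen))
        selected = set(f["selected"])
        tp = len(active & selected)
        precision = tp / len(selected) if selected else np.nan
        recall = tp / len(active) if active else np.nan
        truth_coef = pd.Series(0.0, index=f["candidates"])
        env = truth.env_coef(gen)
        truth_coef[env.index] = env
        lag1, lag2 = design_column_names(gen)[:2]
        truth_coef[lag1] = truth.beta_lag1
        truth_coef[lag2] = truth.beta_lag2
        fitted = pd.Series(0.0, index=f["candidates"])
        for k, v in f["coef"].items():
            fitted[k] = v
        hits = [v for v in active & selected]
        sign_agree = (np.mean([np.sign(fitted[v]) == np.sign(truth_coef[v]) for v in hits])
                      if hits else np.nan)
        rmse_env = float(np.sqrt(np.mean((fitted[env.index] - env) ** 2)))
        rows.append({"population": f["population"], "generation": gen,
                     "precision": precision, "recall": recall,
                     "sign_agreement": sign_agree, "rmse_env_coef": rmse_env})
    return pd.DataFrame(rows)


def _read_required(path, what: str) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return pd.read_csv(p)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _library_versions() -> dict:
    import sklearn
    import scipy
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__, "scipy": scipy.__version__}
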