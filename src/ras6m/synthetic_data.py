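"""Seeded generators emulating the statistical structure of each real input.

Three generators cover the pipeline's inputs:

* :func:`simulate_dose_response` — 4PL-shaped percent-growth readings for a
  panel of cell lines at the six standard screening concentrations
  (20, 10, 2, 1, 0.2, 0.1 uM) with replicate Gaussian noise;
* :func:`simulate_expression_ic50` — a log2 expression matrix in which a
  small subset of genes linearly determines IC50 plus Gaussian noise
  (emulating a 17-line screening cohort);
* :func:`simulate_survival_cohort` — an AML-style survival cohort whose
  hazard jumps by a specified ratio for patients at or above a true
  expression cutoff, with independent censoring.

Every generator is a pure function of its :class:`SimulationConfig` (seed
included): the same config yields byte-identical output files.  Ground
truth is written as sidecar TSVs so downstream checks never re-derive it
from code internals.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ras6m.dose_response import four_pl, inverse_four_pl

__all__ = [
    "SimulationConfig",
    "simulate_dose_response",
    "simulate_expression_ic50",
    "simulate_survival_cohort",
]

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the three generators, with study-scale defaults.

    Defaults mirror the study conditions: 17 cell lines screened at six
    concentrations in triplicate with ~5% growth noise; 9 candidate genes
    of which 3 truly drive IC50; 163 patients with hazard ratio 3 above
    the 40th-percentile expression cutoff and ~20% censoring.
    """

    seed: int = 0
    # dose-response
    n_cell_lines: int = 17
    concentrations: tuple[float, ...] = (20.0, 10.0, 2.0, 1.0, 0.2, 0.1)
    replicates: int = 3
    viability_noise_sd: float = 5.0  # percent growth
    drug: str = "DrugA"
    # expression -> IC50
    n_genes: int = 9
    n_true_predictors: int = 3
    coefficients: tuple[float, ...] = (2.0, -1.5, 1.0)
    intercept: float = 1.0
    expression_mean: float = 7.0
    expression_sd: float = 1.0
    ic50_noise_sd: float = 0.25  # uM
    # survival
    n_patients: int = 163
    biomarker_gene: str = "BIOMARK1"
    biomarker_mean: float = 8.0
    biomarker_sd: float = 1.5
    true_cutoff_percentile: float = 40.0
    hazard_ratio: float = 3.0
    baseline_hazard: float = 1.0 / 400.0  # events per day (low-risk group)
    censoring_fraction: float = 0.2

    def __post_init__(self) -> None:
        if min(self.n_cell_lines, self.replicates, self.n_genes, self.n_patients) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_true_predictors > self.n_genes:
            raise ValueError("n_true_predictors cannot exceed n_genes")
        if len(self.coefficients) != self.n_true_predictors:
            raise ValueError("need one coefficient per true predictor")
        if not self.hazard_ratio > 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must lie in [0, 1)")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("concentrations", "coefficients"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def _write(df: pd.DataFrame, path: Path, index: bool) -> None:
    sep = "," if path.suffix == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=index, float_format=_FLOAT_FMT)


def simulate_dose_response(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell-line 4PL viability data plus a ground-truth table.

    Each cell line draws a = 100, d ~ U[0, 30], c log-uniform over the
    tested dose range, b ~ U[0.5, 3]; percent growth at each dose and
    replicate is the 4PL value plus N(0, viability_noise_sd).  Returns
    (tidy measurements, truth table with parameters and closed-form IC50);
    written as ``dose_response.csv`` and ``dose_response_truth.tsv`` when
    ``out_dir`` is given.
    """
    rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.concentrations, dtype=float)
    rows = []
    truth = []
    for i in range(config.n_cell_lines):
        cell = f"CL{i + 1:03d}"
        a = 100.0
        d = rng.uniform(0.0, 30.0)
        c = float(np.exp(rng.uniform(np.log(doses.min()), np.log(doses.max()))))
        b = rng.uniform(0.5, 3.0)
        ic50 = inverse_four_pl(50.0, a, d, c, b)
        truth.append(
            {"cell_line": cell, "a": a, "d": d, "c": c, "b": b, "ic50": ic50}
        )
        for dose in doses:
            mu = four_pl(dose, a, d, c, b)
            for rep in range(1, config.replicates + 1):
                rows.append(
                    {
                        "cell_line": cell,
                        "drug": config.drug,
                        "concentration_uM": dose,
                        "replicate": rep,
                        "percent_growth": mu
                        + rng.normal(0.0, config.viability_noise_sd),
                    }
                )
    data = pd.DataFrame(rows)
    truth_df = pd.DataFrame(truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write(data, out / "dose_response.csv", index=False)
        _write(truth_df, out / "dose_response_truth.tsv", index=False)
    return data, truth_df


def simulate_expression_ic50(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a log2 expression matrix whose first genes drive IC50.

    Expression is Normal(expression_mean, expression_sd) per gene and
    sample; IC50 = intercept + sum coef_i * expr_i over the true
    predictors (genes G001..) plus N(0, ic50_noise_sd).  Returns
    (expression genes x samples, IC50 Series, truth table of per-term
    coefficients); files ``expression.tsv``, ``ic50.tsv``,
    ``expression_ic50_truth.tsv``.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:03d}" for i in range(config.n_genes)]
    samples = [f"CL{i + 1:03d}" for i in range(config.n_cell_lines)]
    expr = pd.DataFrame(
        rng.normal(
            config.expression_mean,
            config.expression_sd,
            size=(config.n_genes, config.n_cell_lines),
        ),
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )
    coefs = np.zeros(config.n_genes)
    coefs[: config.n_true_predictors] = config.coefficients
    ic50 = pd.Series(
        config.intercept
        + coefs @ expr.to_numpy()
        + rng.normal(0.0, config.ic50_noise_sd, size=config.n_cell_lines),
        index=samples,
        name="ic50",
    )
    truth = pd.DataFrame(
        {
            "term": ["intercept"] + genes,
            "coefficient": np.concatenate([[config.intercept], coefs]),
            "is_true_predictor": [False] + list(coefs != 0),
        }
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write(expr, out / "expression.tsv", index=True)
        ic50_df = ic50.rename_axis("cell_line").reset_index()
        ic50_df.insert(1, "drug", config.drug)
        _write(ic50_df, out / "ic50.tsv", index=False)
        _write(truth, out / "expression_ic50_truth.tsv", index=False)
    return expr, ic50, truth


def simulate_survival_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a survival cohort with a thresholded-expression hazard.

    One biomarker gene is drawn Normal(biomarker_mean, biomarker_sd);
    patients at or above the true cutoff (the configured percentile of the
    realized expression values) have exponential survival with hazard
    baseline_hazard * hazard_ratio, the rest with baseline_hazard.  A
    randomly chosen ``censoring_fraction`` of patients is censored at a
    uniform fraction of their event time.  Returns (survival table,
    expression matrix with one gene row, truth table); files
    ``survival.tsv``, ``survival_expression.tsv``, ``survival_truth.tsv``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients = [f"P{i + 1:04d}" for i in range(n)]
    expr_vals = rng.normal(config.biomarker_mean, config.biomarker_sd, size=n)
    cutoff = float(np.quantile(expr_vals, config.true_cutoff_percentile / 100.0))
    high = expr_vals >= cutoff
    hazard = np.where(high, config.baseline_hazard * config.hazard_ratio,
                      config.baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < config.censoring_fraction
    obs_time = np.where(censored, event_time * rng.uniform(0.0, 1.0, size=n),
                        event_time)
    obs_time = np.maximum(obs_time, 0.5)  # clock resolution: half a day

    surv = pd.DataFrame(
        {
            "sample_id": patients,
            "time_days": obs_time,
            "event": (~censored).astype(int),
        }
    )
    expr = pd.DataFrame(
        [expr_vals],
        index=pd.Index([config.biomarker_gene], name="gene"),
        columns=patients,
    )
    truth = pd.DataFrame(
        {
            "quantity": [
                "cutoff_value",
                "cutoff_percentile",
                "hazard_ratio",
                "baseline_hazard",
                "censoring_fraction",
            ],
            "value": [
                cutoff,
                config.true_cutoff_percentile,
                config.hazard_ratio,
                config.baseline_hazard,
                config.censoring_fraction,
            ],
        }
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write(surv, out / "survival.tsv", index=False)
        _write(expr, out / "survival_expression.tsv", index=True)
        _write(truth, out / "survival_truth.tsv", index=False)
    return surv, expr, truth
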