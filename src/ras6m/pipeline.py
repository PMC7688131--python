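"""End-to-end orchestration: filter -> 6M fit -> correlate -> best subsets
-> cross-validation -> LRMC -> prognostic classification.

Every intermediate is written as plain TSV/JSON and a manifest records the
configuration, seeds, thresholds, package version and a sha256 per output
file, so a rerun with the same config reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from contextlib import contextmanager
from pathlib import Path

import pandas as pd
import yaml

from ras6m import __version__, dose_response, expression, regression, survival

__all__ = ["PipelineError", "PipelineStageError", "PipelineConfig", "run_pipeline"]


class PipelineError(ValueError):
    pass


class PipelineStageError(PipelineError):
    """Wraps a stage failure with the stage name and offending detail."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclasses.dataclass
class PipelineConfig:
    """Declarative pipeline configuration (mirrors the YAML layout).

    Sections are optional: only the analyses whose inputs are configured
    run.  ``dose_response``, ``expression``, ``regression`` and
    ``survival`` are plain dicts; see the README for the schema.
    """

    output_dir: str
    seed: int = 0
    icxx_convention: str = "growth"
    dose_response: dict | None = None
    expression: dict | None = None
    regression: dict | None = None
    survival: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "output_dir" not in raw:
            raise PipelineError("pipeline config must be a mapping with output_dir")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for section in (self.dose_response, self.expression,
                        self.regression, self.survival):
            if not section:
                continue
            for key in ("input", "matrix", "gene_map", "ic50", "table", "expression"):
                path = section.get(key)
                if path is not None and not Path(path).exists():
                    raise PipelineError(f"input file not found: {path}")


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns {artifact name: path or object}.

    Stages abort with :class:`PipelineStageError` naming the failing stage.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        written.append(path)
        return path

    ic50_series = None
    matrix = None

    if config.dose_response:
        with _stage("dose_response"):
            sec = config.dose_response
            plate = dose_response.read_plate_csv(
                sec["input"], pre_normalized=sec.get("pre_normalized", False)
            )
            drugs = sec.get("drugs") or sorted(set(plate["drug"]))
            fits = pd.concat(
                [
                    dose_response.fit_plate(
                        plate,
                        drug=d,
                        average_replicates=sec.get("average_replicates", False),
                        convention=config.icxx_convention,
                    )
                    for d in drugs
                ],
                ignore_index=True,
            )
            results["fits"] = save(fits, "fits.tsv")
            selected = fits[fits["selected"]]
            ic50_tab = selected[["cell_line", "drug", "ic50"]].dropna()
            results["ic50"] = save(ic50_tab, "ic50_6m.tsv")
            ic50_series = ic50_tab.set_index("cell_line")["ic50"]

    if config.expression:
        with _stage("expression"):
            sec = config.expression
            gene_map = (
                expression.read_gene_map(sec["gene_map"])
                if sec.get("gene_map")
                else None
            )
            matrix = expression.read_expression_matrix(sec["matrix"], gene_map)
            filt = sec.get("filter") or {}
            if filt.get("enabled", True):
                report = expression.variance_filter(
                    matrix,
                    var_min=filt.get("var_min", 0.8),
                    mean_min=filt.get("mean_min", 5.5),
                    range_min=filt.get("range_min", 3.0),
                )
                results["filter_report"] = save(report, "filter_report.tsv", index=True)
                matrix = expression.filter_probes(matrix, report)
            if matrix.gene_map:
                matrix = expression.collapse_probesets(matrix)
            save(matrix.values, "expression_filtered.tsv", index=True)
            results["expression"] = matrix

    if config.regression:
        with _stage("regression"):
            sec = config.regression
            if matrix is None:
                raise PipelineError("regression requires the expression section")
            drug = sec.get("drug")
            if sec.get("ic50"):
                ic50_series = regression.read_ic50_table(sec["ic50"], drug=drug)
            if ic50_series is None:
                raise PipelineError("no IC50 source configured")
            shared = [s for s in matrix.sample_ids if s in ic50_series.index]
            y = ic50_series.loc[shared]
            corr = expression.correlate_with_response(matrix, y)
            results["correlations"] = save(corr, "correlations.tsv", index=True)
            candidates = sec.get("candidates") or list(
                corr["r"].abs().sort_values(ascending=False).head(9).index
            )
            X = matrix.values.loc[candidates, shared].T
            subsets = regression.best_subsets(X, y)
            model = subsets.best
            cv = regression.cross_validate(
                X,
                y,
                n_repeats=sec.get("cv_repeats", 10),
                discovery_n=sec.get("discovery_n", 12),
                test_n=sec.get("test_n", 5),
                seed=config.seed,
            )
            model_json = {
                "drug": drug,
                "formula": model.formula(),
                "intercept": model.intercept,
                "coefficients": model.coefficients,
                "r2": model.r2,
                "r2_adj": model.r2_adj,
                "n": model.n,
                "cv_mean_discovery_r2_adj": cv.mean_discovery_r2_adj,
                "cv_mean_test_r_sq": cv.mean_test_r_sq,
                "cv_mean_test_sy_x": cv.mean_test_sy_x,
            }
            path = out / "model.json"
            path.write_text(json.dumps(model_json, indent=2, sort_keys=True))
            written.append(path)
            results["model"] = model
            results["cv"] = cv

    if config.survival:
        with _stage("survival"):
            sec = config.survival
            surv = survival.read_survival_table(sec["table"])
            surv_expr = expression.read_expression_matrix(sec["expression"])
            shared = [s for s in surv["sample_id"] if s in surv_expr.sample_ids]
            surv = surv.set_index("sample_id").loc[shared]
            cutoffs: dict[str, float] = {}
            scans = []
            for gene in sec.get("genes", list(surv_expr.values.index)):
                if gene not in surv_expr.values.index:
                    raise PipelineError(f"gene {gene!r} absent from survival expression")
                scan = survival.lrmc_scan(
                    surv["time_days"],
                    surv["event"],
                    surv_expr.values.loc[gene, shared],
                    min_group_size=sec.get("min_group_size", 3),
                )
                cutoffs[gene] = scan.selected_cutoff
                tab = scan.table.copy()
                tab.insert(0, "gene", gene)
                scans.append(tab)
                results[f"scan_{gene}"] = scan
            results["scans"] = save(pd.concat(scans, ignore_index=True), "lrmc_scans.tsv")
            classify = sec.get("classify")
            if classify:
                labels = survival.classify_cohort(
                    surv_expr.values[shared],
                    cutoffs,
                    good_high=classify.get("good_high", ("IGF2R", "CTSA")),
                    good_low=classify.get("good_low", ("ATP6AP2",)),
                )
                results["prognosis"] = save(
                    labels.rename_axis("sample_id").reset_index(), "prognosis.tsv"
                )
                good = labels == "Good"
                if good.any() and (~good).any():
                    lr = survival.logrank_test(
                        surv.loc[good[good].index, "time_days"],
                        surv.loc[good[good].index, "event"],
                        surv.loc[good[~good].index, "time_days"],
                        surv.loc[good[~good].index, "event"],
                    )
                    results["prognosis_logrank"] = lr

    with _stage("manifest"):
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "outputs": {p.name: _sha256(p) for p in sorted(written)},
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        results["manifest"] = path
    return results
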