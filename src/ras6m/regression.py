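"""Expression-to-IC50 linear modelling.

Ordinary least-squares fitting, exhaustive best-subsets predictor selection
ranked by adjusted R², prediction by the regression formula
``y = a + n1*x1 + n2*x2 + ...``, the Sy.x goodness-of-fit measure, and
repeated random discovery/test splitting of a cohort.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegressionError",
    "CollinearityError",
    "RegressionModel",
    "GoodnessOfFit",
    "SplitScheme",
    "BestSubsetsResult",
    "CrossValidationResult",
    "fit_linear",
    "best_subsets",
    "predict_from_model",
    "goodness_of_fit",
    "cross_validate",
    "range_spanning_split",
    "read_ic50_table",
]


class RegressionError(ValueError):
    pass


class CollinearityError(RegressionError):
    def __init__(self, predictors):
        self.predictors = list(predictors)
        super().__init__(f"collinear predictors: {self.predictors}")


@dataclass(frozen=True)
class RegressionModel:
    """An OLS model: intercept plus named per-gene coefficients."""

    intercept: float
    coefficients: dict[str, float]
    r2: float
    r2_adj: float
    n: int
    k: int

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def formula(self) -> str:
        terms = [f"{self.intercept:+.4g}"]
        terms += [f"{c:+.4g}*{name}" for name, c in self.coefficients.items()]
        return "y = " + " ".join(terms)


@dataclass(frozen=True)
class GoodnessOfFit:
    """Squared Pearson r between observed and predicted, and Sy.x.

    Sy.x = sqrt(sum (obs - pred)^2 / (n - 2)), the standard deviation of
    the residuals.
    """

    r_sq: float
    sy_x: float


@dataclass(frozen=True)
class SplitScheme:
    discovery_ids: tuple
    test_ids: tuple
    seed: int | None
    mode: str  # "random" | "range-spanning"


@dataclass(frozen=True)
class BestSubsetsResult:
    best: RegressionModel
    by_size: dict[int, RegressionModel]
    n_enumerated: int
    skipped: list[tuple[str, ...]] = field(default_factory=list)


@dataclass(frozen=True)
class CrossValidationResult:
    splits: list[SplitScheme]
    models: list[RegressionModel]
    test_fits: list[GoodnessOfFit]
    mean_discovery_r2_adj: float
    mean_test_r_sq: float
    mean_test_sy_x: float


def _design(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name columns that add no rank to the design (greedy scan)."""
    cols: list[str] = []
    kept = np.ones((len(X), 1))
    for name in X.columns:
        trial = np.column_stack([kept, X[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(trial) == np.linalg.matrix_rank(kept):
            cols.append(name)
        else:
            kept = trial
    return cols


def fit_linear(X: pd.DataFrame, y: pd.Series) -> RegressionModel:
    """Ordinary least squares of the response on the predictor columns.

    Requires n > k + 1 and a full-column-rank design.
    adjusted R² = 1 - (1 - R²)(n - 1)/(n - k - 1).
    """
    X = pd.DataFrame(X)
    y_arr = np.asarray(y, dtype=float)
    n, k = X.shape
    if len(y_arr) != n:
        raise RegressionError("X and y disagree on sample count")
    if n <= k + 1:
        raise RegressionError(f"need n > k + 1 samples (n={n}, k={k})")
    design = _design(X)
    if np.linalg.matrix_rank(design) < k + 1:
        raise CollinearityError(_collinear_columns(X))
    beta, *_ = np.linalg.lstsq(design, y_arr, rcond=None)
    fitted = design @ beta
    rss = float(np.sum((y_arr - fitted) ** 2))
    tss = float(np.sum((y_arr - y_arr.mean()) ** 2))
    if tss == 0:
        raise RegressionError("response is constant; R^2 undefined")
    r2 = min(max(1.0 - rss / tss, 0.0), 1.0)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return RegressionModel(
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(X.columns, beta[1:])},
        r2=r2,
        r2_adj=float(r2_adj),
        n=n,
        k=k,
    )


def best_subsets(
    X: pd.DataFrame, y: pd.Series, max_predictors: int = 20
) -> BestSubsetsResult:
    """Exhaustive all-subsets regression, ranked by adjusted R².

    Enumerates every non-empty predictor subset (2^m - 1 of them), fits
    OLS on each, and returns the per-size winners plus the overall winner
    with the highest adjusted R² (ties: fewer predictors, then
    lexicographic predictor names).  Rank-deficient subsets are skipped
    with a warning; more than ``max_predictors`` candidates is refused.
    """
    X = pd.DataFrame(X)
    m = X.shape[1]
    if m == 0:
        raise RegressionError("no candidate predictors")
    if m > max_predictors:
        raise RegressionError(
            f"{m} candidates exceed the combinatorial guard ({max_predictors})"
        )
    names = list(X.columns)
    by_size: dict[int, RegressionModel] = {}
    best: RegressionModel | None = None
    skipped: list[tuple[str, ...]] = []
    n_enumerated = 0

    def better(a: RegressionModel, b: RegressionModel | None) -> bool:
        if b is None:
            return True
        return (-a.r2_adj, a.k, a.predictors) < (-b.r2_adj, b.k, b.predictors)

    for size in range(1, m + 1):
        for combo in itertools.combinations(names, size):
            n_enumerated += 1
            try:
                model = fit_linear(X[list(combo)], y)
            except CollinearityError:
                skipped.append(combo)
                continue
            if better(model, by_size.get(size)):
                by_size[size] = model
            if better(model, best):
                best = model
    if best is None:
        raise RegressionError("every subset was rank deficient")
    if skipped:
        warnings.warn(f"skipped {len(skipped)} rank-deficient subsets", stacklevel=2)
    return BestSubsetsResult(
        best=best, by_size=by_size, n_enumerated=n_enumerated, skipped=skipped
    )


def predict_from_model(model: RegressionModel, X_new: pd.DataFrame) -> pd.Series:
    """Apply the regression formula: y = intercept + sum coef_i * x_i."""
    X_new = pd.DataFrame(X_new)
    missing = [p for p in model.predictors if p not in X_new.columns]
    if missing:
        raise RegressionError(f"missing predictors: {missing}")
    coef = np.array([model.coefficients[p] for p in model.predictors])
    vals = X_new[list(model.predictors)].to_numpy(dtype=float)
    return pd.Series(model.intercept + vals @ coef, index=X_new.index, name="predicted")


def goodness_of_fit(observed, predicted) -> GoodnessOfFit:
    """Sy.x and squared Pearson r between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise RegressionError("observed and predicted must be 1-d and equal length")
    n = len(obs)
    if n < 3:
        raise RegressionError("need at least 3 pairs")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise RegressionError("constant observed or predicted: r^2 undefined")
    sy_x = float(np.sqrt(np.sum((obs - pred) ** 2) / (n - 2)))
    r = float(np.corrcoef(obs, pred)[0, 1])
    return GoodnessOfFit(r_sq=min(r * r, 1.0), sy_x=sy_x)


def range_spanning_split(
    y: pd.Series, discovery_n: int = 12, test_n: int = 5
) -> SplitScheme:
    """Deterministic split covering the response range in both groups.

    Samples are ranked by response; evenly spaced ranks (including the
    extremes) go to the test group, so both groups span the sensitivity
    range.  A deterministic stand-in for a manual range-spanning choice.
    """
    y = pd.Series(y)
    n = len(y)
    if n != discovery_n + test_n:
        raise RegressionError("cohort size must equal discovery_n + test_n")
    order = y.sort_values(kind="mergesort").index
    ranks = np.unique(np.round(np.linspace(0, n - 1, test_n)).astype(int))
    test_ids = tuple(order[i] for i in ranks)
    discovery_ids = tuple(i for i in y.index if i not in set(test_ids))
    return SplitScheme(discovery_ids, test_ids, seed=None, mode="range-spanning")


def cross_validate(
    X: pd.DataFrame,
    y: pd.Series,
    n_repeats: int = 10,
    discovery_n: int = 12,
    test_n: int = 5,
    seed: int = 0,
    subset_search: bool = False,
) -> CrossValidationResult:
    """Repeated random discovery/test splits with refitting.

    Each repeat samples ``discovery_n`` samples without replacement for
    model fitting (all predictors, or the best-subsets winner when
    ``subset_search=True``) and evaluates the regression formula on the
    held-out ``test_n`` samples.  Reports the mean discovery-fit adjusted
    R² (the figure of merit) alongside held-out r² and Sy.x.  Reproducible
    for a given seed.
    """
    X = pd.DataFrame(X)
    y = pd.Series(y)
    n = len(y)
    if n != discovery_n + test_n:
        raise RegressionError(
            f"cohort size {n} != discovery_n + test_n = {discovery_n + test_n}"
        )
    rng = np.random.default_rng(seed)
    splits: list[SplitScheme] = []
    models: list[RegressionModel] = []
    test_fits: list[GoodnessOfFit] = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        disc = tuple(y.index[i] for i in perm[:discovery_n])
        test = tuple(y.index[i] for i in perm[discovery_n:])
        splits.append(SplitScheme(disc, test, seed=seed, mode="random"))
        X_disc, y_disc = X.loc[list(disc)], y.loc[list(disc)]
        if subset_search:
            model = best_subsets(X_disc, y_disc).best
        else:
            model = fit_linear(X_disc, y_disc)
        models.append(model)
        pred = predict_from_model(model, X.loc[list(test)])
        test_fits.append(goodness_of_fit(y.loc[list(test)], pred))
    return CrossValidationResult(
        splits=splits,
        models=models,
        test_fits=test_fits,
        mean_discovery_r2_adj=float(np.mean([m.r2_adj for m in models])),
        mean_test_r_sq=float(np.mean([g.r_sq for g in test_fits])),
        mean_test_sy_x=float(np.mean([g.sy_x for g in test_fits])),
    )


def read_ic50_table(path, drug: str | None = None) -> pd.Series:
    """Read a tidy IC50 TSV (cell_line, [drug,] ic50) into a Series."""
    df = pd.read_csv(path, sep="\t")
    if "cell_line" not in df.columns or "ic50" not in df.columns:
        raise RegressionError("IC50 table needs cell_line and ic50 columns")
    if drug is not None and "drug" in df.columns:
        df = df[df["drug"] == drug]
        if df.empty:
            raise RegressionError(f"no IC50 rows for drug {drug!r}")
    return df.set_index("cell_line")["ic50"].astype(float)
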