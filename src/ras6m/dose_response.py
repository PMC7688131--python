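"""Six-model (6M) dose-response fitting and derived cytotoxicity metrics.

Percent growth of drug-treated cells is modelled as a four-parameter
logistic (4PL) function of the arithmetic drug concentration ``X``::

    Y(X) = d + (a - d) / (1 + (X / c) ** b)

where ``a`` is the percent growth of untreated cells (the zero-dose
asymptote), ``d`` the percent growth at infinite dose, ``c`` the dose at
which growth is exactly midway between ``a`` and ``d``, and ``b`` the Hill
slope controlling the steepness of the curve.

The 6M procedure fits six constrained variants of this curve to the same
data — the free 4P model, top fixed at ``a = 100``, bottom fixed at
``d = 0``, each with and without a free Hill slope (the 3P variants fix
``b = 1``) — and keeps the fit with the lowest residual standard error
``sqrt(RSS / (n - p))``, where ``p`` counts the free parameters of the
variant.  Derived drug-response metrics (IC50/IC90/IC95, EC50, Amax,
Activity Area) are computed from the selected fit in closed form.

ICxx here is, by default, the dose at which *predicted percent growth*
equals xx (so IC90 sits on the shallow upper part of a killing curve); the
conventional percent-*inhibition* reading is available through
``convention="inhibition"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DoseResponseError",
    "ControlWellError",
    "DegenerateDataError",
    "InsufficientDataError",
    "NoConvergedFitError",
    "DoseResponsePoint",
    "ModelVariant",
    "MODEL_VARIANTS",
    "FourPLFit",
    "ResponseMetrics",
    "SixModelFit",
    "four_pl",
    "inverse_four_pl",
    "normalize_growth",
    "predict_growth",
    "points_from_arrays",
    "fit_variant",
    "fit_all_variants",
    "fit_6m",
    "fit_6m_detailed",
    "response_metrics",
    "read_plate_csv",
    "fit_plate",
]


class DoseResponseError(ValueError):
    """Base class for dose-response errors."""


class ControlWellError(DoseResponseError):
    """Untreated-control signal unusable (non-positive after blank)."""


class DegenerateDataError(DoseResponseError):
    """Data cannot identify the requested curve (e.g. constant growth)."""


class InsufficientDataError(DoseResponseError):
    """Fewer points than free parameters + 1, or < 2 distinct doses."""


class NoConvergedFitError(DoseResponseError):
    """No model variant converged; carries per-variant failure reasons."""

    def __init__(self, failures: Mapping[str, str]):
        self.failures = dict(failures)
        msg = "; ".join(f"{k}: {v}" for k, v in self.failures.items())
        super().__init__(f"no model variant converged ({msg})")


@dataclass(frozen=True)
class DoseResponsePoint:
    """One measurement: arithmetic dose (uM) and percent growth.

    Growth may exceed 100 or fall below 0 after normalization.
    """

    concentration: float
    growth: float

    def __post_init__(self) -> None:
        if not (self.concentration > 0 and math.isfinite(self.concentration)):
            raise DoseResponseError(
                f"concentration must be positive and finite, got {self.concentration!r}"
            )
        if not math.isfinite(self.growth):
            raise DoseResponseError(f"growth must be finite, got {self.growth!r}")


@dataclass(frozen=True)
class ModelVariant:
    """One of the six constrained 4PL variants."""

    name: str
    fixed_a: float | None
    fixed_d: float | None
    fit_slope: bool

    @property
    def n_free(self) -> int:
        """Number of free parameters (1-4)."""
        return (
            2
            - (self.fixed_a is not None)
            - (self.fixed_d is not None)
            + 1  # c is always free
            + (1 if self.fit_slope else 0)
        )


#: The six variants, in canonical order (3P family first, then 4P family).
MODEL_VARIANTS: dict[str, ModelVariant] = {
    "3P": ModelVariant("3P", None, None, False),
    "3P-Top100": ModelVariant("3P-Top100", 100.0, None, False),
    "3P-Bottom0": ModelVariant("3P-Bottom0", None, 0.0, False),
    "4P": ModelVariant("4P", None, None, True),
    "4P-Top100": ModelVariant("4P-Top100", 100.0, None, True),
    "4P-Bottom0": ModelVariant("4P-Bottom0", None, 0.0, True),
}

_VARIANT_ORDER = {name: i for i, name in enumerate(MODEL_VARIANTS)}


@dataclass(frozen=True)
class FourPLFit:
    """A fitted 4PL curve under one variant's constraints.

    ``rse`` is the residual standard error sqrt(RSS / (n - p)) in percent
    growth units, with ``p`` the variant's free-parameter count.
    ``informative`` is False for flat fits (|a - d| ~ 0), which carry no
    dose-response information.
    """

    variant: ModelVariant
    a: float
    d: float
    c: float
    b: float
    rse: float
    n_points: int
    converged: bool
    rss: float = math.nan
    dose_min: float = math.nan
    dose_max: float = math.nan

    @property
    def informative(self) -> bool:
        return abs(self.a - self.d) > 1e-6


@dataclass(frozen=True)
class ResponseMetrics:
    """Drug-response metrics derived from a fitted curve.

    ``ic50``/``ic90``/``ic95`` are ``None`` when the target growth level is
    not reached by the curve (outside the open interval between the two
    asymptotes).  ``activity_area`` is the plain sum of predicted growth
    values over the inclusive arithmetic dose grid with step 0.01 uM (a
    discrete area-under-curve surrogate, not scaled by the step).
    """

    ic50: float | None
    ic90: float | None
    ic95: float | None
    ec50: float
    amax: float
    activity_area: float
    convention: str = "growth"


@dataclass(frozen=True)
class SixModelFit:
    """Result of fitting all six variants: the winner plus every fit."""

    selected: FourPLFit
    fits: dict[str, FourPLFit]
    failures: dict[str, str] = field(default_factory=dict)


def four_pl(x, a: float, d: float, c: float, b: float):
    """Evaluate the 4PL curve Y = d + (a - d) / (1 + (X/c)^b)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        val = d + (a - d) / (1.0 + (x / c) ** b)
    return val if val.ndim else float(val)


def inverse_four_pl(target: float, a: float, d: float, c: float, b: float) -> float | None:
    """Dose at which the curve crosses ``target`` percent growth.

    Closed form ``X = c * ((a - t)/(t - d))**(1/b)``.  Returns ``None``
    ("not reached") when the target lies outside the open interval between
    the asymptotes.
    """
    if b == 0:
        raise DoseResponseError("ICxx undefined for zero Hill slope")
    lo, hi = min(a, d), max(a, d)
    if not (lo < target < hi):
        return None
    return c * ((a - target) / (target - d)) ** (1.0 / b)


def normalize_growth(treated_signal, untreated_signal, blank=0.0):
    """Percent growth: 100 * (treated - blank) / (untreated - blank).

    ``blank`` defaults to 0.  Raises :class:`ControlWellError` when the
    untreated control does not exceed the blank.
    """
    treated = np.asarray(treated_signal, dtype=float)
    untreated = np.asarray(untreated_signal, dtype=float)
    denom = untreated - blank
    if np.any(denom <= 0):
        raise ControlWellError(
            "untreated control signal must exceed blank (non-positive denominator)"
        )
    out = 100.0 * (treated - blank) / denom
    return out if out.ndim else float(out)


def predict_growth(fit: FourPLFit, concentration):
    """Predicted percent growth Ŷ at the given dose(s)."""
    return four_pl(concentration, fit.a, fit.d, fit.c, fit.b)


def points_from_arrays(concentrations, growths) -> list[DoseResponsePoint]:
    """Build validated points from parallel dose / growth arrays."""
    conc = np.asarray(concentrations, dtype=float).ravel()
    grow = np.asarray(growths, dtype=float).ravel()
    if conc.shape != grow.shape:
        raise DoseResponseError("concentration and growth arrays differ in length")
    return [DoseResponsePoint(float(x), float(y)) for x, y in zip(conc, grow)]


def _as_arrays(points: Sequence[DoseResponsePoint]) -> tuple[np.ndarray, np.ndarray]:
    if len(points) == 0:
        raise InsufficientDataError("no dose-response points supplied")
    conc = np.array([p.concentration for p in points], dtype=float)
    grow = np.array([p.growth for p in points], dtype=float)
    return conc, grow


def _average_replicates(conc: np.ndarray, grow: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq = np.unique(conc)
    means = np.array([grow[conc == u].mean() for u in uniq])
    return uniq, means


# Multi-start schedule: base start plus 4 jittered restarts from a fixed
# seed, so fits are deterministic given the data.
_N_RESTARTS = 4
_RESTART_SEED = 20


def fit_variant(
    points: Sequence[DoseResponsePoint],
    variant: ModelVariant | str,
    average_replicates: bool = False,
) -> FourPLFit:
    """Bounded least-squares fit of one 4PL variant.

    Starts from (a0 = max Y, d0 = min Y, c0 = geometric mean of doses,
    b0 = 1) plus four jittered restarts; bounds are a, d in [-100, 300]
    (unless fixed), c in (0, 1e3 * max dose], b in [0.05, 20].  ``rse`` is
    sqrt(RSS / (n - p)).  ``converged`` is False when the optimizer fails
    from every start.
    """
    if isinstance(variant, str):
        variant = MODEL_VARIANTS[variant]
    conc, grow = _as_arrays(points)
    if average_replicates:
        conc, grow = _average_replicates(conc, grow)

    p = variant.n_free
    if len(conc) < p + 1:
        raise InsufficientDataError(
            f"{variant.name} needs at least {p + 1} points (free parameters + 1), got {len(conc)}"
        )
    if np.unique(conc).size < 2:
        raise InsufficientDataError("need at least 2 distinct concentrations")
    if variant.fit_slope and np.ptp(grow) == 0:
        raise DegenerateDataError(
            "all growth values identical: Hill slope is unidentifiable"
        )

    free: list[str] = []
    x0: list[float] = []
    lb: list[float] = []
    ub: list[float] = []
    log_c_lo = math.log10(conc.min()) - 6.0
    log_c_hi = math.log10(conc.max()) + 3.0  # c <= 1e3 * max dose
    if variant.fixed_a is None:
        free.append("a")
        x0.append(float(np.clip(grow.max(), -100.0, 300.0)))
        lb.append(-100.0)
        ub.append(300.0)
    if variant.fixed_d is None:
        free.append("d")
        x0.append(float(np.clip(grow.min(), -100.0, 300.0)))
        lb.append(-100.0)
        ub.append(300.0)
    free.append("log_c")
    x0.append(float(np.mean(np.log10(conc))))
    lb.append(log_c_lo)
    ub.append(log_c_hi)
    if variant.fit_slope:
        free.append("b")
        x0.append(1.0)
        lb.append(0.05)
        ub.append(20.0)

    def unpack(theta: np.ndarray) -> tuple[float, float, float, float]:
        vals = dict(zip(free, theta))
        a = variant.fixed_a if variant.fixed_a is not None else vals["a"]
        d = variant.fixed_d if variant.fixed_d is not None else vals["d"]
        c = 10.0 ** vals["log_c"]
        b = vals["b"] if variant.fit_slope else 1.0
        return float(a), float(d), float(c), float(b)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, d, c, b = unpack(theta)
        return four_pl(conc, a, d, c, b) - grow

    rng = np.random.default_rng(_RESTART_SEED)
    starts = [np.array(x0)]
    for _ in range(_N_RESTARTS):
        jit = np.array(x0, dtype=float)
        for i, name in enumerate(free):
            if name in ("a", "d"):
                jit[i] += rng.normal(0.0, 5.0)
            elif name == "log_c":
                jit[i] += rng.uniform(-1.0, 1.0)
            else:  # b
                jit[i] *= math.exp(rng.uniform(-0.8, 0.8))
        starts.append(np.clip(jit, lb, ub))

    best = None
    any_success = False
    for start in starts:
        try:
            res = optimize.least_squares(
                residuals,
                start,
                bounds=(lb, ub),
                method="trf",
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=5000,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
        any_success = any_success or bool(res.success)

    if best is None:  # pragma: no cover - least_squares essentially never raises
        raise DegenerateDataError("optimizer could not evaluate the model")

    a, d, c, b = unpack(best.x)
    rss = float(np.sum(residuals(best.x) ** 2))
    rse = math.sqrt(rss / (len(conc) - p))
    return FourPLFit(
        variant=variant,
        a=a,
        d=d,
        c=c,
        b=b,
        rse=rse,
        n_points=len(conc),
        converged=any_success,
        rss=rss,
        dose_min=float(conc.min()),
        dose_max=float(conc.max()),
    )


def fit_all_variants(
    points: Sequence[DoseResponsePoint], average_replicates: bool = False
) -> tuple[dict[str, FourPLFit], dict[str, str]]:
    """Fit every variant; returns (fits, per-variant failure reasons)."""
    fits: dict[str, FourPLFit] = {}
    failures: dict[str, str] = {}
    for name, variant in MODEL_VARIANTS.items():
        try:
            fit = fit_variant(points, variant, average_replicates=average_replicates)
        except DoseResponseError as exc:
            failures[name] = str(exc)
            continue
        if fit.converged:
            fits[name] = fit
        else:
            fits[name] = fit
            failures[name] = "optimizer did not converge"
    return fits, failures


def fit_6m_detailed(
    points: Sequence[DoseResponsePoint],
    average_replicates: bool = False,
    on_flat: str = "error",
) -> SixModelFit:
    """Fit all six variants and select the lowest residual standard error.

    Ties are broken toward fewer free parameters, then canonical variant
    order.  ``on_flat`` controls flat (non-informative) winners: ``"error"``
    raises :class:`DegenerateDataError`, ``"flag"`` returns the fit (check
    ``fit.informative``).
    """
    fits, failures = fit_all_variants(points, average_replicates=average_replicates)
    candidates = [f for f in fits.values() if f.converged]
    if not candidates:
        raise NoConvergedFitError(failures or {"all": "no variant converged"})
    selected = min(
        candidates,
        key=lambda f: (f.rse, f.variant.n_free, _VARIANT_ORDER[f.variant.name]),
    )
    if not selected.informative and on_flat == "error":
        raise DegenerateDataError(
            "selected fit is flat (a ~ d): response carries no dose information; "
            "pass on_flat='flag' to accept it"
        )
    return SixModelFit(selected=selected, fits=fits, failures=failures)


def fit_6m(
    points: Sequence[DoseResponsePoint],
    average_replicates: bool = False,
    on_flat: str = "error",
) -> FourPLFit:
    """Convenience wrapper returning only the selected fit."""
    return fit_6m_detailed(
        points, average_replicates=average_replicates, on_flat=on_flat
    ).selected


_GRID_STEP = 0.01


def _activity_area(fit: FourPLFit, dose_min: float, dose_max: float) -> float:
    n = int(round((dose_max - dose_min) / _GRID_STEP))
    grid = dose_min + _GRID_STEP * np.arange(n + 1)
    return float(np.sum(predict_growth(fit, grid)))


def response_metrics(
    fit: FourPLFit,
    dose_min: float | None = None,
    dose_max: float | None = None,
    convention: str = "growth",
) -> ResponseMetrics:
    """Closed-form drug-response metrics from a fitted curve.

    ICxx solves Ŷ = t for t = 50/90/95 percent *growth* under the default
    convention; ``convention="inhibition"`` reads IC90/IC95 as 90/95 percent
    inhibition (growth 10/5).  EC50 is the midpoint dose, i.e. ``c``.
    Amax = a - d.  The Activity Area grid defaults to the fitted
    concentration range.
    """
    if convention not in ("growth", "inhibition"):
        raise DoseResponseError(f"unknown ICxx convention {convention!r}")
    if dose_min is None:
        dose_min = fit.dose_min
    if dose_max is None:
        dose_max = fit.dose_max
    if not (dose_min > 0 and dose_max > dose_min):
        raise DoseResponseError("need 0 < dose_min < dose_max for metrics")

    targets = (50.0, 90.0, 95.0) if convention == "growth" else (50.0, 10.0, 5.0)
    ic50, ic90, ic95 = (
        inverse_four_pl(t, fit.a, fit.d, fit.c, fit.b) for t in targets
    )
    return ResponseMetrics(
        ic50=ic50,
        ic90=ic90,
        ic95=ic95,
        ec50=fit.c,
        amax=fit.a - fit.d,
        activity_area=_activity_area(fit, dose_min, dose_max),
        convention=convention,
    )


# ---------------------------------------------------------------------------
# Plate CSV I/O and batch fitting


def read_plate_csv(path, pre_normalized: bool = False, blank: float = 0.0) -> pd.DataFrame:
    """Read a cytotoxicity CSV into tidy percent-growth form.

    Expected columns: ``cell_line, drug, concentration_uM, replicate`` plus
    either ``percent_growth`` (``pre_normalized=True``) or ``signal``.  Raw
    signals are normalized against the mean signal of the zero-concentration
    control rows of the same (cell_line, drug).
    """
    df = pd.read_csv(path)
    required = {"cell_line", "drug", "concentration_uM", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise DoseResponseError(f"plate CSV missing columns: {sorted(missing)}")
    if pre_normalized or "percent_growth" in df.columns:
        if "percent_growth" not in df.columns:
            raise DoseResponseError("pre_normalized requires a percent_growth column")
        return df[df["concentration_uM"] > 0].reset_index(drop=True)
    if "signal" not in df.columns:
        raise DoseResponseError("plate CSV needs a signal or percent_growth column")
    out = []
    for (cell, drug), grp in df.groupby(["cell_line", "drug"], sort=False):
        controls = grp.loc[grp["concentration_uM"] == 0, "signal"]
        if controls.empty:
            raise ControlWellError(
                f"no zero-concentration control wells for {cell}/{drug}"
            )
        treated = grp[grp["concentration_uM"] > 0].copy()
        treated["percent_growth"] = normalize_growth(
            treated["signal"].to_numpy(), controls.mean(), blank
        )
        out.append(treated.drop(columns="signal"))
    return pd.concat(out, ignore_index=True)


def fit_plate(
    data: pd.DataFrame,
    drug: str | None = None,
    average_replicates: bool = False,
    convention: str = "growth",
    on_flat: str = "error",
) -> pd.DataFrame:
    """Fit the 6M procedure per (cell_line, drug); long table of all fits.

    One row per (cell_line, drug, variant) with the fitted parameters; the
    selected variant's row carries the derived metrics.
    """
    if drug is not None:
        if drug not in set(data["drug"]):
            raise DoseResponseError(f"drug {drug!r} not present in plate data")
        data = data[data["drug"] == drug]
    rows = []
    for (cell, drg), grp in data.groupby(["cell_line", "drug"], sort=True):
        points = points_from_arrays(grp["concentration_uM"], grp["percent_growth"])
        result = fit_6m_detailed(
            points, average_replicates=average_replicates, on_flat=on_flat
        )
        metrics = response_metrics(result.selected, convention=convention)
        for name, fit in result.fits.items():
            sel = name == result.selected.variant.name
            row = {
                "cell_line": cell,
                "drug": drg,
                "variant": name,
                "a": fit.a,
                "d": fit.d,
                "c": fit.c,
                "b": fit.b,
                "rse": fit.rse,
                "n_points": fit.n_points,
                "converged": fit.converged,
                "selected": sel,
            }
            if sel:
                row.update(
                    ic50=metrics.ic50,
                    ic90=metrics.ic90,
                    ic95=metrics.ic95,
                    ec50=metrics.ec50,
                    amax=metrics.amax,
                    activity_area=metrics.activity_area,
                )
            rows.append(row)
    return pd.DataFrame(rows)
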