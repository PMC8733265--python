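"""Binding-parameter estimation from MST titration series.

Two fit models are provided, reflecting a genuine ambiguity in how
normalized MST dose–response data are commonly analyzed:

``fit_logistic``
    The four-parameter logistic (Hill) curve
    ``S(L_t) = S_free + (S_bound − S_free) / (1 + (EC50 / L_t)^h)``
    in total-titrant concentration.  Its midpoint is an *EC50*; it equals
    the dissociation constant only when the labeled species does not
    deplete the titrant.  With the labeled target at 0.1 μmol/l and Kd
    values down to 0.3 μmol/l, depletion is not negligible, and the exact
    half-occupancy relation is ``EC50 = Kd + R_t/2``.

``fit_depletion``
    The exact mass-action isotherm: occupancy from the ligand-depletion
    quadratic at each ladder point, mapped through the two-state signal.
    Its ``Kd`` is a true dissociation constant regardless of depletion.

Both fits use a deterministic initialization (plateaus from the first and
last deciles of the ladder, midpoint from the first half-range crossing,
h = 1) and bounded least squares, so a given series always yields the
same fit — no random restarts.  Residuals are unweighted and the fit is
performed on linear signal versus log-spaced concentrations.

Classification operationalizes the affinity table's footnotes:
``no_binding`` when the fitted amplitude is indistinguishable from the
residual noise (|amplitude| < 3 × residual SD — the shape of the
tail-vs-tail negative control), and ``cannot_determine`` ("cnd") when the
midpoint is not resolved by the ladder: its upper 95% confidence bound
exceeds the top concentration, or the estimate lies in the ladder's last
decade (EC50 > top/10), meaning the bound plateau was never sampled and
the estimate rests on extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq, curve_fit

from .equilibria import (
    BindingDomainError,
    CompetitionSystem,
    SolverError,
    check_concentration,
    complex_concentration,
    fraction_bound,
    solve_competition,
)
from .mst_signal import normalize_series
from .synthetic_data import TitrationSeries

__all__ = [
    "Classification",
    "FitResult",
    "AggregateResult",
    "AggregationError",
    "fit_logistic",
    "fit_depletion",
    "aggregate",
    "predict_competition_ec50",
    "welch_test",
    "WelchResult",
    "compare_to_control",
]


class Classification(Enum):
    BINDER = "binder"
    NO_BINDING = "no_binding"
    CANNOT_DETERMINE = "cannot_determine"


@dataclass(frozen=True)
class FitResult:
    """Outcome of one titration fit.

    ``kd_or_ec50`` is a Kd for the depletion model and an EC50 for the
    logistic model; it is ``None`` when classification is ``no_binding``
    (there is nothing to estimate) and retained as a diagnostic for
    ``cannot_determine``.
    """

    model_kind: str  # "logistic" | "depletion"
    kd_or_ec50: float | None
    hill: float | None
    signal_free: float
    signal_bound: float
    stderr: Mapping[str, float]
    residual_sse: float
    converged: bool
    classification: Classification
    flags: tuple[str, ...] = ()

    @property
    def amplitude(self) -> float:
        return self.signal_bound - self.signal_free


@dataclass(frozen=True)
class AggregateResult:
    """Replicate mean ± SEM of fitted Kds (the affinity-table cell)."""

    mean_kd: float
    sem: float
    n: int


class AggregationError(ValueError):
    """Replicates disagree on classification or are too few to pool."""


def _check_series(series: TitrationSeries) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(series.titrant_totals, dtype=float)
    y = np.asarray(series.signals, dtype=float)
    if x.size < 8:
        raise BindingDomainError("fitting needs >= 8 titration points")
    return x, y


def _flat_result(model_kind: str, y: np.ndarray) -> FitResult:
    base = float(np.mean(y))
    return FitResult(
        model_kind=model_kind,
        kd_or_ec50=None,
        hill=None,
        signal_free=base,
        signal_bound=base,
        stderr={},
        residual_sse=float(np.sum((y - base) ** 2)),
        converged=True,
        classification=Classification.NO_BINDING,
        flags=("flat",),
    )


def _initial_plateaus(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # first/last deciles of the ladder, at least two points each
    k = max(2, x.size // 10)
    return float(np.mean(y[:k])), float(np.mean(y[-k:]))


def _initial_midpoint(x: np.ndarray, y: np.ndarray, s_free: float, s_bound: float) -> float:
    half = 0.5 * (s_free + s_bound)
    direction = 1.0 if s_bound >= s_free else -1.0
    crossed = np.nonzero(direction * (y - half) >= 0.0)[0]
    if crossed.size:
        return float(x[crossed[0]])
    return float(np.sqrt(x[0] * x[-1]))  # geometric midrange fallback


def _classify(
    amplitude: float,
    residual_sd: float,
    ec50: float,
    se_ec50: float,
    top: float,
) -> tuple[Classification, tuple[str, ...]]:
    if abs(amplitude) < 3.0 * residual_sd:
        return Classification.NO_BINDING, ("amplitude below noise",)
    flags: list[str] = []
    upper = ec50 + 1.96 * se_ec50 if math.isfinite(se_ec50) else math.inf
    if upper > top:
        flags.append("EC50 upper CI beyond ladder")
    if ec50 > top / 10.0:
        flags.append("saturation unreachable")
    if flags:
        return Classification.CANNOT_DETERMINE, tuple(flags)
    return Classification.BINDER, ()


def _finish(
    model_kind: str,
    x: np.ndarray,
    y: np.ndarray,
    popt: np.ndarray,
    pcov: np.ndarray,
    names: Sequence[str],
    predict,
    hill: float | None,
    converged: bool,
) -> FitResult:
    resid = y - predict(x, *popt)
    sse = float(np.sum(resid * resid))
    dof = max(x.size - len(popt), 1)
    residual_sd = math.sqrt(sse / dof)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    stderr = {n: float(s) for n, s in zip(names, se)}
    params = dict(zip(names, popt))
    ec50 = float(params["midpoint"])
    classification, flags = _classify(
        amplitude=float(params["signal_bound"] - params["signal_free"]),
        residual_sd=residual_sd,
        ec50=ec50,
        se_ec50=stderr.get("midpoint", math.inf),
        top=float(x[-1]),
    )
    if not converged:
        flags = flags + ("did not converge",)
    return FitResult(
        model_kind=model_kind,
        kd_or_ec50=None if classification is Classification.NO_BINDING else ec50,
        hill=hill,
        signal_free=float(params["signal_free"]),
        signal_bound=float(params["signal_bound"]),
        stderr=stderr,
        residual_sse=sse,
        converged=converged,
        classification=classification,
        flags=flags,
    )


def fit_logistic(series: TitrationSeries, fix_hill: bool = False) -> FitResult:
    """Fit the logistic (Hill) dose–response curve; midpoint is an EC50.

    ``fix_hill=True`` pins h = 1 (pure hyperbolic shape in total titrant).
    The midpoint is bounded to [ladder_min/100, ladder_max × 100].
    """
    x, y = _check_series(series)
    if normalize_series(y).flat:
        return _flat_result("logistic", y)
    s_free0, s_bound0 = _initial_plateaus(x, y)
    ec0 = _initial_midpoint(x, y, s_free0, s_bound0)
    lo, hi = x[0] / 100.0, x[-1] * 100.0
    ec0 = min(max(ec0, lo), hi)

    if fix_hill:
        def model(L, s_free, s_bound, ec50):
            return s_free + (s_bound - s_free) / (1.0 + ec50 / L)

        p0 = [s_free0, s_bound0, ec0]
        bounds = ([-np.inf, -np.inf, lo], [np.inf, np.inf, hi])
        names = ["signal_free", "signal_bound", "midpoint"]
    else:
        def model(L, s_free, s_bound, ec50, h):
            return s_free + (s_bound - s_free) / (1.0 + (ec50 / L) ** h)

        p0 = [s_free0, s_bound0, ec0, 1.0]
        bounds = ([-np.inf, -np.inf, lo, 0.2], [np.inf, np.inf, hi, 6.0])
        names = ["signal_free", "signal_bound", "midpoint", "hill"]

    converged = True
    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        converged = False
        popt, pcov = np.asarray(p0), np.full((len(p0), len(p0)), np.nan)
    hill = 1.0 if fix_hill else float(popt[3])
    return _finish("logistic", x, y, popt, pcov, names, model, hill, converged)


def fit_depletion(
    series: TitrationSeries, labeled_total: float | None = None
) -> FitResult:
    """Fit the exact ligand-depletion isotherm; midpoint is a true Kd.

    The model is ``S(L_t) = S_free + (S_bound − S_free) · θ(R_t, L_t, Kd)``
    with θ the receptor occupancy from the depletion quadratic, so the
    estimate is a dissociation constant irrespective of how strongly the
    labeled species (total ``labeled_total``, default from the series)
    depletes the titrant.
    """
    x, y = _check_series(series)
    rt = check_concentration(
        series.labeled_total if labeled_total is None else labeled_total,
        "labeled_total",
    )
    if rt == 0.0:
        raise BindingDomainError("labeled_total must be > 0 for a depletion fit")
    if normalize_series(y).flat:
        return _flat_result("depletion", y)
    s_free0, s_bound0 = _initial_plateaus(x, y)
    ec0 = _initial_midpoint(x, y, s_free0, s_bound0)
    kd0 = max(ec0 - rt / 2.0, x[0] / 10.0)  # EC50 = Kd + R_t/2, inverted
    lo, hi = x[0] / 100.0, x[-1] * 100.0
    kd0 = min(max(kd0, lo), hi)

    def model(L, s_free, s_bound, kd):
        theta = complex_concentration(rt, L, kd) / rt
        return s_free + (s_bound - s_free) * theta

    converged = True
    try:
        popt, pcov = curve_fit(
            model,
            x,
            y,
            p0=[s_free0, s_bound0, kd0],
            bounds=([-np.inf, -np.inf, lo], [np.inf, np.inf, hi]),
            maxfev=20000,
        )
    except RuntimeError:
        converged = False
        popt = np.asarray([s_free0, s_bound0, kd0])
        pcov = np.full((3, 3), np.nan)
    names = ["signal_free", "signal_bound", "midpoint"]
    return _finish("depletion", x, y, popt, pcov, names, model, None, converged)


def aggregate(fits: Sequence[FitResult]) -> AggregateResult:
    """Pool replicate fits into mean ± SEM (``SEM = SD / sqrt(n)``).

    Requires at least two converged binder fits; replicates with any other
    classification make the pool incoherent and raise
    :class:`AggregationError` listing the offenders.
    """
    if len(fits) < 2:
        raise AggregationError("need >= 2 replicate fits for a finite SEM")
    bad = [
        (i, f.classification.value)
        for i, f in enumerate(fits)
        if f.classification is not Classification.BINDER or not f.converged
    ]
    if bad:
        raise AggregationError(f"non-binder or unconverged replicates: {bad}")
    kds = np.array([f.kd_or_ec50 for f in fits], dtype=float)
    return AggregateResult(
        mean_kd=float(np.mean(kds)),
        sem=float(np.std(kds, ddof=1) / math.sqrt(len(kds))),
        n=len(kds),
    )


def predict_competition_ec50(
    kd_a: float,
    kd_b: float,
    a_total: float,
    r_total: float,
) -> float:
    """Titrant-B total at which B occupies half the receptor, exactly.

    Computed by root-finding over the exact ternary equilibrium, so the
    prediction is depletion-aware.  In the limit ``r_total → 0`` it
    reduces to the Cheng–Prusoff form ``kd_b · (1 + a_total / kd_a)``;
    with no competitor it reduces to the binary half-occupancy point
    ``kd_b + r_total / 2``.
    """
    check_concentration(a_total, "a_total")
    check_concentration(r_total, "r_total")
    if kd_a <= 0 or kd_b <= 0:
        raise BindingDomainError("both Kds must be > 0")

    def theta_b(bt: float) -> float:
        state = solve_competition(
            CompetitionSystem(
                receptor_total=r_total,
                competitor_a_total=a_total,
                titrant_b_total=bt,
                kd_a=kd_a,
                kd_b=kd_b,
            )
        )
        return state.complexes[("R", "B")] / r_total if r_total else (
            state.free["B"] / (state.free["B"] + kd_b)  # unreachable; r_total > 0 below
        )

    if r_total == 0.0:
        # no receptor: occupancy is ill-defined; return the analytic limit
        return kd_b * (1.0 + a_total / kd_a)

    hi = kd_b * (1.0 + a_total / kd_a) * 4.0 + r_total + kd_b
    while theta_b(hi) < 0.5:
        hi *= 4.0
        if hi > 1.0e12:
            raise SolverError("could not bracket the half-occupancy point")
    return float(brentq(lambda bt: theta_b(bt) - 0.5, 0.0, hi, rtol=1.0e-12))


@dataclass(frozen=True)
class WelchResult:
    t: float
    p: float
    df: float
    flags: tuple[str, ...] = ()


def welch_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Unpaired two-tailed t test, Welch variant (unequal variances).

    Degenerate identical zero-variance groups return t = 0, p = 1 with a
    ``"degenerate"`` flag rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise BindingDomainError("each group needs n >= 2")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return WelchResult(t=0.0, p=1.0, df=float(a.size + b.size - 2),
                               flags=("degenerate",))
        return WelchResult(t=math.copysign(math.inf, np.mean(a) - np.mean(b)),
                           p=0.0, df=float(a.size + b.size - 2),
                           flags=("degenerate",))
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), p=float(res.pvalue), df=float(res.df))


def compare_to_control(
    control: Sequence[float], variants: Mapping[str, Sequence[float]]
) -> dict[str, dict[str, float]]:
    """Each variant vs one control: Welch t with Bonferroni adjustment.

    A pragmatic stand-in for Dunnett's many-to-one procedure: the
    per-comparison Welch p-values are multiplied by the number of variants
    (capped at 1).  Slightly conservative relative to exact Dunnett
    critical values.
    """
    m = len(variants)
    out: dict[str, dict[str, float]] = {}
    for name, grp in variants.items():
        res = welch_test(grp, control)
        out[name] = {"t": res.t, "p_raw": res.p, "p_adj": min(res.p * m, 1.0)}
    return out
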