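"""Confirmatory quantitative analyses around the screen.

Dose-response EC50 estimation under the four-parameter logistic (Hill)
model, amino-acid mass/molar unit conversion, fold changes, the
Mantel-Cox logrank test for tumor latency, and the ns/*/**/*** p-value
star convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy.optimize import least_squares

from .errors import DomainError, FitError, UndefinedStatisticError

#: Molar mass of L-asparagine (C4H8N2O3), g/mol.
ASPARAGINE_MOLAR_MASS = 132.12


@dataclass
class DoseResponseFit:
    """Fitted four-parameter logistic curve.

    ``bottom``/``top`` are the high- and low-dose asymptotes in response
    units, ``ec50`` the dose of half-maximal response (same units as the
    doses), ``hill`` the slope, ``rss`` the residual sum of squares.
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float

    def predict(self, dose):
        return four_param_logistic(dose, self.bottom, self.top, self.ec50, self.hill)


@dataclass(frozen=True)
class SurvivalSample:
    """One animal's tumor-latency observation.

    ``time`` in days (> 0); ``event`` 1 for tumor onset, 0 for censoring.
    """

    time: float
    event: int
    group: str = ""


def four_param_logistic(dose, bottom, top, ec50, hill):
    """response = bottom + (top - bottom) / (1 + (dose/ec50)^hill).

    At dose == ec50 the response is exactly (top + bottom)/2 for any
    slope.  hill > 0 gives a curve decreasing from ``top`` at low dose
    toward ``bottom`` at high dose.
    """
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


def fit_dose_response(doses, responses,
                      fix_top_bottom: tuple[float, float] | None = None,
                      ) -> DoseResponseFit:
    """Least-squares 4PL fit on log-dose; deterministic given its inputs.

    Initialization: top/bottom from the mean response at the lowest and
    highest dose, EC50 from the dose whose response is nearest the
    half-way response, hill = 1.  EC50 is optimized on a log scale so it
    stays positive.  ``fix_top_bottom = (top, bottom)`` pins the
    asymptotes and fits only EC50 and slope (then >= 2 distinct doses
    suffice instead of >= 4).

    Raises :class:`DomainError` for non-positive doses and
    :class:`FitError` (carrying the initialization) on non-convergence.
    """
    d = np.asarray(list(doses), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if d.shape != y.shape:
        raise DomainError("doses and responses must have equal length")
    if (d <= 0).any():
        raise DomainError("doses must be strictly positive")
    if not np.isfinite(y).all():
        raise DomainError("responses must be finite")
    n_distinct = np.unique(d).size
    needed = 2 if fix_top_bottom is not None else 4
    if n_distinct < needed:
        raise DomainError(f"need >= {needed} distinct doses, got {n_distinct}")

    order = np.argsort(d)
    d_sorted, y_sorted = d[order], y[order]
    if fix_top_bottom is not None:
        top0, bottom0 = float(fix_top_bottom[0]), float(fix_top_bottom[1])
    else:
        top0 = float(y_sorted[d_sorted == d_sorted[0]].mean())
        bottom0 = float(y_sorted[d_sorted == d_sorted[-1]].mean())
    half = 0.5 * (top0 + bottom0)
    ec50_0 = float(d_sorted[np.argmin(np.abs(y_sorted - half))])
    hill0 = 1.0

    if fix_top_bottom is not None:
        top_f, bottom_f = float(fix_top_bottom[0]), float(fix_top_bottom[1])

        def residuals(theta):
            log_ec50, hill = theta
            return four_param_logistic(d, bottom_f, top_f,
                                       math.exp(log_ec50), hill) - y

        x0 = np.array([math.log(ec50_0), hill0])
    else:
        def residuals(theta):
            bottom, top, log_ec50, hill = theta
            return four_param_logistic(d, bottom, top,
                                       math.exp(log_ec50), hill) - y

        x0 = np.array([bottom0, top0, math.log(ec50_0), hill0])

    result = least_squares(residuals, x0, method="lm",
                           xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    if not result.success:
        raise FitError(f"4PL fit did not converge: {result.message}",
                       init=x0.tolist(), trace=result)
    if fix_top_bottom is not None:
        log_ec50, hill = result.x
        bottom, top = bottom_f, top_f
    else:
        bottom, top, log_ec50, hill = result.x
    return DoseResponseFit(bottom=float(bottom), top=float(top),
                           ec50=float(math.exp(log_ec50)), hill=float(hill),
                           rss=float(np.sum(result.fun ** 2)))


def mass_to_molar(conc_mg_per_l: float, molar_mass_g_per_mol: float) -> float:
    """Convert a mass concentration (mg/L) to micromolar.

    For L-asparagine (132.12 g/mol) this maps the 100 mg/L culture
    supplement to ~757 uM and typical untreated mouse serum, 6.87 mg/L,
    to ~52 uM.
    """
    if molar_mass_g_per_mol <= 0:
        raise DomainError("molar mass must be > 0")
    if conc_mg_per_l < 0:
        raise DomainError("concentration must be >= 0")
    return conc_mg_per_l / molar_mass_g_per_mol * 1000.0


def molar_to_mass(conc_um: float, molar_mass_g_per_mol: float) -> float:
    """Inverse of :func:`mass_to_molar`: micromolar to mg/L."""
    if molar_mass_g_per_mol <= 0:
        raise DomainError("molar mass must be > 0")
    if conc_um < 0:
        raise DomainError("concentration must be >= 0")
    return conc_um * molar_mass_g_per_mol / 1000.0


def fold_change(numerator: float, denominator: float) -> float:
    """Simple ratio, e.g. the 52 uM / 4 uM = 13-fold serum asparagine drop."""
    if denominator <= 0:
        raise DomainError("denominator must be > 0")
    return numerator / denominator


def _as_time_event(group: Iterable) -> tuple[np.ndarray, np.ndarray]:
    times, events = [], []
    for s in group:
        if isinstance(s, SurvivalSample):
            t, e = s.time, s.event
        else:
            t, e = s
        if t <= 0:
            raise DomainError("survival times must be > 0")
        if e not in (0, 1):
            raise DomainError("event indicator must be 0 or 1")
        times.append(float(t))
        events.append(int(e))
    return np.asarray(times), np.asarray(events)


def logrank_test(group_a: Sequence, group_b: Sequence) -> tuple[float, float]:
    """Mantel-Cox logrank comparison of two latency curves.

    Accepts sequences of :class:`SurvivalSample` or ``(time, event)``
    pairs.  Returns ``(chi_square, p)`` for the 1-df Mantel-Haenszel
    statistic, no continuity correction, hypergeometric variance at ties.

    Raises :class:`UndefinedStatisticError` when no events occurred.
    """
    ta, ea = _as_time_event(group_a)
    tb, eb = _as_time_event(group_b)
    if ta.size == 0 or tb.size == 0:
        raise DomainError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise UndefinedStatisticError("logrank undefined with no events")
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def p_to_stars(p: float) -> str:
    """Significance stars: ns (p>=0.05), * (<0.05), ** (<0.01), *** (<0.001)."""
    if not 0 < p <= 1:
        raise DomainError(f"p must be in (0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
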