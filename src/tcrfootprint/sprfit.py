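"""SPR binding-parameter estimation.

Two independent fits per variant and replicate, mirroring the two-assay
experimental design:

* equilibrium: bound = Max·C / (C + K_D)   (Langmuir isotherm), giving K_D
  and the maximal response Max;
* dissociation: R(t) = R0·exp(−k_off·t) (+ optional constant baseline),
  giving k_off.

k_on is never fitted; it is derived algebraically as k_on = k_off / K_D,
with its relative error the quadrature combination of the k_off and K_D
relative errors.

Replicates are fitted separately and aggregated afterwards: the reported
central value is the replicate mean, the reported spread is the range for
n = 2 and the SD for n ≥ 3. The uncertainty used downstream is
max(spread, mean fit SE): with two replicates the range alone is an
unreliable scale estimate (it can be arbitrarily small by chance), so the
fit covariance provides a noise floor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .binding import DissociationTrace, EquilibriumSeries
from .errors import (DataValidationError, DegenerateDataError,
                     FitConvergenceError, InsufficientDataError)

__all__ = [
    "AffinityFit", "DissociationFit", "VariantKinetics",
    "fit_equilibrium", "fit_dissociation", "derive_kon",
    "aggregate_replicates", "with_fold_changes",
]

_XTOL = 1e-8
_N_RESTARTS = 3


@dataclass(frozen=True)
class AffinityFit:
    """Result of one equilibrium (Langmuir isotherm) fit.

    Censored fits (affinity too low to measure) carry no point estimate;
    ``kd_lower_bound`` is the finite bound K_D ≥ censor_factor × top tested
    concentration.
    """

    variant: str
    replicate: int
    kd: float | None
    kd_se: float
    rmax: float | None
    rmax_se: float
    residual_rms: float
    converged: bool
    censored: bool = False
    kd_lower_bound: float | None = None
    n_points: int = 0


@dataclass(frozen=True)
class DissociationFit:
    """Result of one 1:1 dissociation fit."""

    variant: str
    replicate: int
    koff: float
    koff_se: float
    r0: float
    r0_se: float
    baseline: float | None
    residual_rms: float
    n_points: int


@dataclass(frozen=True)
class VariantKinetics:
    """Replicate-aggregated binding parameters for one variant.

    ``kd_sigma`` / ``koff_sigma`` are the uncertainties used downstream
    (max of replicate spread and mean fit SE); ``kd_spread`` / ``koff_spread``
    are the raw range/SD values as conventionally reported.
    k_on · K_D = k_off holds exactly by construction.
    """

    variant: str
    n_replicates: int
    kd: float | None = None
    kd_spread: float = 0.0
    kd_sigma: float = 0.0
    censored: bool = False
    kd_lower_bound: float | None = None
    koff: float | None = None
    koff_spread: float = 0.0
    koff_sigma: float = 0.0
    kon: float | None = None
    kon_sigma: float = 0.0
    kon_upper_bound: float | None = None
    fold_kd: float | None = None
    fold_koff: float | None = None
    fold_kon_decrease: float | None = None


def _curve_fit_retry(model, x, y, p0, bounds, what: str):
    """curve_fit with up to 3 perturbed restarts before erroring."""
    last = None
    starts = [np.asarray(p0, dtype=float)]
    for k in range(1, _N_RESTARTS + 1):
        starts.append(np.asarray(p0, dtype=float) * (2.0 ** (k - 1.5)))
    for start in starts:
        start = np.clip(start, bounds[0], None)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, x, y, p0=start, bounds=bounds,
                    xtol=_XTOL, ftol=_XTOL, maxfev=20000)
            return popt, pcov
        except (RuntimeError, ValueError) as exc:  # pragma: no cover
            last = exc
    raise FitConvergenceError(f"{what}: fit failed after restarts ({last})")


def fit_equilibrium(series: EquilibriumSeries, *,
                    censor_factor: float = 5.0) -> AffinityFit:
    """Fit the Langmuir isotherm bound = Max·C/(C + K_D) to one series.

    Initial values: Max0 = 1.1 × max response, K_D0 = the tested
    concentration whose response is nearest half of the maximum. The fit is
    marked censored when the fitted K_D exceeds ``censor_factor`` × the top
    tested concentration or the fit cannot bound K_D.
    """
    c = series.concentrations
    r = series.responses
    if len(c) < 5:
        raise InsufficientDataError(
            f"{series.variant}/{series.replicate}: need >=5 points, "
            f"got {len(c)}")
    if np.ptp(r) <= 0 or np.allclose(r, r[0]):
        raise DegenerateDataError(
            f"{series.variant}/{series.replicate}: no response variation")

    rmax0 = 1.1 * float(r.max())
    kd0 = float(c[np.argmin(np.abs(r - 0.5 * r.max()))])

    def model(cc, rmax, kd):
        return rmax * cc / (cc + kd)

    popt, pcov = _curve_fit_retry(
        model, c, r, (rmax0, kd0), ([0.0, 0.0], [np.inf, np.inf]),
        f"equilibrium {series.variant}/{series.replicate}")
    rmax, kd = (float(v) for v in popt)
    ses = np.sqrt(np.diag(pcov))
    rmax_se, kd_se = (float(v) for v in ses)
    resid = r - model(c, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    top = float(c.max())
    # a K_D whose standard error exceeds the estimate itself is unbounded
    # (flat or noise-level series); treat it like an unmeasurable affinity
    unbounded = not (np.isfinite(kd_se) and kd > 0 and kd_se <= kd)
    if kd > censor_factor * top or unbounded:
        return AffinityFit(
            variant=series.variant, replicate=series.replicate,
            kd=None, kd_se=math.inf, rmax=None, rmax_se=math.inf,
            residual_rms=rms, converged=True, censored=True,
            kd_lower_bound=censor_factor * top, n_points=len(c))
    return AffinityFit(
        variant=series.variant, replicate=series.replicate,
        kd=kd, kd_se=kd_se, rmax=rmax, rmax_se=rmax_se,
        residual_rms=rms, converged=True, n_points=len(c))


def fit_dissociation(trace: DissociationTrace, *,
                     baseline: bool = False) -> DissociationFit:
    """Fit R(t) = R0·exp(−k_off·(t − t_start)) (+ c) inside the fit window."""
    t, r = trace.window()
    if len(t) < 10:
        raise InsufficientDataError(
            f"{trace.variant}/{trace.replicate}: need >=10 points in the "
            f"fit window, got {len(t)}")
    t0 = t - t[0]
    # log-linear initialization on the positive part of the trace
    pos = r > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t0[pos], np.log(r[pos]), 1)
    else:
        slope, intercept = 0.0, 0.0
    if slope >= 0 and r[-1] >= r[0]:
        raise DegenerateDataError(
            f"{trace.variant}/{trace.replicate}: non-decaying trace")
    k0 = max(-float(slope), 1e-6)
    r00 = float(np.exp(intercept)) if pos.sum() >= 2 else float(r[0])

    if baseline:
        def model(tt, r0, k, cbase):
            return r0 * np.exp(-k * tt) + cbase
        p0 = (r00, k0, 0.0)
        lo, hi = [0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]
    else:
        def model(tt, r0, k):
            return r0 * np.exp(-k * tt)
        p0 = (r00, k0)
        lo, hi = [0.0, 0.0], [np.inf, np.inf]

    popt, pcov = _curve_fit_retry(
        model, t0, r, p0, (lo, hi),
        f"dissociation {trace.variant}/{trace.replicate}")
    ses = np.sqrt(np.diag(pcov))
    koff = float(popt[1])
    if koff <= 0:
        raise DegenerateDataError(
            f"{trace.variant}/{trace.replicate}: fitted k_off <= 0")
    resid = r - model(t0, *popt)
    return DissociationFit(
        variant=trace.variant, replicate=trace.replicate,
        koff=koff, koff_se=float(ses[1]),
        r0=float(popt[0]), r0_se=float(ses[0]),
        baseline=float(popt[2]) if baseline else None,
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        n_points=len(t))


def derive_kon(kd: float, kd_sigma: float, koff: float,
               koff_sigma: float) -> tuple[float, float]:
    """k_on = k_off/K_D; relative error = ⊕ of the input relative errors."""
    if kd <= 0 or koff <= 0:
        raise DataValidationError("K_D and k_off must be positive")
    kon = koff / kd
    rel = math.hypot(koff_sigma / koff, kd_sigma / kd)
    return kon, kon * rel


def _spread_and_sigma(values: Sequence[float],
                      fit_ses: Sequence[float]) -> tuple[float, float]:
    values = list(values)
    n = len(values)
    if n == 1:
        spread = 0.0
    elif n == 2:
        spread = abs(values[0] - values[1])          # range
    else:
        spread = float(np.std(values, ddof=1))        # SD
    finite = [s for s in fit_ses if math.isfinite(s)]
    floor = float(np.mean(finite)) if finite else 0.0
    return spread, max(spread, floor)


def aggregate_replicates(variant: str,
                         affinity_fits: Sequence[AffinityFit],
                         dissociation_fits: Sequence[DissociationFit] = ()
                         ) -> VariantKinetics:
    """Combine replicate fits into one :class:`VariantKinetics`.

    A variant with any censored affinity replicate is censored (the
    conservative call: a replicate that could not bound K_D contradicts a
    point estimate from its sibling), carrying the tightest (largest) K_D
    lower bound and no k_on point estimate.
    """
    if not affinity_fits:
        raise DataValidationError(f"{variant}: no affinity fits")
    conv = [f for f in affinity_fits if not f.censored]
    if len(conv) < len(affinity_fits):
        conv = []  # mixed replicates: censor the variant

    koff = koff_spread = koff_sigma = None
    if dissociation_fits:
        koffs = [f.koff for f in dissociation_fits]
        koff = float(np.mean(koffs))
        koff_spread, koff_sigma = _spread_and_sigma(
            koffs, [f.koff_se for f in dissociation_fits])

    if not conv:
        bound = max(f.kd_lower_bound for f in affinity_fits
                    if f.kd_lower_bound is not None)
        kon_ub = koff / bound if koff is not None else None
        return VariantKinetics(
            variant=variant, n_replicates=len(affinity_fits),
            censored=True, kd_lower_bound=bound,
            koff=koff, koff_spread=koff_spread or 0.0,
            koff_sigma=koff_sigma or 0.0, kon_upper_bound=kon_ub)

    kds = [f.kd for f in conv]
    kd = float(np.mean(kds))
    kd_spread, kd_sigma = _spread_and_sigma(kds, [f.kd_se for f in conv])
    kon = kon_sigma = None
    if koff is not None:
        kon, kon_sigma = derive_kon(kd, kd_sigma, koff, koff_sigma)
    return VariantKinetics(
        variant=variant, n_replicates=len(conv),
        kd=kd, kd_spread=kd_spread, kd_sigma=kd_sigma,
        koff=koff, koff_spread=koff_spread or 0.0,
        koff_sigma=koff_sigma or 0.0,
        kon=kon, kon_sigma=kon_sigma or 0.0)


def with_fold_changes(results: Mapping[str, VariantKinetics],
                      wt_label: str = "WT") -> dict[str, VariantKinetics]:
    """Attach WT-normalized fold changes to every variant.

    fold_kd = K_D,mut / K_D,wt (fold increase; computed from the bound for
    censored variants), fold_koff likewise, and fold_kon_decrease =
    k_on,wt / k_on,mut (indeterminate for censored variants).
    """
    if wt_label not in results:
        raise DataValidationError(
            f"WT variant {wt_label!r} missing from panel; fold changes "
            "undefined")
    wt = results[wt_label]
    if wt.censored or wt.kd is None:
        raise DataValidationError("WT affinity is censored; panel "
                                  "unanalyzable")
    out: dict[str, VariantKinetics] = {}
    for label, res in results.items():
        kd_eff = res.kd if not res.censored else res.kd_lower_bound
        fold_kd = kd_eff / wt.kd if kd_eff is not None else None
        fold_koff = (res.koff / wt.koff
                     if res.koff is not None and wt.koff else None)
        fold_kon = (wt.kon / res.kon
                    if res.kon is not None and wt.kon else None)
        out[label] = replace(res, fold_kd=fold_kd, fold_koff=fold_koff,
                             fold_kon_decrease=fold_kon)
    return out
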