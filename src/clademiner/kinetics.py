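"""Michaelis-Menten fitting and fermentation yield accounting.

Rates are in µM/s, substrate and enzyme concentrations in µM, so
kcat = Vmax / [E]0 is dimensionally forced to 1/s. The fit is ordinary
nonlinear least squares (Levenberg-Marquardt) initialized from a
Lineweaver-Burk double-reciprocal regression, with a few perturbed
restarts before giving up; standard errors come from the Jacobian at the
optimum.

Yield accounting mirrors common fermentation reporting: specific yield in
mg product per g dry cell weight (DCW), fold change versus a baseline
strain (displayed half-up-rounded to 2 decimals, raw ratio kept),
intracellular/extracellular percentage split, and total titer as the sum
of component titers in mg/L. Molar conversions need a caller-supplied
molecular weight; no compound table is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import KineticDataset

__all__ = [
    "KineticFit",
    "YieldSummary",
    "FitError",
    "fit_michaelis_menten",
    "yield_metrics",
    "round_half_up",
    "read_kinetics_csv",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge after bounded restarts."""


@dataclass
class KineticFit:
    km: float  # µM
    vmax: float  # µM/s
    kcat: float | None  # 1/s; None when enzyme concentration unknown
    se_km: float
    se_vmax: float
    r2: float
    n: int
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


@dataclass
class YieldSummary:
    specific_yield: float | None  # mg / g DCW
    fold_change: float | None  # display value, 2 decimals half-up
    fold_change_raw: float | None
    fraction_intracellular: float | None  # %
    fraction_extracellular: float | None  # %
    total_titer: float  # mg/L
    component_titers: dict[str, float]


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(data: KineticDataset) -> KineticFit:
    """Fit v = Vmax*S/(Km+S) to initial-rate data.

    Requires >= 3 distinct substrate concentrations. Initial values come
    from a Lineweaver-Burk regression on the positive-rate points; up to
    five perturbed restarts are attempted on non-convergence. A Km
    estimate collapsing toward 0 or far beyond the sampled range is
    flagged in ``warnings``.
    """
    s = np.asarray(data.substrate_concs, dtype=float)
    v = np.asarray(data.rates, dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")

    p0 = _lineweaver_burk_init(s, v)
    rng = np.random.default_rng(12345)
    last_exc: Exception | None = None
    for attempt in range(6):
        trial = p0 if attempt == 0 else p0 * rng.uniform(0.3, 3.0, size=2)
        try:
            popt, pcov = curve_fit(
                _mm, s, v, p0=trial, method="lm", maxfev=20000
            )
            if np.all(np.isfinite(popt)) and popt[0] > 0 and popt[1] > 0:
                break
        except (RuntimeError, ValueError) as exc:
            last_exc = exc
    else:
        raise FitError(
            f"Michaelis-Menten fit did not converge after restarts "
            f"(n={len(s)}, S range {s.min():g}-{s.max():g}): {last_exc}"
        )

    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = v - _mm(s, *popt)
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    warn: list[str] = []
    if km < s.min() / 100.0 or km > s.max() * 100.0:
        warn.append(f"Km estimate {km:g} far outside sampled range")
    kcat = vmax / data.enzyme_conc if data.enzyme_conc else None
    return KineticFit(
        km=km,
        vmax=vmax,
        kcat=kcat,
        se_km=float(se[1]),
        se_vmax=float(se[0]),
        r2=r2,
        n=len(s),
        warnings=warn,
    )


def _lineweaver_burk_init(s: np.ndarray, v: np.ndarray) -> np.ndarray:
    mask = v > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / s[mask], 1.0 / v[mask], 1)
        if intercept > 0:
            vmax0 = 1.0 / intercept
            km0 = slope * vmax0
            if km0 > 0:
                return np.array([vmax0, km0])
    return np.array([max(v.max(), 1e-9) * 1.5, float(np.median(s))])


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (so 1.684782... -> 1.68, 0.125 -> 0.13)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def yield_metrics(
    component_titers: dict[str, float],
    dcw: float | None = None,
    specific_yield: float | None = None,
    baseline_specific_yield: float | None = None,
    extracellular_fraction: float | None = None,
) -> YieldSummary:
    """Fermentation yield arithmetic.

    ``specific_yield`` (mg/g DCW) may be given directly or derived as
    total titer / dcw; fold change is specific yield over the baseline
    strain's; the intracellular fraction is 100 minus the extracellular
    percentage; the total titer is the sum of component titers.
    """
    if any(t < 0 for t in component_titers.values()):
        raise ValueError("titers must be non-negative")
    total = float(sum(component_titers.values()))
    if specific_yield is None and dcw is not None:
        if dcw <= 0:
            raise ValueError("dcw must be positive")
        specific_yield = total / dcw
    fold = fold_raw = None
    if baseline_specific_yield is not None:
        if baseline_specific_yield == 0:
            raise ZeroDivisionError("baseline specific yield is zero")
        if specific_yield is None:
            raise ValueError("fold change needs a specific yield")
        fold_raw = specific_yield / baseline_specific_yield
        fold = round_half_up(fold_raw, 2)
    intra = extra = None
    if extracellular_fraction is not None:
        if not (0.0 <= extracellular_fraction <= 100.0):
            raise ValueError("extracellular fraction must be in [0, 100]")
        extra = float(extracellular_fraction)
        intra = 100.0 - extra
    return YieldSummary(
        specific_yield=specific_yield,
        fold_change=fold,
        fold_change_raw=fold_raw,
        fraction_intracellular=intra,
        fraction_extracellular=extra,
        total_titer=total,
        component_titers=dict(component_titers),
    )


def read_kinetics_csv(path) -> KineticDataset:
    """Read a kinetics CSV (columns S_uM, rate_uM_per_s; optional first
    comment line ``# enzyme_conc_uM=<x> noise_sd=<y>``)."""
    path = Path(path)
    first = path.read_text().splitlines()[0]
    enzyme_conc, noise_sd = 1.0, 0.0
    if first.startswith("#"):
        meta = dict(item.split("=") for item in first.lstrip("# ").split() if "=" in item)
        enzyme_conc = float(meta.get("enzyme_conc_uM", 1.0))
        noise_sd = float(meta.get("noise_sd", 0.0))
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    return KineticDataset(
        substrate_concs=frame["S_uM"].to_numpy(),
        rates=frame["rate_uM_per_s"].to_numpy(),
        enzyme_conc=enzyme_conc,
        noise_sd=noise_sd,
    )
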