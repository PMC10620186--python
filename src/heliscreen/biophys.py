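"""Biophysical models for trimerizer validation.

Covers the quantitative tools used to confirm cooperative ternary-complex
formation: steady-state 1:1 SPR affinity fits, percent-ternary-complex
from expected vs observed SPR responses, four-parameter logistic (4PL)
and biphasic dose-response fits, and an explicit mass-action model of the
presenter : Helicon : target ternary equilibrium with a cooperativity
factor alpha. Non-cooperative heterobifunctional binders (alpha = 1)
show the classic bell-shaped "hook" — at high ligand dose, saturated
binary complexes outcompete the ternary complex — while strongly
cooperative trimerizers do not over practical dose ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "BindingIsotherm",
    "FitResult",
    "TernarySystem",
    "fit_steady_state",
    "percent_ternary",
    "fit_4pl",
    "fit_biphasic",
    "solve_ternary",
    "ternary_signal",
]


@dataclass
class BindingIsotherm:
    conc: np.ndarray  # nM
    response: np.ndarray

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.conc.shape != self.response.shape:
            raise ValueError("conc and response must have equal length")
        if (self.conc < 0).any():
            raise ValueError("concentrations must be non-negative")


@dataclass
class FitResult:
    params: dict[str, float]
    residuals: np.ndarray
    converged: bool
    flags: list[str] = field(default_factory=list)


# -- steady-state 1:1 affinity ------------------------------------------------


def steady_state_model(conc: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    """R(C) = Rmax * C / (KD + C); R(KD) = Rmax/2."""
    conc = np.asarray(conc, dtype=float)
    return rmax * conc / (kd + conc)


def fit_steady_state(iso: BindingIsotherm) -> FitResult:
    """Least-squares fit of the 1:1 steady-state affinity model."""
    if len(iso.conc) < 4:
        raise ValueError("need at least 4 concentrations spanning the transition")
    rmax0 = float(iso.response.max())
    flags: list[str] = []
    if rmax0 <= 0:
        return FitResult(
            {"kd": float("nan"), "rmax": 0.0},
            iso.response.copy(),
            converged=True,
            flags=["kd_unidentifiable"],
        )
    half = rmax0 / 2
    kd0 = float(iso.conc[np.argmin(np.abs(iso.response - half))]) or float(np.median(iso.conc[iso.conc > 0]))
    try:
        popt, _ = curve_fit(
            steady_state_model, iso.conc, iso.response, p0=[kd0, rmax0], maxfev=20000
        )
        converged = True
    except RuntimeError as exc:
        return FitResult({"kd": kd0, "rmax": rmax0}, iso.response, False, [f"no_convergence: {exc}"])
    kd, rmax = float(popt[0]), float(popt[1])
    resid = iso.response - steady_state_model(iso.conc, kd, rmax)
    if kd > iso.conc.max():
        flags.append("kd_above_dose_range")
    return FitResult({"kd": kd, "rmax": rmax}, resid, converged, flags)


# -- percent ternary complex (SPR ABA) ---------------------------------------


def percent_ternary(
    rmax_obs: float,
    r_immob: float,
    mw_immobilized: float,
    mw_helicon: float,
    mw_analyte: float,
    include_helicon: bool = True,
) -> float:
    """Percent of ternary complex formed on an SPR surface.

    Rmax_expected = R_immob * (MW_helicon + MW_analyte) / MW_immobilized,
    i.e. the response if every immobilized molecule carried one Helicon
    and one analyte; percent = 100 * Rmax_obs / Rmax_expected. The
    Helicon's mass (2-3 kDa) can be excluded with
    ``include_helicon=False``.
    """
    if mw_immobilized <= 0:
        raise ValueError("MW of the immobilized component must be positive")
    if r_immob <= 0:
        raise ValueError("immobilization response must be positive")
    added = mw_analyte + (mw_helicon if include_helicon else 0.0)
    rmax_expected = r_immob * added / mw_immobilized
    return 100.0 * rmax_obs / rmax_expected


# -- dose-response fits -------------------------------------------------------


def four_pl(dose: np.ndarray, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    """4PL with variable slope: y = bottom + (top-bottom)/(1+(EC50/x)^hill)."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


def fit_4pl(dose: np.ndarray, signal: np.ndarray) -> FitResult:
    """Least-squares four-parameter dose-response fit."""
    dose = np.asarray(dose, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(dose) < 5:
        raise ValueError("need at least 5 doses")
    lo, hi = float(signal.min()), float(signal.max())
    ascending = signal[np.argmax(dose)] >= signal[np.argmin(dose)]
    p0 = [lo, hi, float(np.sqrt(dose[dose > 0].min() * dose.max())), 1.0 if ascending else -1.0]
    try:
        popt, _ = curve_fit(four_pl, dose, signal, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        return FitResult(dict(zip(["bottom", "top", "ec50", "hill"], p0)), signal, False, [str(exc)])
    params = dict(zip(["bottom", "top", "ec50", "hill"], map(float, popt)))
    resid = signal - four_pl(dose, **params)
    flags = [] if dose[dose > 0].min() <= params["ec50"] <= dose.max() else ["ec50_outside_dose_range"]
    return FitResult(params, resid, True, flags)


def biphasic(
    dose: np.ndarray, bottom: float, top: float, ec50_rise: float, ec50_fall: float, hill: float
) -> np.ndarray:
    """Bell-shaped product of an ascending and a descending logistic
    sharing one plateau and slope. For equal slopes the peak sits at the
    geometric mean of the two EC50s.
    """
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rise = 1.0 / (1.0 + (ec50_rise / dose) ** hill)
        fall = 1.0 / (1.0 + (dose / ec50_fall) ** hill)
    return bottom + (top - bottom) * rise * fall


def fit_biphasic(dose: np.ndarray, signal: np.ndarray) -> FitResult:
    """Fit the bell-shaped biphasic curve; monotone data fall back to 4PL.

    Reports ``peak_dose`` (geometric mean of the two EC50s) alongside the
    fitted parameters.
    """
    dose = np.asarray(dose, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(dose) < 7:
        raise ValueError("need at least 7 doses")
    order = np.argsort(dose)
    d_sorted, s_sorted = dose[order], signal[order]
    peak_idx = int(np.argmax(s_sorted))
    span = s_sorted.max() - s_sorted.min()
    # monotone (or edge-peaked) data cannot constrain two EC50s
    interior_peak = 0 < peak_idx < len(s_sorted) - 1
    falls_after_peak = s_sorted[-1] < s_sorted[peak_idx] - 0.05 * span
    if not (interior_peak and falls_after_peak):
        res = fit_4pl(dose, signal)
        res.flags.append("monotone_fallback_4pl")
        return res
    peak_dose0 = d_sorted[peak_idx]
    p0 = [float(s_sorted.min()), float(s_sorted.max()), peak_dose0 / 3, peak_dose0 * 3, 1.0]
    lower = [-np.inf, -np.inf, 0.0, 0.0, 0.0]
    try:
        popt, _ = curve_fit(
            biphasic, dose, signal, p0=p0, bounds=(lower, np.inf), maxfev=40000
        )
    except RuntimeError as exc:
        return FitResult(dict(zip(["bottom", "top", "ec50_rise", "ec50_fall", "hill"], p0)),
                         signal, False, [str(exc)])
    params = dict(zip(["bottom", "top", "ec50_rise", "ec50_fall", "hill"], map(float, popt)))
    params["peak_dose"] = float(np.sqrt(abs(params["ec50_rise"] * params["ec50_fall"])))
    resid = signal - biphasic(dose, *popt)
    return FitResult(params, resid, True, [])


# -- ternary equilibrium ------------------------------------------------------


@dataclass
class TernarySystem:
    """Presenter (A) + target (T) + Helicon (H) mass-action equilibrium.

    Binary steps: AH = A*H/K_AH, TH = T*H/K_TH. The ternary step is
    cooperativity-scaled: ATH = AH*T/(K_TH/alpha) (equivalently
    alpha*A*T*H/(K_AH*K_TH)); alpha > 1 means the presenter-bound Helicon
    binds target more tightly than free Helicon. Totals and constants in
    nM.
    """

    a_total: float
    t_total: float
    h_total: float
    k_ah: float
    k_th: float
    alpha: float = 1.0
    species: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.a_total, self.t_total, self.h_total) < 0:
            raise ValueError("totals must be non-negative")
        if min(self.k_ah, self.k_th) <= 0 or self.alpha <= 0:
            raise ValueError("dissociation constants and alpha must be positive")


def _free_a(sys: TernarySystem, h: float, t: float) -> float:
    return sys.a_total / (1.0 + h / sys.k_ah + sys.alpha * h * t / (sys.k_ah * sys.k_th))


def _free_t(sys: TernarySystem, h: float) -> float:
    """Free target consistent with free H (A eliminated in closed form)."""
    if sys.t_total == 0:
        return 0.0

    def g(t: float) -> float:
        a = _free_a(sys, h, t)
        return t * (1.0 + h / sys.k_th + sys.alpha * h * a / (sys.k_ah * sys.k_th)) - sys.t_total

    if g(sys.t_total) <= 0:
        return sys.t_total
    return brentq(g, 0.0, sys.t_total, xtol=1e-300, rtol=1e-14)


def solve_ternary(system: TernarySystem) -> dict[str, float]:
    """Solve the coupled equilibria for all six species.

    Nested bracketed root finding: the total-H residual is monotone in
    free H, and for each trial H the total-T residual is monotone in free
    T, so both 1-D problems have a unique bracketed root. Mass balance
    holds to ~1e-9 relative.
    """
    sys = system

    def h_residual(h: float) -> float:
        t = _free_t(sys, h)
        a = _free_a(sys, h, t)
        ah = a * h / sys.k_ah
        th = t * h / sys.k_th
        ath = sys.alpha * a * t * h / (sys.k_ah * sys.k_th)
        return h + ah + th + ath - sys.h_total

    if sys.h_total == 0:
        h = 0.0
    elif h_residual(sys.h_total) <= 0:
        h = sys.h_total
    else:
        h = brentq(h_residual, 0.0, sys.h_total, xtol=1e-300, rtol=1e-14)
    t = _free_t(sys, h)
    a = _free_a(sys, h, t)
    species = {
        "A": a,
        "T": t,
        "H": h,
        "AH": a * h / sys.k_ah,
        "TH": t * h / sys.k_th,
        "ATH": sys.alpha * a * t * h / (sys.k_ah * sys.k_th),
    }
    system.species = species
    return species


def ternary_signal(
    doses: np.ndarray,
    a_total: float,
    t_total: float,
    k_ah: float,
    k_th: float,
    alpha: float,
) -> np.ndarray:
    """Ternary-complex concentration as a function of Helicon dose (nM)."""
    out = []
    for h0 in np.asarray(doses, dtype=float):
        sysm = TernarySystem(a_total, t_total, h0, k_ah, k_th, alpha)
        out.append(solve_ternary(sysm)["ATH"])
    return np.array(out)
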