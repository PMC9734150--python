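"""Enzyme-kinetics models for allosteric activation of a two-subunit enzyme.

Implements the steady-state and equilibrium models used to characterise
ATP phosphoribosyltransferase (ATPPRT) variants: Michaelis–Menten substrate
saturation, a Boltzmann sigmoid for thermal-denaturation (DSF) melting
curves, a tight-binding quadratic for activation of the catalytic subunit
(HisGS) by the regulatory protein (HisZ) when free-regulator depletion
matters, the derived holoenzyme (complex) concentration, and the Hill
equation for cooperative sigmoidal activation.

Each model has a plain evaluator and an ``lmfit``-based nonlinear
least-squares fit that reports asymptotic standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

__all__ = [
    "KineticsError",
    "FitError",
    "RateMeasurementSet",
    "michaelis_rate",
    "melting_fraction",
    "binding_rate",
    "complex_concentration",
    "hill_rate",
    "MichaelisFit",
    "MeltingFit",
    "BindingFit",
    "HillFit",
    "fit_michaelis",
    "fit_melting",
    "fit_binding",
    "fit_hill",
    "FoldChangeReport",
    "fold_change",
]


class KineticsError(ValueError):
    pass


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or yields invalid parameters."""


@dataclass(frozen=True)
class RateMeasurementSet:
    """Initial-rate (or signal) measurements versus a varied concentration.

    ``x`` is the varied quantity — substrate S in mM, regulator Z in μM, or
    temperature in °C for melting curves; ``v`` the measured rate or signal.
    ``fixed`` carries named constants such as total enzyme ``E_T`` (μM) or
    catalytic-subunit concentration ``G`` (μM).
    """

    x: np.ndarray
    v: np.ndarray
    fixed: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if x.shape != v.shape or x.ndim != 1:
            raise KineticsError("x and v must be 1-D arrays of equal length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "v", v)
        for name, val in self.fixed.items():
            if name in ("E_T", "G") and not val > 0:
                raise KineticsError(f"fixed constant {name} must be > 0, got {val}")


# ---------------------------------------------------------------------------
# evaluators
# ---------------------------------------------------------------------------

def michaelis_rate(S, k_cat: float, K_M: float):
    """Michaelis–Menten turnover v/E_T = k_cat·S/(K_M + S)."""
    S = np.asarray(S, dtype=float)
    return k_cat * S / (K_M + S)


def melting_fraction(T, LL: float, UL: float, T_m: float, c: float):
    """Boltzmann sigmoid for fraction unfolded vs temperature (°C).

    F_U = LL + (UL − LL) / (1 + exp((T_m − T)/c)); LL/UL are the folded and
    unfolded baselines, T_m the melting temperature, c the transition slope.
    """
    T = np.asarray(T, dtype=float)
    arg = np.clip((T_m - T) / c, -700.0, 700.0)  # avoid exp overflow at c -> 0
    return LL + (UL - LL) / (1.0 + np.exp(arg))


def _tight_binding_complex(G, Z, K_D):
    G = np.asarray(G, dtype=float)
    Z = np.asarray(Z, dtype=float)
    s = G + Z + K_D
    disc = s * s - 4.0 * G * Z
    scale = np.maximum(s * s, 1.0)
    if np.any(disc < -1e-9 * scale):
        raise KineticsError("negative discriminant in tight-binding expression")
    return (s - np.sqrt(np.clip(disc, 0.0, None))) / 2.0


def binding_rate(Z, G: float, V_max: float, K_D_app: float):
    """Tight-binding activation: rate vs regulator concentration Z (μM).

    v = V_max · (G + Z + K_D − √((G+Z+K_D)² − 4GZ)) / (2G), the quadratic
    solution for complex formation when Z is not in large excess over the
    catalytic subunit G, so free-regulator depletion cannot be neglected.
    """
    if not G > 0:
        raise KineticsError("G must be > 0")
    return V_max * _tight_binding_complex(G, Z, K_D_app) / G


def complex_concentration(G, Z, K_D_app: float):
    """Equilibrium holoenzyme concentration from total G, total Z and K_D.

    ATPPRT = (G + Z + K_D − √((G+Z+K_D)² − 4GZ)) / 2, bounded by min(G, Z).
    """
    G = np.asarray(G, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if np.any(G < 0) or np.any(Z < 0):
        raise KineticsError("concentrations must be ≥ 0")
    return _tight_binding_complex(G, Z, K_D_app)


def hill_rate(Z, V_max: float, K_half: float, h: float, form: str = "standard"):
    """Hill equation for sigmoidal activation.

    ``standard`` form: v = V_max·Z^h/(K_0.5^h + Z^h), dimensionally
    consistent, with K_0.5 the concentration at the inflection point.
    ``as_printed`` form keeps K_0.5 un-exponentiated,
    v = V_max·Z^h/(K_0.5 + Z^h); both reduce to the hyperbola at h = 1.
    """
    Z = np.asarray(Z, dtype=float)
    if not h > 0:
        raise KineticsError("Hill coefficient must be > 0")
    zh = np.power(Z, h)
    if form == "standard":
        return V_max * zh / (K_half**h + zh)
    if form == "as_printed":
        return V_max * zh / (K_half + zh)
    raise KineticsError(f"unknown Hill form {form!r}")


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MichaelisFit:
    k_cat: float
    K_M: float
    k_cat_err: float | None
    K_M_err: float | None
    residual_ss: float
    data: RateMeasurementSet

    def as_dict(self) -> dict:
        return {
            "model": "michaelis",
            "k_cat": self.k_cat,
            "K_M": self.K_M,
            "k_cat_err": self.k_cat_err,
            "K_M_err": self.K_M_err,
            "residual_ss": self.residual_ss,
        }


@dataclass(frozen=True)
class MeltingFit:
    T_m: float
    c: float
    LL: float
    UL: float
    errors: dict
    residual_ss: float

    def as_dict(self) -> dict:
        return {
            "model": "melting",
            "T_m": self.T_m,
            "c": self.c,
            "LL": self.LL,
            "UL": self.UL,
            "errors": self.errors,
            "residual_ss": self.residual_ss,
        }


@dataclass(frozen=True)
class BindingFit:
    V_max: float
    K_D_app: float
    G: float
    V_max_err: float | None
    K_D_app_err: float | None
    residual_ss: float

    def complex_at(self, Z) -> np.ndarray:
        """Holoenzyme concentration at regulator concentration(s) Z (μM)."""
        return complex_concentration(self.G, Z, self.K_D_app)

    def as_dict(self) -> dict:
        return {
            "model": "binding",
            "V_max": self.V_max,
            "K_D_app": self.K_D_app,
            "G": self.G,
            "V_max_err": self.V_max_err,
            "K_D_app_err": self.K_D_app_err,
            "residual_ss": self.residual_ss,
        }


@dataclass(frozen=True)
class HillFit:
    V_max: float
    K_half: float
    h: float
    form: str
    errors: dict
    residual_ss: float
    descriptive_only: bool = True
    """Hill fits to non-pseudo-first-order titrations describe the sigmoidal
    shape; the fitted constants are apparent, not thermodynamic."""

    def as_dict(self) -> dict:
        return {
            "model": "hill",
            "form": self.form,
            "V_max": self.V_max,
            "K_0.5": self.K_half,
            "h": self.h,
            "errors": self.errors,
            "residual_ss": self.residual_ss,
            "descriptive_only": self.descriptive_only,
        }


def _run_fit(model: Model, params, x, y) -> "lmfit.model.ModelResult":
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(y, params, x=x, method="leastsq",
                           fit_kws={"xtol": 1e-12, "ftol": 1e-12})
    if not result.success:
        raise FitError(f"fit did not converge: {result.message}")
    return result


def _stderr(result, name):
    p = result.params[name]
    return float(p.stderr) if p.stderr is not None else None


def fit_michaelis(data: RateMeasurementSet) -> MichaelisFit:
    """Fit a substrate-saturation curve; returns k_cat (s⁻¹) and K_M (mM).

    If ``data.fixed`` contains ``E_T`` the rates are divided by it first so
    the fitted amplitude is the turnover number.
    """
    S, v = data.x, data.v
    if len(np.unique(S)) < 4:
        raise KineticsError("need ≥ 4 distinct substrate concentrations")
    if "E_T" in data.fixed:
        v = v / data.fixed["E_T"]
    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        raise FitError("rates are non-positive; no saturation to fit")
    half = vmax0 / 2.0
    km0 = float(S[np.argmin(np.abs(v - half))]) or float(np.median(S[S > 0]))
    model = Model(lambda x, k_cat, K_M: michaelis_rate(x, k_cat, K_M))
    params = model.make_params(k_cat=dict(value=vmax0, min=0),
                               K_M=dict(value=km0, min=0))
    res = _run_fit(model, params, S, v)
    kcat = float(res.params["k_cat"].value)
    km = float(res.params["K_M"].value)
    if kcat <= 0 or km <= 0:
        raise FitError("non-positive parameter estimate")
    return MichaelisFit(kcat, km, _stderr(res, "k_cat"), _stderr(res, "K_M"),
                        float(np.sum(res.residual**2)), data)


def fit_melting(curve: RateMeasurementSet) -> MeltingFit:
    """Fit a DSF melting curve to the Boltzmann sigmoid (T in °C)."""
    T, y = curve.x, curve.v
    span = float(np.ptp(y))
    if span == 0:
        raise FitError("flat melting signal: no unfolding transition to fit")
    ll0, ul0 = float(np.min(y)), float(np.max(y))
    mid = (ll0 + ul0) / 2.0
    tm0 = float(T[np.argmin(np.abs(y - mid))])
    model = Model(lambda x, LL, UL, T_m, c: melting_fraction(x, LL, UL, T_m, c))
    params = model.make_params(LL=ll0, UL=ul0, T_m=tm0,
                               c=dict(value=2.0, min=1e-6))
    res = _run_fit(model, params, T, y)
    ll, ul = float(res.params["LL"].value), float(res.params["UL"].value)
    tm, c = float(res.params["T_m"].value), float(res.params["c"].value)
    if not ll < ul:
        raise FitError("fitted baselines do not describe an unfolding transition (LL ≥ UL)")
    if not (T.min() <= tm <= T.max()):
        raise FitError(f"fitted T_m {tm:.1f} °C outside the scanned range")
    errors = {k: _stderr(res, k) for k in ("LL", "UL", "T_m", "c")}
    return MeltingFit(tm, c, ll, ul, errors, float(np.sum(res.residual**2)))


def fit_binding(data: RateMeasurementSet, G: float | None = None) -> BindingFit:
    """Fit tight-binding activation data; G (μM) is fixed, not fitted.

    Reports V_max and the apparent dissociation constant K_D^app (μM).
    """
    if G is None:
        G = data.fixed.get("G")
    if G is None or not G > 0:
        raise KineticsError("catalytic-subunit concentration G must be given and > 0")
    Z, v = data.x, data.v
    if len(np.unique(Z)) < 5:
        raise KineticsError("need ≥ 5 regulator concentrations")
    vmax0 = float(np.max(v))
    half = vmax0 / 2.0
    kd0 = max(float(Z[np.argmin(np.abs(v - half))]), 1e-3)
    model = Model(lambda x, V_max, K_D: binding_rate(x, G, V_max, K_D))
    params = model.make_params(V_max=dict(value=vmax0, min=0),
                               K_D=dict(value=kd0, min=1e-9))
    res = _run_fit(model, params, Z, v)
    vmax = float(res.params["V_max"].value)
    kd = float(res.params["K_D"].value)
    if kd <= 0:
        raise FitError("non-positive K_D estimate")
    return BindingFit(vmax, kd, float(G), _stderr(res, "V_max"),
                      _stderr(res, "K_D"), float(np.sum(res.residual**2)))


def fit_hill(data: RateMeasurementSet, form: str = "standard") -> HillFit:
    """Fit sigmoidal activation data to the Hill equation.

    The fit is descriptive: when regulator and catalytic-subunit
    concentrations are comparable the pseudo-first-order assumption behind
    the Hill form does not hold, so K_0.5 and h characterise the shape of
    the titration, not microscopic binding constants.
    """
    Z, v = data.x, data.v
    if len(np.unique(Z)) < 6:
        raise KineticsError("need ≥ 6 regulator concentrations spanning the inflection")
    vmax0 = float(np.max(v))
    half = vmax0 / 2.0
    k0 = max(float(Z[np.argmin(np.abs(v - half))]), 1e-3)
    model = Model(lambda x, V_max, K_half, h: hill_rate(x, V_max, K_half, h, form=form))
    params = model.make_params(V_max=dict(value=vmax0, min=0),
                               K_half=dict(value=k0, min=1e-9),
                               h=dict(value=1.5, min=1e-3, max=10.0))
    res = _run_fit(model, params, Z, v)
    errors = {k: _stderr(res, k) for k in ("V_max", "K_half", "h")}
    return HillFit(float(res.params["V_max"].value),
                   float(res.params["K_half"].value),
                   float(res.params["h"].value),
                   form, errors, float(np.sum(res.residual**2)))


# ---------------------------------------------------------------------------
# fold-change arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldChangeReport:
    """Ratio of two rate constants, e.g. activation by the regulatory subunit
    (k_cat of the holoenzyme over v/E_T of the free catalytic subunit) or
    catalytic impairment (wild-type over mutant rate)."""

    numerator: float
    denominator: float
    numerator_label: str
    denominator_label: str
    unit: str
    fold: float
    fold_rounded: int

    def __str__(self) -> str:
        return (f"{self.numerator_label} / {self.denominator_label} = "
                f"{self.fold:.4g} ({self.fold_rounded}-fold)")


def fold_change(numerator: float, denominator: float, *,
                numerator_label: str = "numerator",
                denominator_label: str = "denominator",
                numerator_unit: str = "s^-1",
                denominator_unit: str = "s^-1") -> FoldChangeReport:
    """Fold ratio of two rate constants; units must cancel.

    The rounded fold uses round-half-away-from-zero to the nearest integer,
    the convention used when quoting "N-fold" changes.
    """
    if numerator_unit != denominator_unit:
        raise KineticsError(
            f"unit mismatch: {numerator_unit} vs {denominator_unit}")
    if not denominator > 0:
        raise KineticsError("denominator must be > 0")
    fold = numerator / denominator
    rounded = int(math.floor(abs(fold) + 0.5)) * (1 if fold >= 0 else -1)
    return FoldChangeReport(numerator, denominator, numerator_label,
                            denominator_label, numerator_unit, fold, rounded)
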