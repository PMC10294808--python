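"""Sorption kinetics, adsorption isotherms and drug-release model fitting.

Implements the standard empirical laws used for molecular uptake and
release on LDH sorbents:

* kinetics (uptake Q(t), mg/g): pseudo-first-order, pseudo-second-order,
  Elovich;
* isotherms (Q vs equilibrium concentration): Freundlich ``Q = k C^(1/n)``
  and Sips ``Q = Qm K C^m / (1 + K C^m)`` (m > 1 flags positive
  cooperativity between adsorbed molecules);
* release (cumulative fraction F(t)): zero order, first order, Higuchi,
  Hixson-Crowell and Korsmeyer-Peppas ``F = k t^n`` (fitted only below 60%
  release, its validity domain; n < 0.5 labels Fickian diffusion).

All fits are multi-start nonlinear least squares on the untransformed
response; R^2 is always ``1 - SS_res/SS_tot`` on that response so that
models of different form are comparable.  Standard errors come from the
Jacobian at the optimum (Gauss-Newton approximation).

Concentrations are in ppm == mg/L (dilute aqueous assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticDataset",
    "IsothermDataset",
    "ReleaseDataset",
    "FitResult",
    "CalibrationLine",
    "KINETIC_MODELS",
    "RELEASE_MODELS",
    "kinetic_model",
    "release_model",
    "freundlich",
    "sips",
    "fit_kinetics",
    "fit_freundlich",
    "fit_sips",
    "fit_release",
    "compare_models",
    "loading_from_concentration",
    "concentration_from_absorbance",
]


# ---------------------------------------------------------------------------
# datasets


@dataclass
class KineticDataset:
    """Uptake Q (mg/g) versus contact time t (minutes)."""

    t: np.ndarray
    Q: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if len(self.t) != len(self.Q):
            raise ValueError("t and Q length mismatch")
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be non-negative and strictly increasing")
        if np.any(self.Q < 0):
            raise ValueError("Q must be non-negative")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_min": self.t, "Q_mg_per_g": self.Q}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "KineticDataset":
        df = pd.read_csv(path)
        return cls(df["t_min"].to_numpy(), df["Q_mg_per_g"].to_numpy())


@dataclass
class IsothermDataset:
    """Uptake Q (mg/g) versus equilibrium concentration C_eq (ppm)."""

    C_eq: np.ndarray
    Q: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.C_eq = np.asarray(self.C_eq, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if len(self.C_eq) != len(self.Q):
            raise ValueError("C_eq and Q length mismatch")
        if np.any(self.C_eq < 0) or np.any(self.Q < 0):
            raise ValueError("C_eq and Q must be non-negative")

    def to_csv(self, path) -> None:
        pd.DataFrame({"Ceq_ppm": self.C_eq, "Q_mg_per_g": self.Q}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IsothermDataset":
        df = pd.read_csv(path)
        return cls(df["Ceq_ppm"].to_numpy(), df["Q_mg_per_g"].to_numpy())


@dataclass
class ReleaseDataset:
    """Cumulative released fraction F in [0, 1] versus time t (minutes).

    F must be non-decreasing up to measurement noise; decreases beyond
    ``noise_tolerance`` are rejected.
    """

    t: np.ndarray
    F: np.ndarray
    metadata: dict = field(default_factory=dict)
    noise_tolerance: float = 0.05

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if len(self.t) != len(self.F):
            raise ValueError("t and F length mismatch")
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be non-negative and strictly increasing")
        if np.any(self.F < 0) or np.any(self.F > 1):
            raise ValueError("released fraction must lie in [0, 1]")
        if np.any(np.diff(self.F) < -self.noise_tolerance):
            raise ValueError("released fraction decreases by more than the noise tolerance")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_min": self.t, "fraction_released": self.F}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReleaseDataset":
        df = pd.read_csv(path)
        return cls(df["t_min"].to_numpy(), df["fraction_released"].to_numpy())


@dataclass
class FitResult:
    """A fitted model: parameters, standard errors, R^2 and residuals."""

    model: str
    params: dict
    se: dict
    r2: float
    residuals: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.r2 > 1 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")
        if any(v < 0 for v in self.se.values() if np.isfinite(v)):
            raise ValueError("standard errors must be non-negative")

    @property
    def n_params(self) -> int:
        return len(self.params)

    def __repr__(self):
        p = ", ".join(
            f"{k}={v:.4g}+-{self.se.get(k, float('nan')):.2g}" for k, v in self.params.items()
        )
        return f"FitResult({self.model}: {p}, R2={self.r2:.4f})"


@dataclass(frozen=True)
class CalibrationLine:
    """UV-vis calibration: absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float = 0.0
    r2: float = 1.0
    wavelength: float = 464.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    @classmethod
    def from_standards(cls, conc, absorbance, wavelength: float = 464.0) -> "CalibrationLine":
        conc = np.asarray(conc, float)
        absorbance = np.asarray(absorbance, float)
        slope, intercept = np.polyfit(conc, absorbance, 1)
        pred = slope * conc + intercept
        ss_tot = np.sum((absorbance - absorbance.mean()) ** 2)
        r2 = 1.0 - np.sum((absorbance - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
        return cls(float(slope), float(intercept), float(r2), wavelength)


# ---------------------------------------------------------------------------
# model functions


def _pfo(t, Qe, k1):
    return Qe * (1.0 - np.exp(-k1 * t))


def _pso(t, Qe, k2):
    return Qe**2 * k2 * t / (1.0 + Qe * k2 * t)


def _elovich(t, alpha, beta):
    return np.log1p(alpha * beta * t) / beta


def freundlich(C, k, n):
    """Freundlich isotherm Q = k C^(1/n)."""
    return k * np.power(C, 1.0 / n)


def sips(C, Qm, Ks, m):
    """Sips (Langmuir-Freundlich) isotherm Q = Qm Ks C^m / (1 + Ks C^m)."""
    x = Ks * np.power(C, m)
    return Qm * x / (1.0 + x)


def _zero_order(t, k):
    return k * t


def _first_order(t, k):
    return 1.0 - np.exp(-k * t)


def _higuchi(t, k):
    return k * np.sqrt(t)


def _hixson_crowell(t, k):
    return 1.0 - np.clip(1.0 - k * t, 0.0, None) ** 3


def _korsmeyer_peppas(t, k, n):
    return k * np.power(t, n)


KINETIC_MODELS = {
    "pfo": (_pfo, ("Qe", "k1")),
    "pso": (_pso, ("Qe", "k2")),
    "elovich": (_elovich, ("alpha", "beta")),
}

RELEASE_MODELS = {
    "zero": (_zero_order, ("k",)),
    "first": (_first_order, ("k",)),
    "higuchi": (_higuchi, ("k",)),
    "hixson_crowell": (_hixson_crowell, ("k",)),
    "korsmeyer_peppas": (_korsmeyer_peppas, ("k", "n")),
}


def kinetic_model(name: str):
    """Kinetic law Q(t; params) by name (pfo | pso | elovich)."""
    try:
        return KINETIC_MODELS[name][0]
    except KeyError:
        raise ValueError(
            f"unknown kinetic model {name!r}; choose from {sorted(KINETIC_MODELS)}"
        ) from None


def release_model(name: str):
    """Release law F(t; params) by name."""
    try:
        return RELEASE_MODELS[name][0]
    except KeyError:
        raise ValueError(
            f"unknown release model {name!r}; choose from {sorted(RELEASE_MODELS)}"
        ) from None


# ---------------------------------------------------------------------------
# fitting machinery


def _exp_safe(x: float) -> float:
    return float(np.exp(np.clip(x, -500, 500)))


def _weights(y: np.ndarray) -> np.ndarray:
    """Relative-error weights: measurement noise on these assays scales
    with the signal, so the loss is on relative residuals (with a floor to
    keep near-zero readings from dominating)."""
    y = np.abs(np.asarray(y, float))
    floor = 0.05 * y.max() if y.max() > 0 else 1.0
    return np.maximum(y, floor)


def _multistart_ls(func, x, y, starts, bounds):
    """Multi-start weighted least squares; returns (best_result, any_converged)."""
    lb, ub = (np.asarray(b, float) for b in bounds)
    w = _weights(y)
    best, best_cost, converged = None, np.inf, False
    for p0 in starts:
        p0 = np.minimum(np.maximum(np.asarray(p0, float), lb * (1 + 1e-12) + 1e-300),
                        np.where(np.isfinite(ub), ub, np.asarray(p0, float)))
        try:
            res = least_squares(
                lambda p: (func(x, *p) - y) / w, p0, bounds=(lb, ub), max_nfev=2000
            )
        except Exception:
            continue
        if np.isfinite(res.cost) and res.cost < best_cost:
            best, best_cost = res, res.cost
        converged = converged or bool(res.success)
    return best, converged


def _finish(model_name, func, x, y, res, converged, names, extra_flags=None):
    y = np.asarray(y, float)
    if res is None:
        return FitResult(
            model_name,
            {n: np.nan for n in names},
            {n: np.nan for n in names},
            -np.inf,
            np.full_like(y, np.nan),
            {"converged": False, **(extra_flags or {})},
        )
    p = res.x
    resid = func(x, *p) - y
    # R^2 on the untransformed response, comparable across models
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    # Gauss-Newton covariance of the weighted problem (res.jac/res.fun are
    # the weighted Jacobian/residuals, so this is consistent under the
    # relative-error model)
    dof = max(len(y) - len(p), 1)
    J = res.jac
    s2 = float(np.sum(res.fun**2)) / dof
    cov = np.linalg.pinv(J.T @ J) * s2
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return FitResult(
        model_name,
        dict(zip(names, (float(v) for v in p))),
        dict(zip(names, (float(v) for v in se))),
        float(min(r2, 1.0)),
        resid,
        {"converged": bool(converged), **(extra_flags or {})},
    )


def fit_kinetics(d: KineticDataset, model: str = "pso") -> FitResult:
    """Fit an uptake-kinetics law by multi-start nonlinear least squares.

    Non-convergence is reported through ``flags['converged']`` rather than
    an exception.
    """
    func, names = KINETIC_MODELS.get(model, (None, None))
    if func is None:
        raise ValueError(f"unknown kinetic model {model!r}")
    if len(d.t) < 4:
        raise ValueError("need at least 4 kinetic points")
    t, Q = d.t, d.Q
    qmax = max(Q.max(), 1e-12)
    t_half = t[len(t) // 2] if t[0] > 0 else max(t[1], 1e-6)
    if model == "pfo":
        starts = [(qmax * a, b / t_half) for a in (1.0, 1.3) for b in (0.2, 1.0, 5.0)]
        bounds = ([1e-12, 1e-12], [np.inf, np.inf])
    elif model == "pso":
        starts = [(qmax * a, b / (qmax * t_half)) for a in (1.0, 1.3) for b in (0.2, 1.0, 5.0)]
        bounds = ([1e-12, 1e-15], [np.inf, np.inf])
    else:  # elovich
        beta0 = 3.0 / qmax
        starts = [(a / (t_half * beta0), beta0 * b) for a in (0.5, 5.0, 50.0) for b in (0.5, 2.0)]
        bounds = ([1e-15, 1e-15], [np.inf, np.inf])
    res, conv = _multistart_ls(func, t, Q, starts, bounds)
    return _finish(model, func, t, Q, res, conv, names)


def fit_freundlich(d: IsothermDataset) -> FitResult:
    """Fit Q = k C^(1/n); the log-log line provides the principal start."""
    if len(d.C_eq) < 4:
        raise ValueError("need at least 4 isotherm points")
    if np.any(d.C_eq <= 0):
        raise ValueError("Freundlich fit requires C_eq > 0")
    C, Q = d.C_eq, d.Q
    pos = Q > 0
    if pos.sum() >= 2:
        b, a = np.polyfit(np.log(C[pos]), np.log(Q[pos]), 1)
        k0, n0 = _exp_safe(a), 1.0 / np.clip(b, 1e-3, None)
    else:
        k0, n0 = max(Q.max(), 1.0), 1.0
    starts = [(k0 * f, n0 * g) for f in (0.3, 1.0, 3.0) for g in (0.7, 1.0, 1.5)]
    bounds = ([1e-12, 0.05], [np.inf, 50.0])
    func, names = (lambda C, k, n: freundlich(C, k, n)), ("k", "n")
    res, conv = _multistart_ls(func, C, Q, starts, bounds)
    return _finish("freundlich", func, C, Q, res, conv, names)


def fit_sips(d: IsothermDataset) -> FitResult:
    """Fit the Sips isotherm.

    Without a plateau in the data the (Qm, Ks) pair is weakly identified;
    the fit is still returned, with correspondingly wide standard errors
    and ``flags['plateau']`` False.  ``flags['cooperative']`` records
    whether the fitted exponent exceeds 1.
    """
    if len(d.C_eq) < 5:
        raise ValueError("need at least 5 isotherm points for the 3-parameter Sips fit")
    C, Q = d.C_eq, d.Q
    qmax = max(Q.max(), 1e-12)
    cmid = max(float(np.median(C)), 1e-12)
    starts = [
        (qmax * a, cmid ** (-m), m)
        for a in (1.2, 2.0, 6.0)
        for m in (0.7, 1.0, 2.0, 3.0)
    ]
    bounds = ([1e-12, 1e-30, 0.05], [np.inf, np.inf, 20.0])
    func, names = (lambda C, Qm, Ks, m: sips(C, Qm, Ks, m)), ("Qm", "Ks", "m")
    res, conv = _multistart_ls(func, C, Q, starts, bounds)
    fit = _finish("sips", func, C, Q, res, conv, names)
    fit.flags["plateau"] = bool(res is not None and Q.max() >= 0.85 * res.x[0])
    fit.flags["cooperative"] = bool(fit.params.get("m", 0.0) > 1.0)
    return fit


def fit_release(d: ReleaseDataset, model: str = "korsmeyer_peppas") -> FitResult:
    """Fit a release law F(t).

    The Korsmeyer-Peppas power law is fitted only on points with F <= 0.6
    (its validity domain); fewer than 3 such points is an error.  The
    fitted exponent is classified: n < 0.5 labels Fickian diffusion.
    """
    func, names = RELEASE_MODELS.get(model, (None, None))
    if func is None:
        raise ValueError(f"unknown release model {model!r}")
    t, F = d.t, d.F
    if model == "korsmeyer_peppas":
        mask = F <= 0.6
        if mask.sum() < 3:
            raise ValueError(
                f"only {int(mask.sum())} points with F <= 0.6; the "
                "Korsmeyer-Peppas fit needs at least 3"
            )
        t, F = t[mask], F[mask]
        pos = (F > 0) & (t > 0)
        if pos.sum() >= 2:
            n0, logk0 = np.polyfit(np.log(t[pos]), np.log(F[pos]), 1)
            k0 = _exp_safe(logk0)
            n0 = float(np.clip(n0, 0.05, 2.5))
        else:
            n0, k0 = 0.5, 0.1
        starts = [(k0 * f, n0 * g) for f in (0.5, 1.0, 2.0) for g in (0.7, 1.0, 1.4)]
        bounds = ([1e-12, 0.01], [np.inf, 3.0])
    else:
        denom = {
            "zero": t.max(),
            "first": 1.0,
            "higuchi": np.sqrt(t.max()),
            "hixson_crowell": 3.0 * t.max(),
        }[model]
        scale = max(F.max() / max(denom, 1e-12), 1e-9)
        starts = [(scale * f,) for f in (0.3, 1.0, 3.0)]
        bounds = ([1e-12], [np.inf])
    res, conv = _multistart_ls(func, t, F, starts, bounds)
    fit = _finish(model, func, t, F, res, conv, names)
    if model == "korsmeyer_peppas" and np.isfinite(fit.params.get("n", np.nan)):
        n = fit.params["n"]
        fit.flags["mechanism"] = (
            "fickian_diffusion" if n < 0.5 else "anomalous_transport" if n < 1.0 else "case_ii"
        )
    return fit


def compare_models(fits) -> list[FitResult]:
    """Rank fits of one dataset by R^2 (ties: fewer parameters win).

    Returns the list best-first; ``compare_models(fits)[0]`` is the winner.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    if len({len(f.residuals) for f in fits}) != 1:
        raise ValueError("fits compare different datasets (residual lengths differ)")
    return sorted(fits, key=lambda f: (-f.r2, f.n_params, f.model))


# ---------------------------------------------------------------------------
# loading arithmetic and UV-vis calibration


def loading_from_concentration(
    C0: float, C_eq: float, V: float, m: float, allow_negative: bool = False
) -> float:
    """Uptake Q = (C0 - C_eq) V / m in mg/g (C in ppm = mg/L, V in L, m in g).

    Negative Q (a release experiment read through the same arithmetic) is
    only allowed when ``allow_negative`` is set.
    """
    if V <= 0 or m <= 0:
        raise ValueError("V and m must be positive")
    Q = (C0 - C_eq) * V / m
    if Q < 0 and not allow_negative:
        raise ValueError(
            f"C_eq={C_eq} exceeds C0={C0} (negative loading); pass "
            "allow_negative=True for release-context arithmetic"
        )
    return Q


def concentration_from_absorbance(
    A: float, cal: CalibrationLine, dilution: float = 1.0, A_max: float | None = None
) -> float:
    """Concentration (ppm) from absorbance through a calibration line,
    multiplied by the sample dilution factor (10 for TC, 100 for ibuprofen
    in the reference protocol).  Warns when extrapolating above ``A_max``.
    """
    if cal.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    if A_max is not None and A > A_max:
        warnings.warn(
            f"absorbance {A} above calibrated range (max {A_max}); extrapolating",
            stacklevel=2,
        )
    return (A - cal.intercept) / cal.slope * dilution
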