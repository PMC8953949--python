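"""Saturation-binding analysis for ligand-receptor ELISA curves.

The model is one-site specific binding, optionally with a Hill slope:

    A(L) = Amax * L^h / (Kd^h + L^h)

where A is the absorbance of the oxidized substrate (proportional to bound
ligand), L the molar ligand concentration in nM, Amax the absorbance at
saturation, Kd the equilibrium dissociation constant, and h the Hill
coefficient (h = 1 recovers A = Amax / (1 + Kd/L)).  Fitting is unweighted
nonlinear least squares; Scatchard transforms and a percent-inhibition
summary for competition assays are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .errors import DomainError


def model_one_site(L, Amax: float, Kd: float, h: float = 1.0):
    """One-site specific binding with Hill slope; h=1 is simple binding."""
    if Amax <= 0 or Kd <= 0 or h <= 0:
        raise DomainError("Amax, Kd and h must be positive")
    L = np.asarray(L, dtype=float)
    if (L <= 0).any():
        raise DomainError("ligand concentrations must be positive")
    Lh = L ** h
    return Amax * Lh / (Kd ** h + Lh)


@dataclass
class BindingCurve:
    """Paired (concentration nM, absorbance OD) observations."""

    L: np.ndarray
    A: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.L.shape != self.A.shape or self.L.ndim != 1:
            raise DomainError("L and A must be matching 1-D arrays")
        if (self.L <= 0).any():
            raise DomainError("concentrations must be strictly positive")


@dataclass
class FitResult:
    Amax: float
    Kd: float
    h: float
    se_Amax: float
    se_Kd: float
    se_h: float | None
    rss: float
    converged: bool

    def as_dict(self) -> dict:
        return {
            "Amax": self.Amax,
            "Kd_nM": self.Kd,
            "hill": self.h,
            "se_Amax": self.se_Amax,
            "se_Kd_nM": self.se_Kd,
            "se_hill": self.se_h,
            "rss": self.rss,
            "converged": self.converged,
        }


class SaturationBindingModel(BaseEstimator):
    """Nonlinear least-squares estimator for the one-site binding model.

    Parameters
    ----------
    hill : bool
        When True the Hill coefficient h is fitted; otherwise it is fixed
        at 1 (the plain one-site model).

    Fitted attributes: ``Amax_``, ``Kd_`` (nM), ``h_``, ``se_``
    (standard errors from the Jacobian), ``rss_``, ``converged_``.
    """

    def __init__(self, hill: bool = False):
        self.hill = hill

    def fit(self, L, A=None):
        if isinstance(L, BindingCurve):
            curve = L
        else:
            curve = BindingCurve(np.ravel(L), np.asarray(A, dtype=float))
        L_, A_ = curve.L, curve.A
        if len(np.unique(L_)) < 4:
            raise DomainError("fitting needs at least 4 distinct concentrations")
        amax0 = float(A_.max())
        if amax0 <= 0:
            amax0 = 1e-6
        kd0 = float(L_[np.argmin(np.abs(A_ - amax0 / 2.0))])
        p0 = [amax0, kd0] + ([1.0] if self.hill else [])

        def residuals(p):
            h = p[2] if self.hill else 1.0
            Lh = L_ ** h
            return p[0] * Lh / (p[1] ** h + Lh) - A_

        sol = least_squares(
            residuals,
            p0,
            bounds=(1e-12, np.inf),
            xtol=1e-10,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=10000,
        )
        p = sol.x
        rss = float(2.0 * sol.cost)
        n, k = len(L_), len(p)
        # standard errors from the Gauss-Newton covariance J^T J
        se = np.full(k, np.nan)
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (rss / max(n - k, 1))
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            pass
        self.Amax_ = float(p[0])
        self.Kd_ = float(p[1])
        self.h_ = float(p[2]) if self.hill else 1.0
        self.se_ = {
            "Amax": float(se[0]),
            "Kd": float(se[1]),
            "h": float(se[2]) if self.hill else None,
        }
        self.rss_ = rss
        self.converged_ = bool(sol.success)
        return self

    def predict(self, L):
        return model_one_site(np.ravel(L), self.Amax_, self.Kd_, self.h_)

    def result(self) -> FitResult:
        return FitResult(
            Amax=self.Amax_,
            Kd=self.Kd_,
            h=self.h_,
            se_Amax=self.se_["Amax"],
            se_Kd=self.se_["Kd"],
            se_h=self.se_["h"],
            rss=self.rss_,
            converged=self.converged_,
        )


def fit_binding(curve: BindingCurve, hill: bool = False) -> FitResult:
    """Fit a saturation curve; non-convergence is flagged, not raised."""
    return SaturationBindingModel(hill=hill).fit(curve).result()


@dataclass
class ScatchardResult:
    bound: np.ndarray  # A
    bound_over_free: np.ndarray  # A / L
    slope: float  # -1/Kd for ideal one-site data
    intercept: float
    x_intercept: float  # Amax for ideal data


def scatchard(curve: BindingCurve) -> ScatchardResult:
    """Scatchard transform: (A, A/L) points and their least-squares line."""
    x = curve.A
    y = curve.A / curve.L
    slope, intercept = np.polyfit(x, y, 1)
    x_int = -intercept / slope if slope != 0 else np.nan
    return ScatchardResult(
        bound=x, bound_over_free=y, slope=float(slope),
        intercept=float(intercept), x_intercept=float(x_int),
    )


def percent_inhibition(od_with_competitor: float, od_alone: float) -> float:
    """Competition summary: 100 * (1 - OD_with / OD_alone), capped at 100."""
    if od_alone <= 0:
        raise DomainError("od_alone must be positive")
    return min(100.0, 100.0 * (1.0 - od_with_competitor / od_alone))


def ug_ml_to_nM(conc_ug_ml, mw_kda: float):
    """Convert a protein mass concentration to molarity in nM."""
    if mw_kda <= 0:
        raise DomainError("molecular weight must be positive")
    return np.asarray(conc_ug_ml, dtype=float) / mw_kda * 1000.0


def read_binding_tsv(path: str | Path) -> BindingCurve:
    """Read a curve from TSV: columns ``conc_nM``+``od``, or
    ``conc_ug_ml``+``mw_kda``+``od``."""
    df = pd.read_csv(path, sep="\t")
    if "conc_nM" in df.columns:
        L = df["conc_nM"].to_numpy(dtype=float)
    elif {"conc_ug_ml", "mw_kda"} <= set(df.columns):
        L = ug_ml_to_nM(df["conc_ug_ml"].to_numpy(dtype=float), float(df["mw_kda"].iloc[0]))
    else:
        raise DomainError("TSV needs conc_nM or conc_ug_ml + mw_kda columns")
    if "od" not in df.columns:
        raise DomainError("TSV needs an od column")
    return BindingCurve(L=L, A=df["od"].to_numpy(dtype=float))


def plot_binding(curve: BindingCurve, fit: FitResult, path: str | Path) -> None:
    """Curve + fitted model with a Scatchard inset, written as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogx(curve.L, curve.A, "o", label="data")
    grid = np.geomspace(curve.L.min(), curve.L.max(), 200)
    ax.semilogx(grid, model_one_site(grid, fit.Amax, fit.Kd, fit.h), "-",
                label=f"fit: Kd = {fit.Kd:.3g} nM")
    ax.set_xlabel("ligand (nM)")
    ax.set_ylabel("absorbance (OD)")
    ax.legend(loc="lower right", fontsize=8)
    sc = scatchard(curve)
    inset = fig.add_axes([0.22, 0.55, 0.28, 0.28])
    inset.plot(sc.bound, sc.bound_over_free, "o", ms=3)
    xs = np.linspace(0, sc.bound.max() * 1.05, 50)
    inset.plot(xs, sc.intercept + sc.slope * xs, "-", lw=1)
    inset.set_xlabel("bound", fontsize=7)
    inset.set_ylabel("bound/free", fontsize=7)
    inset.tick_params(labelsize=6)
    fig.savefig(path, dpi=120)
    plt.close(fig)
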