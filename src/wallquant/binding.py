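"""One-site saturation radioligand binding: model, background handling, fitting.

The specific signal follows the single-site hyperbola
``B(L) = Bmax * L / (Kd + L)`` on total ligand (free ~ total, the standard
assumption when ligand is in excess of the protein-bound fraction), plus an
optional linear nonspecific term. Nonspecific/background binding measured
in a protein-free assay is subtracted point-wise by default. A
depletion-corrected variant (quadratic solution for the complex when
protein and ligand amounts are comparable) is available behind a flag.

Kd and Bmax are estimated by nonlinear least squares; parameter standard
errors come from the Jacobian at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import List, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin


def one_site(L, kd: float, bmax: float, background_slope: float = 0.0):
    """Specific one-site binding plus linear nonspecific term.

    ``bmax * L / (kd + L) + background_slope * L``; L may be scalar or array.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if bmax < 0 or background_slope < 0:
        raise ValueError("bmax and background_slope must be >= 0")
    L = np.asarray(L, dtype=float)
    out = bmax * L / (kd + L) + background_slope * L
    return out if out.ndim else float(out)


def one_site_depletion(L, kd: float, bmax: float, protein_total: float):
    """Depletion-corrected one-site binding (free ligand solved exactly).

    With total protein P and total ligand L in the same concentration
    units, the complex C solves C^2 - C(P + L + Kd) + P*L = 0; the bound
    signal is Bmax * C / P. Use when ligand and protein amounts are
    comparable so free ~ total does not hold.
    """
    if kd <= 0 or protein_total <= 0:
        raise ValueError("kd and protein_total must be positive")
    L = np.asarray(L, dtype=float)
    s = protein_total + L + kd
    c = (s - np.sqrt(s**2 - 4.0 * protein_total * L)) / 2.0
    out = bmax * c / protein_total
    return out if out.ndim else float(out)


@dataclass
class BindingCurve:
    """Ligand-vs-bound measurements, optionally with a matched background series.

    Ligand values must be strictly positive; points are sorted ascending in
    ligand on construction (the matched series are reordered with them).
    """

    ligand: np.ndarray
    bound: np.ndarray
    background: np.ndarray | None = None
    unit: str = "uM"

    def __post_init__(self):
        self.ligand = np.asarray(self.ligand, dtype=float)
        self.bound = np.asarray(self.bound, dtype=float)
        if self.ligand.ndim != 1 or self.ligand.size == 0:
            raise ValueError("ligand must be a non-empty 1-D sequence")
        if np.any(self.ligand <= 0):
            raise ValueError("ligand values must be strictly positive")
        if self.bound.shape != self.ligand.shape:
            raise ValueError("bound must match ligand point-for-point")
        if not np.all(np.isfinite(self.bound)):
            raise ValueError("bound values must be finite")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != self.ligand.shape:
                raise ValueError("background series must match the ligand grid")
        order = np.argsort(self.ligand, kind="stable")
        self.ligand = self.ligand[order]
        self.bound = self.bound[order]
        if self.background is not None:
            self.background = self.background[order]

    @property
    def n_points(self) -> int:
        return int(self.ligand.size)


def subtract_background(
    curve: BindingCurve, background: BindingCurve | None = None
) -> BindingCurve:
    """Point-wise subtraction of the protein-free background series.

    Uses ``curve.background`` unless an explicit background curve (same
    ligand grid) is given. Negative differences are clipped to zero with a
    warning; the returned curve carries no background series.
    """
    if background is not None:
        if background.ligand.shape != curve.ligand.shape or not np.allclose(
            background.ligand, curve.ligand
        ):
            raise ValueError("background ligand grid does not match the curve")
        bg = background.bound
    elif curve.background is not None:
        bg = curve.background
    else:
        raise ValueError("no background series available to subtract")
    diff = curve.bound - bg
    if np.any(diff < 0):
        warnings.warn(
            f"background exceeded total binding at {int(np.sum(diff < 0))} "
            "point(s); clipped to 0",
            stacklevel=2,
        )
        diff = np.clip(diff, 0.0, None)
    return BindingCurve(ligand=curve.ligand, bound=diff, background=None, unit=curve.unit)


@dataclass
class BindingFit:
    """Fitted one-site parameters with uncertainties and diagnostics."""

    kd: float
    bmax: float
    background_slope: float
    kd_se: float
    bmax_se: float
    converged: bool
    rss: float
    n_points: int
    unit: str = "uM"
    warnings: List[str] = dc_field(default_factory=list)


class OneSiteBindingModel(RegressorMixin, BaseEstimator):
    """sklearn-style regressor for one-site saturation binding.

    fit(X, y) takes ligand concentrations (n,) or (n, 1) and bound signal;
    fitted attributes are ``kd_``, ``bmax_`` (and ``background_slope_``
    when ``fit_background=True``), with standard errors ``kd_se_`` /
    ``bmax_se_`` from the Jacobian, residual sum of squares ``rss_``, a
    ``converged_`` flag and accumulated ``warnings_``.

    Parameters
    ----------
    fit_background
        Co-fit a linear nonspecific slope instead of assuming the data are
        background-subtracted.
    depletion
        Use the depletion-corrected model (requires ``protein_total`` in
        the same concentration units as the ligand).
    start_kd, start_bmax
        Optional initial values; defaults are median(ligand) and max(bound).
    """

    def __init__(self, fit_background: bool = False, depletion: bool = False,
                 protein_total: float | None = None,
                 start_kd: float | None = None, start_bmax: float | None = None,
                 max_nfev: int = 10000):
        self.fit_background = fit_background
        self.depletion = depletion
        self.protein_total = protein_total
        self.start_kd = start_kd
        self.start_bmax = start_bmax
        self.max_nfev = max_nfev

    def _validate(self, X, y):
        L = np.asarray(X, dtype=float)
        if L.ndim == 2 and L.shape[1] == 1:
            L = L[:, 0]
        if L.ndim != 1:
            raise ValueError("ligand must be a 1-D sequence (or column vector)")
        y = np.asarray(y, dtype=float)
        if y.shape != L.shape:
            raise ValueError("bound must match ligand point-for-point")
        if np.unique(L).size < 3:
            raise ValueError("need at least 3 distinct ligand points to fit")
        if np.all(y <= 0):
            raise ValueError("bound signal is all zero (or negative); nothing to fit")
        if self.depletion and (self.protein_total is None or self.protein_total <= 0):
            raise ValueError("depletion mode requires a positive protein_total")
        return L, y

    def _model(self, L, *params):
        if self.depletion:
            core = one_site_depletion(L, params[0], params[1], self.protein_total)
        else:
            core = one_site(L, params[0], params[1])
        if self.fit_background:
            core = core + params[2] * np.asarray(L, dtype=float)
        return core

    def fit(self, X, y):
        L, y = self._validate(X, y)
        self.warnings_ = []
        kd0 = self.start_kd if self.start_kd is not None else float(np.median(L))
        bmax0 = self.start_bmax if self.start_bmax is not None else float(y.max())
        p0 = [kd0, bmax0] + ([0.0] if self.fit_background else [])
        lo = [1e-12, 1e-12] + ([0.0] if self.fit_background else [])
        hi = [np.inf] * len(p0)
        try:
            popt, pcov = curve_fit(
                self._model, L, y, p0=p0, bounds=(lo, hi), max_nfev=self.max_nfev
            )
        except RuntimeError as e:
            raise RuntimeError(f"one-site fit failed to converge: {e}") from e
        self.kd_ = float(popt[0])
        self.bmax_ = float(popt[1])
        self.background_slope_ = float(popt[2]) if self.fit_background else 0.0
        perr = np.sqrt(np.diag(pcov))
        self.kd_se_ = float(perr[0])
        self.bmax_se_ = float(perr[1])
        if not np.all(np.isfinite(perr[:2])):
            self.warnings_.append("singular Jacobian: parameter errors unreliable")
        resid = y - self._model(L, *popt)
        self.rss_ = float(np.sum(resid**2))
        self.converged_ = True
        if L.max() < self.kd_:
            self.warnings_.append(
                "weak-saturation: largest ligand concentration below fitted Kd"
            )
        return self

    def predict(self, X):
        L = np.asarray(X, dtype=float)
        if L.ndim == 2 and L.shape[1] == 1:
            L = L[:, 0]
        params = [self.kd_, self.bmax_]
        if self.fit_background:
            params.append(self.background_slope_)
        return self._model(L, *params)


def fit_binding(
    curve: BindingCurve,
    start: tuple[float, float] | None = None,
    fit_background: bool = False,
    depletion: bool = False,
    protein_total: float | None = None,
) -> BindingFit:
    """Fit the one-site model to a (background-subtracted) binding curve.

    If the curve carries a background series it is subtracted first. Raises
    on fewer than 3 distinct ligand points, an all-zero signal, or failure
    to converge; a fit whose largest ligand lies below the Kd estimate
    converges with a "weak-saturation" warning attached.
    """
    if curve.background is not None:
        curve = subtract_background(curve)
    model = OneSiteBindingModel(
        fit_background=fit_background,
        depletion=depletion,
        protein_total=protein_total,
        start_kd=start[0] if start else None,
        start_bmax=start[1] if start else None,
    )
    model.fit(curve.ligand, curve.bound)
    for w in model.warnings_:
        warnings.warn(w, stacklevel=2)
    return BindingFit(
        kd=model.kd_,
        bmax=model.bmax_,
        background_slope=model.background_slope_,
        kd_se=model.kd_se_,
        bmax_se=model.bmax_se_,
        converged=model.converged_,
        rss=model.rss_,
        n_points=curve.n_points,
        unit=curve.unit,
        warnings=list(model.warnings_),
    )
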