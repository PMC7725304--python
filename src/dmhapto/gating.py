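"""Boltzmann gating and pH dependence of the KDM1 K+ channel.

KDM1 is a hyperpolarization- and acid-activated inward-rectifying K+
channel (a KAT1 ortholog) expressed in the trigger hair's sensory cells.
Its voltage dependence follows a Boltzmann open probability

    po(V) = 1 / (1 + exp(a*F/RT * (V - V1/2)))

with apparent gating-charge factor ``a`` and half-activation voltage
``V1/2``.  External acidification shifts V1/2 positive according to a
combined Boltzmann / law-of-mass-action model with apparent pK values of
the open and closed channel state:

    V1/2(pH) = V1/2_inf - RT/(a*F) * ln[(10^pH + 10^pK_C) / (10^pH + 10^pK_O)]

For an acid-activated channel pK_O > pK_C, so protonation stabilizes the
open state and V1/2 approaches V1/2_inf at high pH.

This module provides the forward models, scikit-learn style least-squares
fitters with parameter recovery, and the standard two-electrode
voltage-clamp analyses: tail-current normalization to relative open
probabilities, per-cell I-V normalization, the Nernst slope of the reversal
potential, and the fractional block statistic for channel blockers
(Cs+, TEA+, Ba2+).

Voltages in mV throughout; currents in any consistent unit (inward
currents negative by convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import FitError

__all__ = [
    "BoltzmannParams",
    "PHModelParams",
    "open_probability",
    "v_half_at_ph",
    "BoltzmannCurveFit",
    "PHCurveFit",
    "fit_boltzmann",
    "fit_ph_model",
    "tail_to_open_probability",
    "nernst_shift_per_decade",
    "fractional_block",
    "normalize_currents",
    "WT_PH_PARAMS",
    "H147S_PH_PARAMS",
]


@dataclass(frozen=True)
class BoltzmannParams:
    """Boltzmann gating-curve parameters."""

    a: float
    v_half: float
    rt_over_f: float = 25.2

    def __post_init__(self) -> None:
        if self.rt_over_f <= 0:
            raise ValueError("rt_over_f must be > 0")


@dataclass(frozen=True)
class PHModelParams:
    """Parameters of the pH-dependent V1/2 model."""

    v_half_inf: float
    pk_o: float
    pk_c: float
    a: float = 0.6
    rt_over_f: float = 25.2

    def __post_init__(self) -> None:
        if self.a <= 0 or self.rt_over_f <= 0:
            raise ValueError("a and rt_over_f must be > 0")

    @property
    def vs(self) -> float:
        """Voltage-sensitivity scale RT/(a*F) in mV (42 mV for KDM1)."""
        return self.rt_over_f / self.a

    @property
    def acid_activated(self) -> bool:
        return self.pk_o > self.pk_c


# Fitted parameters for wild-type KDM1 and the pH-sensor mutant H147S
# (a = 0.6, RT/F = 25.2 mV, hence Vs = 42 mV in both).
WT_PH_PARAMS = PHModelParams(v_half_inf=-177.048, pk_o=5.1328, pk_c=4.04)
H147S_PH_PARAMS = PHModelParams(v_half_inf=-153.632, pk_o=4.6285, pk_c=4.1914)


def open_probability(v, p: BoltzmannParams):
    """Boltzmann open probability; strictly decreasing in V.

    Accepts a scalar or array of voltages (mV).
    """
    v = np.asarray(v, dtype=float)
    z = (p.a / p.rt_over_f) * (v - p.v_half)
    out = 1.0 / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def v_half_at_ph(ph, p: PHModelParams):
    """Half-activation voltage (mV) at the given external pH.

    With the wild-type parameters this evaluates to -95.6 mV at pH 4 and
    -177.0 mV at pH 7, matching the measured values (-95.7 and -176.1 mV)
    within a millivolt.
    """
    ph = np.asarray(ph, dtype=float)
    ratio = (10.0 ** ph + 10.0 ** p.pk_c) / (10.0 ** ph + 10.0 ** p.pk_o)
    out = p.v_half_inf - p.vs * np.log(ratio)
    return float(out) if out.ndim == 0 else out


class BoltzmannCurveFit(BaseEstimator, RegressorMixin):
    """Least-squares fit of a Boltzmann activation curve.

    Parameters
    ----------
    fixed_a : float or None
        If given, only V1/2 is fitted and ``a`` is held at this value.
    rt_over_f : float
        Thermal voltage (mV).
    n_starts : int
        Multi-start count for the nonlinear optimizer; starts are spread
        around the data-driven initial guess (V1/2 at the voltage whose
        relative open probability is nearest 0.5).

    Attributes (after ``fit``)
    --------------------------
    a_, v_half_ : float
        Estimates; ``a_ < 0`` indicates a monotone-increasing curve,
        inconsistent with hyperpolarization activation (see
        ``hyperpolarization_activated_``).
    stderr_a_, stderr_v_half_ : float
        Approximate standard errors from the Jacobian at the optimum.
    residual_norm_ : float
        Euclidean norm of the residuals.
    """

    def __init__(self, fixed_a: float | None = None, rt_over_f: float = 25.2,
                 n_starts: int = 5):
        self.fixed_a = fixed_a
        self.rt_over_f = rt_over_f
        self.n_starts = n_starts

    def _model(self, v, a, v_half):
        return 1.0 / (1.0 + np.exp((a / self.rt_over_f) * (v - v_half)))

    def fit(self, X, y):
        """Fit to voltages ``X`` (mV, shape (n,) or (n, 1)) and relative
        open probabilities ``y``."""
        v = np.asarray(X, dtype=float).reshape(-1)
        po = np.asarray(y, dtype=float).reshape(-1)
        if v.size != po.size:
            raise ValueError("X and y must have the same length")
        if np.unique(v).size < 5:
            raise FitError("need >= 5 distinct voltages to fit a Boltzmann curve")
        if po.max() - po.min() < 0.2:
            raise FitError(
                "dynamic range of the activation curve < 0.2; curve too flat to fit"
            )

        v_half0 = v[np.argmin(np.abs(po - 0.5))]
        spread = max(np.ptp(v) / 4.0, 10.0)
        offsets = np.linspace(-spread, spread, self.n_starts)
        best = None
        for off in offsets:
            if self.fixed_a is None:
                x0 = np.array([1.0, v_half0 + off])
                fun = lambda q: self._model(v, q[0], q[1]) - po
            else:
                x0 = np.array([v_half0 + off])
                fun = lambda q: self._model(v, self.fixed_a, q[0]) - po
            try:
                res = optimize.least_squares(fun, x0, method="lm", max_nfev=2000)
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitError("Boltzmann fit did not converge from any start")

        if self.fixed_a is None:
            self.a_, self.v_half_ = map(float, best.x)
        else:
            self.a_ = float(self.fixed_a)
            self.v_half_ = float(best.x[0])
        self.residual_norm_ = float(np.linalg.norm(best.fun))
        self._set_stderr(best, v.size)
        self.hyperpolarization_activated_ = bool(self.a_ > 0)
        return self

    def _set_stderr(self, res, n):
        k = res.x.size
        dof = max(n - k, 1)
        s2 = 2.0 * res.cost / dof
        jtj = res.jac.T @ res.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
        if self.fixed_a is None:
            self.stderr_a_, self.stderr_v_half_ = map(float, se)
        else:
            self.stderr_a_ = 0.0
            self.stderr_v_half_ = float(se[0])

    def predict(self, X):
        check_is_fitted(self, "v_half_")
        v = np.asarray(X, dtype=float).reshape(-1)
        return self._model(v, self.a_, self.v_half_)

    @property
    def params_(self) -> BoltzmannParams:
        check_is_fitted(self, "v_half_")
        return BoltzmannParams(self.a_, self.v_half_, self.rt_over_f)


class PHCurveFit(BaseEstimator, RegressorMixin):
    """Least-squares fit of the pH-dependent V1/2 model.

    ``a`` and ``rt_over_f`` are held fixed (as in the published analysis);
    (V1/2_inf, pK_O, pK_C) are estimated from >= 4 (pH, V1/2) points.
    Multi-start initialisation places the pK guesses at the data pH
    extremes to guard against the pK_O/pK_C exchange degeneracy.

    Attributes: ``v_half_inf_``, ``pk_o_``, ``pk_c_``, ``residual_norm_``,
    ``acid_activated_`` (pK_O > pK_C), ``degenerate_`` (|pK_O - pK_C|
    below 1e-3, a practically unidentifiable fit).
    """

    def __init__(self, a: float = 0.6, rt_over_f: float = 25.2, n_starts: int = 5):
        self.a = a
        self.rt_over_f = rt_over_f
        self.n_starts = n_starts

    def _model(self, ph, v_inf, pk_o, pk_c):
        vs = self.rt_over_f / self.a
        ratio = (10.0 ** ph + 10.0 ** pk_c) / (10.0 ** ph + 10.0 ** pk_o)
        return v_inf - vs * np.log(ratio)

    def fit(self, X, y):
        ph = np.asarray(X, dtype=float).reshape(-1)
        vh = np.asarray(y, dtype=float).reshape(-1)
        if ph.size != vh.size:
            raise ValueError("X and y must have the same length")
        if np.unique(ph).size < 4:
            raise FitError("need >= 4 distinct pH points (3 parameters + 1)")

        lo, hi = ph.min(), ph.max()
        mids = np.linspace(lo, hi, self.n_starts)
        best = None
        for mid in mids:
            x0 = np.array([vh.min(), hi if mid == lo else mid, lo])
            fun = lambda q: self._model(ph, *q) - vh
            try:
                res = optimize.least_squares(fun, x0, method="lm", max_nfev=5000)
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitError("pH-model fit did not converge from any start")

        self.v_half_inf_, self.pk_o_, self.pk_c_ = map(float, best.x)
        self.residual_norm_ = float(np.linalg.norm(best.fun))
        self.acid_activated_ = bool(self.pk_o_ > self.pk_c_)
        self.degenerate_ = bool(abs(self.pk_o_ - self.pk_c_) < 1e-3)
        return self

    def predict(self, X):
        check_is_fitted(self, "pk_o_")
        return self._model(np.asarray(X, dtype=float).reshape(-1),
                           self.v_half_inf_, self.pk_o_, self.pk_c_)

    @property
    def params_(self) -> PHModelParams:
        check_is_fitted(self, "pk_o_")
        return PHModelParams(self.v_half_inf_, self.pk_o_, self.pk_c_,
                             self.a, self.rt_over_f)


def fit_boltzmann(voltages, rel_po, fixed_a: float | None = None,
                  rt_over_f: float = 25.2) -> BoltzmannCurveFit:
    """Thin functional wrapper over :class:`BoltzmannCurveFit`."""
    return BoltzmannCurveFit(fixed_a=fixed_a, rt_over_f=rt_over_f).fit(voltages, rel_po)


def fit_ph_model(ph, v_half, a: float = 0.6, rt_over_f: float = 25.2) -> PHCurveFit:
    """Thin functional wrapper over :class:`PHCurveFit`."""
    return PHCurveFit(a=a, rt_over_f=rt_over_f).fit(ph, v_half)


def tail_to_open_probability(voltages, tail_currents) -> pd.DataFrame:
    """Convert tail currents (measured after a fixed post-pulse) to a
    relative open-probability curve.

    rel_po(V) = I_tail(V) / max|I_tail|, with the shared sign handled so
    that rel_po lies in [0, 1] and the saturating voltage maps to 1.
    Values slightly above 1 due to noise are retained (clipping would bias
    a subsequent V1/2 fit).
    """
    v = np.asarray(voltages, dtype=float).reshape(-1)
    tails = np.asarray(tail_currents, dtype=float).reshape(-1)
    if v.size != tails.size:
        raise ValueError("voltages and tail_currents must have the same length")
    if v.size < 3:
        raise ValueError("need >= 3 test voltages")
    nz = tails[tails != 0]
    if nz.size == 0:
        raise ValueError("all tail currents are zero")
    if not (np.all(nz <= 0) or np.all(nz >= 0)):
        raise ValueError("tail currents must share one sign")
    scale = np.max(np.abs(tails))
    rel = np.abs(tails) / scale
    return pd.DataFrame({"V_mV": v, "rel_po": rel})


def nernst_shift_per_decade(reversal_potentials, external_k) -> dict[str, float]:
    """Slope of the reversal potential vs log10 of external [K+].

    An ideally K+-selective channel shifts by RT/F*ln(10) ~ 58 mV per
    10-fold change in external K+.  Returns the regression slope (mV per
    decade) with its standard error and intercept.
    """
    e_rev = np.asarray(reversal_potentials, dtype=float).reshape(-1)
    k_ext = np.asarray(external_k, dtype=float).reshape(-1)
    if np.any(k_ext <= 0):
        raise ValueError("external K+ concentrations must be > 0")
    if np.unique(k_ext).size < 2:
        raise ValueError("need >= 2 distinct external K+ concentrations")
    res = stats.linregress(np.log10(k_ext), e_rev)
    return {
        "slope_mv_per_decade": float(res.slope),
        "stderr": float(res.stderr),
        "intercept_mv": float(res.intercept),
    }


def fractional_block(i_control: float, i_blocked: float) -> dict[str, float | bool]:
    """Fractional current block 1 - I_blocked/I_control at a fixed voltage.

    For KDM1 at -150 mV, 30 mM Cs+ blocks ~90% of the current while TEA+
    and Ba2+ block ~60%.  The raw ratio is clipped to [0, 1]; an
    out-of-range raw value (sign change or potentiation) is flagged.
    """
    if i_control == 0:
        raise ValueError("control current must be non-zero")
    if i_control * i_blocked < 0:
        raise ValueError("control and blocked currents must share sign convention")
    raw = 1.0 - i_blocked / i_control
    return {
        "fraction": float(min(max(raw, 0.0), 1.0)),
        "raw": float(raw),
        "in_range": bool(0.0 <= raw <= 1.0),
    }


def normalize_currents(
    data: pd.DataFrame,
    reference_condition: str,
    reference_voltage: float,
) -> pd.DataFrame:
    """Per-cell normalization of an I-V dataset, then across-cell averaging.

    ``data`` must have columns ``cell_id``, ``condition``, ``V_mV``, ``I``.
    Every cell's currents are divided by |I| at the reference
    (condition, voltage), preserving sign, so the reference mean has
    magnitude 1; normalized values are then averaged across cells per
    (condition, voltage) with the standard deviation as spread.
    """
    required = {"cell_id", "condition", "V_mV", "I"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = data.copy()
    ref = out[(out["condition"] == reference_condition)
              & (np.isclose(out["V_mV"], reference_voltage))]
    ref_by_cell = ref.groupby("cell_id")["I"].mean()
    cells = out["cell_id"].unique()
    absent = np.asarray(sorted(set(cells) - set(ref_by_cell.index))).tolist()
    if absent:
        raise ValueError(
            f"cells missing the reference measurement "
            f"({reference_condition!r} at {reference_voltage} mV): {absent}"
        )
    if (ref_by_cell == 0).any():
        zero = sorted(ref_by_cell[ref_by_cell == 0].index)
        raise ValueError(f"zero reference current for cells: {zero}")
    out["I_norm"] = out["I"] / out["cell_id"].map(ref_by_cell.abs())
    mean = (
        out.groupby(["condition", "V_mV"], as_index=False)["I_norm"]
        .agg(I_norm_mean="mean", I_norm_sd="std", n_cells="count")
    )
    return mean
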