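"""On-cell-western quantification and one-site saturation binding fits.

Each plate well carries two detection wavelengths: the 784-nm signal
reports the covalently attached label and the 658-nm signal the total
receptor present, so the 784/658 ratio normalizes labeling to receptor
amount.  Background (no-primary-antibody) wells are averaged per
wavelength and subtracted before the ratio is formed.  Wells co-incubated
with an excess competitive blocker (e.g. 10 µM naloxone) measure
nonspecific labeling.

The saturation model is the standard one-site form with a linear
nonspecific component::

    total(L) = Bmax * L / (Kd + L) + ns * L

where L is the labeling concentration (nM), Bmax the saturating specific
ratio, and ns the nonspecific slope (ratio units per nM) estimated from
the blocked wells.  Because the fluorophore attaches covalently, the
fitted "Kd" is an apparent labeling coefficient (half-maximal labeling
concentration under the fixed incubation protocol), not an equilibrium
dissociation constant; the customary symbol is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from receptorquant.errors import FitError

__all__ = [
    "BindingPlate",
    "BindingFit",
    "OneSiteBindingModel",
    "normalize_wells",
    "fit_one_site",
]

WELL_COLUMNS = (
    "concentration_nM",
    "signal_784",
    "signal_658",
    "blocked",
    "no_primary",
    "replicate_id",
)


@dataclass
class BindingPlate:
    """Per-well two-wavelength intensities with condition labels.

    ``wells`` is a DataFrame with columns ``concentration_nM``,
    ``signal_784``, ``signal_658``, ``blocked`` (competitive blocker
    co-incubation), ``no_primary`` (background well) and ``replicate_id``.
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(WELL_COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate missing columns: {sorted(missing)}")
        w = self.wells
        if (w["concentration_nM"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        if not w["no_primary"].any():
            raise ValueError("plate needs at least one background (no_primary) well")
        assay = w[~w["no_primary"]]
        conc = set(assay.loc[~assay["blocked"], "concentration_nM"])
        blocked_conc = set(assay.loc[assay["blocked"], "concentration_nM"])
        if not conc or conc != blocked_conc:
            raise ValueError(
                "each concentration must be present in blocked and unblocked wells"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "BindingPlate":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.wells.to_csv(path, index=False)


@dataclass
class BindingFit:
    """One-site fit result.

    ``specific`` holds the per-concentration fitted specific curve
    (total − nonspecific) alongside the observed mean normalized ratios.
    """

    kd_nM: float
    bmax: float
    ns_slope: float
    covariance: np.ndarray
    specific: pd.DataFrame
    shared: bool = False
    warnings_: list[str] = field(default_factory=list)


def normalize_wells(plate: BindingPlate) -> pd.DataFrame:
    """Background-subtract and form the per-well 784/658 ratio.

    Background per wavelength is the mean over the no-primary wells.  Wells
    whose 658-nm denominator is non-positive after subtraction are flagged
    (``excluded=True``) with a NaN ratio rather than dropped, so the caller
    can audit them.
    """
    w = plate.wells
    bg = w[w["no_primary"]]
    bg784 = float(bg["signal_784"].mean())
    bg658 = float(bg["signal_658"].mean())
    out = w[~w["no_primary"]].copy()
    num = out["signal_784"] - bg784
    den = out["signal_658"] - bg658
    out["excluded"] = den <= 0
    out["ratio"] = np.where(out["excluded"], np.nan, num / den.where(den > 0))
    out.attrs["background_784"] = bg784
    out.attrs["background_658"] = bg658
    return out


def _one_site_total(L: np.ndarray, bmax: float, kd: float, ns: float) -> np.ndarray:
    return bmax * L / (kd + L) + ns * L


def _linearized_start(
    L: np.ndarray, y_specific: np.ndarray
) -> tuple[float, float] | None:
    """Exact (Bmax, Kd) for noise-free specific data via the linearization

    ``y (Kd + L) = Bmax L``  ⇔  ``y Kd − L Bmax = −y L``,

    solved in least squares.  Returns None for degenerate designs.
    """
    mask = L > 0
    A = np.column_stack([y_specific[mask], -L[mask]])
    b = -y_specific[mask] * L[mask]
    try:
        (kd, bmax), *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if not (np.isfinite(kd) and np.isfinite(bmax)) or kd <= 0 or bmax <= 0:
        return None
    return float(bmax), float(kd)


class OneSiteBindingModel(BaseEstimator, RegressorMixin):
    """One-site saturation binding regressor with linear nonspecific term.

    Parameters
    ----------
    shared : bool, default False
        If False (sequential fit), the nonspecific slope is estimated first
        from the blocked wells by through-origin least squares and held
        fixed while (Bmax, Kd) are fit to the total curve.  If True, all
        three parameters are fit simultaneously to the stacked
        total-and-blocked data.
    kd_warn_factor : float, default 10.0
        Warn when the fitted Kd exceeds this multiple of the largest tested
        concentration (the design cannot support the estimate).

    Attributes
    ----------
    kd_nM_ : float
        Apparent half-maximal labeling concentration.
    bmax_ : float
        Saturating specific ratio.
    ns_slope_ : float
        Nonspecific slope, ratio units per nM.
    covariance_ : ndarray
        Covariance of the fitted parameters (order: Bmax, Kd[, ns]).
    result_ : BindingFit
        Full fit report.
    """

    def __init__(self, shared: bool = False, kd_warn_factor: float = 10.0):
        self.shared = shared
        self.kd_warn_factor = kd_warn_factor

    def fit(
        self,
        concentrations: np.ndarray,
        total_ratios: np.ndarray,
        blocked_ratios: np.ndarray | None = None,
        blocked_concentrations: np.ndarray | None = None,
    ) -> "OneSiteBindingModel":
        """Fit the saturation model.

        Parameters
        ----------
        concentrations, total_ratios : array-like
            Unblocked (total labeling) wells; replicates as repeated rows.
        blocked_ratios : array-like
            Blocked (nonspecific) wells.  ``blocked_concentrations``
            defaults to ``concentrations`` when shapes agree.
        """
        L = np.asarray(concentrations, dtype=np.float64)
        y = np.asarray(total_ratios, dtype=np.float64)
        if blocked_ratios is None:
            raise ValueError("blocked_ratios required to separate nonspecific binding")
        yb = np.asarray(blocked_ratios, dtype=np.float64)
        Lb = (
            np.asarray(blocked_concentrations, dtype=np.float64)
            if blocked_concentrations is not None
            else L[: yb.size]
            if yb.size != L.size
            else L
        )
        keep = np.isfinite(y) & np.isfinite(L)
        L, y = L[keep], y[keep]
        keep_b = np.isfinite(yb) & np.isfinite(Lb)
        Lb, yb = Lb[keep_b], yb[keep_b]
        if np.unique(L[L > 0]).size < 4:
            raise ValueError("need at least 4 distinct nonzero concentrations")

        msgs: list[str] = []
        # nonspecific slope: through-origin least squares on blocked wells
        denom = float(np.sum(Lb * Lb))
        ns0 = float(np.sum(Lb * yb) / denom) if denom > 0 else 0.0

        start = _linearized_start(L, y - ns0 * L)
        if start is None:
            bmax0 = max(float(np.max(y - ns0 * L)), 1e-6)
            kd0 = float(np.median(L[L > 0]))
        else:
            bmax0, kd0 = start

        try:
            if self.shared:
                X = np.concatenate([L, Lb])
                Y = np.concatenate([y, yb])
                is_total = np.concatenate([np.ones(L.size), np.zeros(Lb.size)])

                def model(xdata, bmax, kd, ns):
                    x, tot = xdata
                    return tot * bmax * x / (kd + x) + ns * x

                popt, pcov = curve_fit(
                    model, (X, is_total), Y, p0=[bmax0, kd0, ns0], maxfev=20000
                )
                bmax, kd, ns = popt
            else:

                def model(x, bmax, kd):
                    return _one_site_total(x, bmax, kd, ns0)

                popt, pcov = curve_fit(model, L, y, p0=[bmax0, kd0], maxfev=20000)
                bmax, kd = popt
                ns = ns0
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"one-site fit did not converge: {exc}") from exc
        if not np.all(np.isfinite(popt)):
            raise FitError(f"one-site fit returned non-finite parameters {popt}")

        max_L = float(np.max(L))
        if not (0 < kd < self.kd_warn_factor * max_L):
            msg = (
                f"fitted Kd = {kd:.3g} nM outside (0, {self.kd_warn_factor:g} x "
                f"{max_L:g} nM); the design does not constrain it"
            )
            msgs.append(msg)
            warnings.warn(msg, stacklevel=2)

        uniq = np.unique(L)
        obs = np.array([y[L == c].mean() for c in uniq])
        specific = pd.DataFrame(
            {
                "concentration_nM": uniq,
                "observed_total": obs,
                "fitted_total": _one_site_total(uniq, bmax, kd, ns),
                "fitted_nonspecific": ns * uniq,
                "fitted_specific": bmax * uniq / (kd + uniq),
            }
        )
        self.kd_nM_ = float(kd)
        self.bmax_ = float(bmax)
        self.ns_slope_ = float(ns)
        self.covariance_ = pcov
        self.result_ = BindingFit(
            kd_nM=self.kd_nM_,
            bmax=self.bmax_,
            ns_slope=self.ns_slope_,
            covariance=pcov,
            specific=specific,
            shared=self.shared,
            warnings_=msgs,
        )
        return self

    def fit_plate(self, plate: BindingPlate) -> "OneSiteBindingModel":
        """Normalize a plate's wells and fit (convenience front end)."""
        ratios = normalize_wells(plate)
        ok = ~ratios["excluded"]
        total = ratios[ok & ~ratios["blocked"]]
        blocked = ratios[ok & ratios["blocked"]]
        return self.fit(
            total["concentration_nM"].to_numpy(),
            total["ratio"].to_numpy(),
            blocked["ratio"].to_numpy(),
            blocked["concentration_nM"].to_numpy(),
        )

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        """Fitted total ratio at the given concentrations."""
        check_is_fitted(self, "kd_nM_")
        L = np.asarray(concentrations, dtype=np.float64)
        return _one_site_total(L, self.bmax_, self.kd_nM_, self.ns_slope_)


def fit_one_site(
    concentrations: np.ndarray,
    total_ratios: np.ndarray,
    blocked_ratios: np.ndarray,
    blocked_concentrations: np.ndarray | None = None,
    shared: bool = False,
) -> BindingFit:
    """One-site saturation fit (thin wrapper over OneSiteBindingModel)."""
    model = OneSiteBindingModel(shared=shared).fit(
        concentrations, total_ratios, blocked_ratios, blocked_concentrations
    )
    return model.result_
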