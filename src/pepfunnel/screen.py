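"""Screening-stage analytics: single-site surrogates, chip normalization,
competitive-binding curve fitting.

``SingleSiteSurrogate`` explains a per-peptide response (e.g. a docking
energy) with an additive one-hot model fitted by LASSO; its coefficient
matrix is the equivalent of a weight logo. ``normalize_chip`` removes the
spatially varying fluorescence baseline of a peptide-microarray scan with a
robust second-order polynomial in (row, col) and returns per-peptide
Z-scores, excluding border spots (elevated by over-splash from the border
markers) from hit calling. ``fit_ic50`` fits the single-site competitive
inhibition model f([I]) = f_min + (f_max - f_min) / (1 + [I]/IC50) to
fluorescence-polarization readings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.utils.validation import check_is_fitted

from .alphabet import Q, encode_many

__all__ = [
    "SingleSiteSurrogate",
    "fit_single_site_surrogate",
    "normalize_chip",
    "IC50Fit",
    "fit_ic50",
    "bound_fraction",
]


class SingleSiteSurrogate(BaseEstimator, RegressorMixin):
    """Additive one-hot LASSO model of a per-sequence response.

    Parameters
    ----------
    alphas : array-like or None
        L1 penalty grid; chosen by ``cv``-fold cross-validation. None uses a
        log grid from 1e-4 to 1.
    """

    def __init__(self, alphas=None, cv: int = 5, random_state: int | None = None):
        self.alphas = alphas
        self.cv = cv
        self.random_state = random_state

    @staticmethod
    def _design(sequences) -> np.ndarray:
        codes = encode_many(list(sequences))
        n, N = codes.shape
        X = np.zeros((n, N * Q))
        X[np.repeat(np.arange(n), N), (np.arange(N) * Q + codes).ravel()] = 1.0
        return X

    def fit(self, sequences, y):
        y = np.asarray(y, dtype=float)
        if np.std(y) == 0:
            raise ValueError("constant response: degenerate fit")
        X = self._design(sequences)
        alphas = self.alphas if self.alphas is not None else np.logspace(-4, 0, 9)
        splitter = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        best_alpha, best_r = None, -np.inf
        for alpha in alphas:
            pred = cross_val_predict(Lasso(alpha=alpha, max_iter=5000), X, y, cv=splitter)
            r = pearsonr(y, pred)[0] if np.std(pred) > 0 else 0.0
            if r > best_r:
                best_alpha, best_r = float(alpha), float(r)
        model = Lasso(alpha=best_alpha, max_iter=5000).fit(X, y)
        self.alpha_ = best_alpha
        self.cv_pearson_r_ = best_r
        self.intercept_ = float(model.intercept_)
        self.coef_matrix_ = model.coef_.reshape(-1, Q)
        self.n_columns_ = self.coef_matrix_.shape[0]
        return self

    def predict(self, sequences) -> np.ndarray:
        check_is_fitted(self, "coef_matrix_")
        return self._design(sequences) @ self.coef_matrix_.ravel() + self.intercept_

    def permutation_pvalue(self, sequences, y, n_permutations: int = 200, seed: int = 0) -> float:
        """Permutation p-value for the cross-validated correlation."""
        rng = np.random.default_rng(seed)
        y = np.asarray(y, dtype=float)
        observed = self.cv_pearson_r_
        X = self._design(sequences)
        splitter = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        null = []
        for _ in range(n_permutations):
            perm = rng.permutation(y)
            pred = cross_val_predict(Lasso(alpha=self.alpha_, max_iter=5000), X, perm, cv=splitter)
            null.append(pearsonr(perm, pred)[0] if np.std(pred) > 0 else 0.0)
        return float((1 + np.sum(np.asarray(null) >= observed)) / (1 + n_permutations))


def fit_single_site_surrogate(sequences, responses, alphas=None, cv_folds: int = 5, seed=None):
    return SingleSiteSurrogate(alphas=alphas, cv=cv_folds, random_state=seed).fit(
        sequences, responses
    )


def _quadratic_design(row: np.ndarray, col: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(row, dtype=float), row, col, row**2, col**2, row * col]
    )


def normalize_chip(scan: pd.DataFrame, warn_autocorr: float = 0.2) -> pd.DataFrame:
    """Spatially detrend a chip scan and return per-peptide Z-scores.

    ``scan`` columns: repeat, row, col, peptide_id, roi, fluorescence,
    border. Per repeat the log of each ROI's fluorescence is fitted on
    non-border spots with a robust (Huber-weighted) full second-order
    polynomial in (row, col); residuals are averaged over the two ROIs per
    peptide and Z-normalized over non-border peptides, then averaged across
    repeats. Border peptides keep a Z-score but are flagged and must not be
    hit-called.
    """
    required = {"repeat", "row", "col", "peptide_id", "roi", "fluorescence", "border"}
    missing = required - set(scan.columns)
    if missing:
        raise ValueError(f"scan table is missing columns: {sorted(missing)}")
    if scan["border"].all():
        raise ValueError("all spots on the border: baseline fit impossible")
    per_repeat = []
    for rep, sub in scan.groupby("repeat"):
        sub = sub.copy()
        sub["logf"] = np.log(sub["fluorescence"].to_numpy())
        interior = sub[~sub["border"]]
        X = _quadratic_design(interior["row"].to_numpy(float), interior["col"].to_numpy(float))
        rlm = sm.RLM(interior["logf"].to_numpy(), X, M=sm.robust.norms.HuberT()).fit()
        X_all = _quadratic_design(sub["row"].to_numpy(float), sub["col"].to_numpy(float))
        sub["residual"] = sub["logf"].to_numpy() - X_all @ rlm.params

        _check_autocorrelation(sub[~sub["border"]], warn_autocorr)

        per_pep = sub.groupby("peptide_id").agg(
            residual=("residual", "mean"), border=("border", "any")
        )
        interior_res = per_pep.loc[~per_pep["border"], "residual"]
        mu, sd = interior_res.mean(), interior_res.std()
        # degenerate scan (numerically exact surface): all Z defined as 0
        if not np.isfinite(sd) or sd < 1e-9:
            sd = np.inf
        per_pep["z"] = (per_pep["residual"] - mu) / sd
        per_pep["repeat"] = rep
        per_repeat.append(per_pep.reset_index())
    stacked = pd.concat(per_repeat)
    out = stacked.groupby("peptide_id").agg(z=("z", "mean"), border=("border", "any"))
    return out.reset_index()


def _check_autocorrelation(interior: pd.DataFrame, threshold: float) -> float:
    """Lag-1 (rook-neighbour) spatial autocorrelation of residuals; warns
    above the threshold (possible over-splash between neighbouring spots)."""
    grid = interior.set_index(["row", "col"])["residual"]
    res = grid.to_numpy()
    if res.size < 4 or np.std(res) < 1e-9:
        return 0.0
    pairs = []
    lookup = grid.to_dict()
    for (r, c), v in lookup.items():
        for dr, dc in ((0, 1), (1, 0)):
            other = lookup.get((r + dr, c + dc))
            if other is not None:
                pairs.append((v, other))
    if len(pairs) < 3:
        return 0.0
    a, b = np.array(pairs).T
    rho = float(np.corrcoef(a, b)[0, 1])
    if rho > threshold:
        warnings.warn(
            f"spatial autocorrelation of residuals {rho:.2f} exceeds {threshold}; "
            "possible over-splash within the chip interior"
        )
    return rho


@dataclass
class IC50Fit:
    ic50: float | None
    f_min: float
    f_max: float
    residual_sd: float
    converged: bool
    no_binding: bool
    reason: str = ""


def _single_site(conc, f_min, f_max, ic50):
    return f_min + (f_max - f_min) / (1.0 + conc / ic50)


def fit_ic50(concentrations, polarization, max_tested: float | None = None) -> IC50Fit:
    """Fit the single-site competitive inhibition model.

    A no-binding verdict (rather than an exception) is returned when the fit
    does not converge, when the fitted dynamic range is below three residual
    standard deviations, or when the IC50 lands above the largest tested
    concentration.
    """
    conc = np.asarray(concentrations, dtype=float)
    pol = np.asarray(polarization, dtype=float)
    if conc.ndim != 1 or np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if pol.ndim == 2:  # replicate columns
        conc = np.repeat(conc, pol.shape[1])
        pol = pol.ravel()
    if np.unique(conc).size < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if max_tested is None:
        max_tested = float(conc.max())
    p0 = [pol.min(), pol.max(), float(np.median(np.unique(conc)))]
    try:
        params, _ = curve_fit(
            _single_site,
            conc,
            pol,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 1e9]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        return IC50Fit(None, np.nan, np.nan, np.nan, False, True, f"no convergence: {exc}")
    f_min, f_max, ic50 = map(float, params)
    resid = pol - _single_site(conc, *params)
    resid_sd = float(np.std(resid, ddof=3)) if resid.size > 3 else float(np.std(resid))
    span = abs(f_max - f_min)
    if span < 3 * resid_sd:
        return IC50Fit(ic50, f_min, f_max, resid_sd, True, True, "dynamic range within noise")
    if ic50 > max_tested:
        return IC50Fit(ic50, f_min, f_max, resid_sd, True, True, "IC50 beyond tested range")
    return IC50Fit(ic50, f_min, f_max, resid_sd, True, False)


def bound_fraction(polarization, fit: IC50Fit) -> np.ndarray:
    """Map polarization onto [0, 1] using the fitted endpoints:
    (P - f_min) / (f_max - f_min)."""
    pol = np.asarray(polarization, dtype=float)
    return (pol - fit.f_min) / (fit.f_max - fit.f_min)
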