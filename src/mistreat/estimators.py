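"""Treatment-effect estimators for a (possibly misclassified) binary exposure.

All estimators share one input container, :class:`RegressionInput`, and one
output record, :class:`EstimationResult`.  The regression design is always
``outcome ~ const + treatment [+ eta] + controls + location dummies``;
instruments enter a two-stage least-squares first stage together with every
exogenous regressor.  Standard errors are cluster-robust (CR1 small-sample
scaling) whenever cluster ids are supplied.

The eta-control device: because the reported treatment is ``T = T* + eta``,
the design spanned by ``(1, T, eta, X)`` is identical to the one spanned by
``(1, T*, eta, X)``, so including the misclassification code as a regressor
algebraically equalizes the adoption coefficient across the two treatment
measurements — the property the empirical tables print as 0.00 differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import ndtr
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.tools import numdiff

from ._bvn import bvn_cdf

__all__ = [
    "EstimationResult",
    "RegressionInput",
    "ols_effect",
    "iv_effect",
    "eta_control_effect",
    "lewbel_iv",
    "biprobit_ate",
    "bootstrap_se",
    "slope_ols",
    "slope_iv",
]

WEAK_F_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class EstimationResult:
    """One fitted treatment-effect estimate with its diagnostics."""

    estimator: str
    coef_adoption: float
    se: float
    n_obs: int
    coef_eta: float | None = None
    se_eta: float | None = None
    first_stage_F: float | None = None
    cluster_var: str | None = None
    n_dropped: int = 0
    weak_identification: bool = False
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")

    def to_record(self) -> dict:
        return {
            "estimator": self.estimator,
            "coef_adoption": self.coef_adoption,
            "se": self.se,
            "coef_eta": self.coef_eta,
            "n_obs": self.n_obs,
            "first_stage_F": self.first_stage_F,
            "cluster_var": self.cluster_var,
            "weak_identification": self.weak_identification,
        }


@dataclass
class RegressionInput:
    """Aligned arrays for one regression; rows with missing values are dropped."""

    outcome: np.ndarray
    treatment: np.ndarray
    controls: np.ndarray | None = None
    location: np.ndarray | None = None
    instruments: np.ndarray | None = None
    eta: np.ndarray | None = None
    clusters: np.ndarray | None = None
    control_names: Sequence[str] | None = None
    instrument_names: Sequence[str] | None = None
    cluster_var: str | None = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.treatment = np.asarray(self.treatment, dtype=float)
        n = self.outcome.shape[0]
        if self.controls is not None:
            self.controls = np.atleast_2d(np.asarray(self.controls, dtype=float))
            if self.controls.shape[0] != n and self.controls.shape[1] == n:
                self.controls = self.controls.T
        if self.instruments is not None:
            self.instruments = np.atleast_2d(
                np.asarray(self.instruments, dtype=float)
            )
            if self.instruments.shape[0] != n and self.instruments.shape[1] == n:
                self.instruments = self.instruments.T
        if self.eta is not None:
            self.eta = np.asarray(self.eta, dtype=float)
        if self.location is not None:
            self.location = np.asarray(self.location)
        if self.clusters is not None:
            self.clusters = np.asarray(self.clusters)
        for name, arr in (
            ("treatment", self.treatment),
            ("eta", self.eta),
            ("location", self.location),
            ("clusters", self.clusters),
        ):
            if arr is not None and arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, outcome has {n}")
        for name, arr in (("controls", self.controls), ("instruments", self.instruments)):
            if arr is not None and arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, outcome has {n}")
        if self.controls is not None and self.control_names is None:
            self.control_names = [f"x{j}" for j in range(self.controls.shape[1])]
        if self.instruments is not None and self.instrument_names is None:
            self.instrument_names = [f"z{j}" for j in range(self.instruments.shape[1])]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        treatment: str,
        controls: Sequence[str] = (),
        location: str | None = None,
        instruments: Sequence[str] = (),
        eta: str | None = None,
        clusters: str | None = None,
    ) -> "RegressionInput":
        """Build an input from a table with declared column roles."""
        return cls(
            outcome=df[outcome].to_numpy(),
            treatment=df[treatment].to_numpy(),
            controls=df[list(controls)].to_numpy() if controls else None,
            location=df[location].to_numpy() if location else None,
            instruments=df[list(instruments)].to_numpy() if instruments else None,
            eta=df[eta].to_numpy() if eta else None,
            clusters=df[clusters].to_numpy() if clusters else None,
            control_names=list(controls) or None,
            instrument_names=list(instruments) or None,
            cluster_var=clusters,
        )

    # -- design construction ----------------------------------------------
    def _missing_mask(self) -> np.ndarray:
        ok = np.isfinite(self.outcome) & np.isfinite(self.treatment)
        if self.controls is not None:
            ok &= np.isfinite(self.controls).all(axis=1)
        if self.instruments is not None:
            ok &= np.isfinite(self.instruments).all(axis=1)
        if self.eta is not None:
            ok &= np.isfinite(self.eta)
        if self.location is not None:
            ok &= ~pd.isna(self.location)
        if self.clusters is not None:
            ok &= ~pd.isna(self.clusters)
        return ok

    def design(self, include_eta: bool = False):
        """Return ``(y, X, Z, clusters, n_dropped)`` after listwise deletion.

        ``X`` and ``Z`` are DataFrames with named columns; ``Z`` is ``None``
        when no instruments were supplied.
        """
        ok = self._missing_mask()
        n_dropped = int((~ok).sum())
        y = self.outcome[ok]
        cols: dict[str, np.ndarray] = {"const": np.ones(ok.sum())}
        cols["treatment"] = self.treatment[ok]
        if include_eta:
            if self.eta is None:
                raise ValueError("eta vector required but absent")
            cols["eta"] = self.eta[ok]
        if self.controls is not None:
            for j, name in enumerate(self.control_names):
                cols[name] = self.controls[ok, j]
        X = pd.DataFrame(cols)
        if self.location is not None:
            dummies = pd.get_dummies(
                pd.Series(self.location[ok]).astype(str), prefix="loc", drop_first=True
            ).astype(float)
            X = pd.concat([X.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
        _check_full_rank(X)
        Z = None
        if self.instruments is not None:
            zcols = {"const": np.ones(ok.sum())}
            for j, name in enumerate(self.instrument_names):
                zcols[name] = self.instruments[ok, j]
            Z = pd.DataFrame(zcols)
            exog = [c for c in X.columns if c not in ("const", "treatment")]
            Z = pd.concat(
                [Z.reset_index(drop=True), X[exog].reset_index(drop=True)], axis=1
            )
            _check_full_rank(Z)
        clusters = self.clusters[ok] if self.clusters is not None else None
        return y, X, Z, clusters, n_dropped

    def take(self, idx: np.ndarray, clusters: np.ndarray | None = None) -> "RegressionInput":
        """Row subset (bootstrap helper); optionally override cluster labels."""
        sub = lambda a: None if a is None else a[idx]
        return replace(
            self,
            outcome=self.outcome[idx],
            treatment=self.treatment[idx],
            controls=sub(self.controls),
            location=sub(self.location),
            instruments=sub(self.instruments),
            eta=sub(self.eta),
            clusters=clusters if clusters is not None else sub(self.clusters),
        )


def _check_full_rank(X: pd.DataFrame) -> None:
    a = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(a) < a.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(a, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        tol = d.max() * max(a.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(len(d)) if d[i] < tol]
        bad += [X.columns[j] for j in piv[len(d):]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# covariance helpers


def _cr1_cov(A: np.ndarray, scores: np.ndarray, clusters: np.ndarray | None, k: int):
    """Sandwich covariance A S A' with CR1 (clustered) or HC1 scaling.

    ``scores`` has one row per observation: ``xhat_i * u_i``.
    """
    n = scores.shape[0]
    if clusters is None:
        meat = scores.T @ scores
        scale = n / max(n - k, 1)
    else:
        df = pd.DataFrame(scores)
        sums = df.groupby(pd.Series(clusters).values).sum().to_numpy()
        meat = sums.T @ sums
        g = sums.shape[0]
        scale = (g / max(g - 1, 1)) * ((n - 1) / max(n - k, 1))
    return scale * (A @ meat @ A.T)


def slope_ols(y: np.ndarray, t: np.ndarray) -> float:
    """Closed-form two-variable OLS slope cov(T, Y)/var(T)."""
    m = np.cov(np.asarray(t, float), np.asarray(y, float))
    return float(m[0, 1] / m[0, 0])


def slope_iv(y: np.ndarray, t: np.ndarray, z: np.ndarray) -> float:
    """Closed-form just-identified IV slope cov(z, Y)/cov(z, T)."""
    z = np.asarray(z, float)
    return float(np.cov(z, np.asarray(y, float))[0, 1] / np.cov(z, np.asarray(t, float))[0, 1])


# ---------------------------------------------------------------------------
# estimators


def ols_effect(input: RegressionInput, include_eta: bool = False) -> EstimationResult:
    """Least-squares effect of treatment on the outcome.

    Cluster-robust (CR1) standard errors when cluster ids are present,
    heteroscedasticity-robust (HC1) otherwise.
    """
    y, X, _, clusters, n_dropped = input.design(include_eta=include_eta)
    model = sm.OLS(y, X)
    if clusters is not None:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": clusters})
    else:
        res = model.fit(cov_type="HC1")
    return EstimationResult(
        estimator="ols_eta" if include_eta else "ols",
        coef_adoption=float(res.params["treatment"]),
        se=float(res.bse["treatment"]),
        coef_eta=float(res.params["eta"]) if include_eta else None,
        se_eta=float(res.bse["eta"]) if include_eta else None,
        n_obs=int(res.nobs),
        cluster_var=input.cluster_var if clusters is not None else None,
        n_dropped=n_dropped,
        params=dict(res.params),
        diagnostics={"r2": float(res.rsquared)},
    )


def _first_stage_F(t: np.ndarray, Z: pd.DataFrame, excluded: list[str]) -> float:
    """Homoskedastic partial F-statistic of the excluded instruments."""
    full = sm.OLS(t, Z).fit()
    restricted_cols = [c for c in Z.columns if c not in excluded]
    if restricted_cols:
        restr = sm.OLS(t, Z[restricted_cols]).fit()
        rss_r = restr.ssr
    else:
        rss_r = float(((t - t.mean()) ** 2).sum())
    q = len(excluded)
    dof = len(t) - Z.shape[1]
    if dof <= 0 or full.ssr <= 0:
        return np.inf
    return float(((rss_r - full.ssr) / q) / (full.ssr / dof))


def _fit_2sls(y, X: pd.DataFrame, Z: pd.DataFrame, clusters):
    """Two-stage least squares with CR1/HC1 sandwich covariance."""
    Xa, Za = X.to_numpy(dtype=float), Z.to_numpy(dtype=float)
    if Za.shape[1] < Xa.shape[1]:
        raise ValueError(
            f"under-identified: {Za.shape[1]} instrument columns for "
            f"{Xa.shape[1]} regressors"
        )
    gamma, *_ = np.linalg.lstsq(Za, Xa, rcond=None)
    Xhat = Za @ gamma
    XtX = Xhat.T @ Xa
    beta = np.linalg.solve(XtX, Xhat.T @ y)
    u = y - Xa @ beta
    A = np.linalg.inv(XtX)
    scores = Xhat * u[:, None]
    V = _cr1_cov(A, scores, clusters, Xa.shape[1])
    params = pd.Series(beta, index=X.columns)
    bse = pd.Series(np.sqrt(np.diag(V)), index=X.columns)
    return params, bse


def iv_effect(input: RegressionInput, include_eta: bool = False) -> EstimationResult:
    """Two-stage least-squares effect, instrumenting the treatment.

    Every exogenous regressor (controls, location dummies and, when present,
    the misclassification code) is included in the instrument set; the
    first-stage partial F of the excluded instruments is reported, with a
    weak-identification flag below F = 10.
    """
    if input.instruments is None:
        raise ValueError("iv_effect requires at least one instrument")
    y, X, Z, clusters, n_dropped = input.design(include_eta=include_eta)
    excluded = [c for c in Z.columns if c not in X.columns]
    fsF = _first_stage_F(X["treatment"].to_numpy(), Z, excluded) if excluded else np.inf
    params, bse = _fit_2sls(y, X, Z, clusters)
    return EstimationResult(
        estimator="iv_eta" if include_eta else "iv2sls",
        coef_adoption=float(params["treatment"]),
        se=float(bse["treatment"]),
        coef_eta=float(params["eta"]) if include_eta else None,
        se_eta=float(bse["eta"]) if include_eta else None,
        n_obs=len(y),
        first_stage_F=float(fsF),
        cluster_var=input.cluster_var if clusters is not None else None,
        n_dropped=n_dropped,
        weak_identification=bool(fsF < WEAK_F_THRESHOLD),
        params=dict(params),
    )


def eta_control_effect(input: RegressionInput) -> EstimationResult:
    """Effect with the misclassification code included as a regressor.

    Runs OLS, or 2SLS when instruments are present (the code enters as an
    exogenous included instrument).  Returns both the adoption coefficient and
    the coefficient on the code.
    """
    if input.eta is None:
        raise ValueError("eta_control_effect requires the eta vector")
    if not np.any(input.eta):
        # degenerate all-zero code: the column spans nothing, so the model is
        # exactly the plain regression with a zero coefficient on the code
        res = (
            iv_effect(input) if input.instruments is not None else ols_effect(input)
        )
        res.estimator = "iv_eta" if input.instruments is not None else "ols_eta"
        res.coef_eta = 0.0
        res.se_eta = 0.0
        return res
    if input.instruments is not None:
        return iv_effect(input, include_eta=True)
    return ols_effect(input, include_eta=True)


def lewbel_iv(
    input: RegressionInput,
    continuous_cols: Sequence[str] | None = None,
    het_pvalue_threshold: float = 0.10,
) -> EstimationResult:
    """Heteroscedasticity-based IV with internally constructed instruments.

    The treatment is first projected on the exogenous regressors; instruments
    are then formed as mean-centered continuous regressors times the
    first-stage residuals, valid when those residuals are heteroscedastic in
    the regressors.  A Breusch-Pagan test of the first stage is attached and
    the result is flagged weakly identified when the test does not reject.
    """
    if input.instruments is not None:
        raise ValueError("lewbel_iv constructs its own instruments; drop Z")
    if input.controls is None:
        raise ValueError("lewbel_iv requires at least one continuous control")
    y, X, _, clusters, n_dropped = input.design(include_eta=False)
    exog_cols = [c for c in X.columns if c != "treatment"]
    exog = X[exog_cols]
    t = X["treatment"].to_numpy()
    fs = sm.OLS(t, exog).fit()
    e = fs.resid

    if continuous_cols is None:
        continuous_cols = [
            c
            for c in input.control_names
            if c in X.columns and np.unique(X[c].to_numpy()).size > 10
        ]
        if not continuous_cols:  # fall back to any non-constant control
            continuous_cols = [
                c for c in input.control_names if np.unique(X[c].to_numpy()).size > 2
            ]
    if not continuous_cols:
        raise ValueError("no continuous regressor available to build instruments")

    zcols = {}
    for c in continuous_cols:
        xc = X[c].to_numpy()
        zcols[f"lw_{c}"] = (xc - xc.mean()) * e
    Z = pd.concat([exog.reset_index(drop=True), pd.DataFrame(zcols)], axis=1)

    _, bp_pvalue, _, _ = het_breuschpagan(e, exog.to_numpy())
    weak = bool(bp_pvalue > het_pvalue_threshold)
    params, bse = _fit_2sls(y, X, Z, clusters)
    fsF = _first_stage_F(t, Z, list(zcols))
    return EstimationResult(
        estimator="lewbel",
        coef_adoption=float(params["treatment"]),
        se=float(bse["treatment"]),
        n_obs=len(y),
        first_stage_F=float(fsF),
        cluster_var=input.cluster_var if clusters is not None else None,
        n_dropped=n_dropped,
        weak_identification=weak or fsF < WEAK_F_THRESHOLD,
        params=dict(params),
        diagnostics={"bp_pvalue": float(bp_pvalue), "instruments": list(zcols)},
    )


# ---------------------------------------------------------------------------
# bivariate probit


class ConvergenceError(RuntimeError):
    pass


def biprobit_ate(
    input: RegressionInput,
    fix_rho: float | None = None,
    maxiter: int = 500,
    gtol: float = 1e-6,
) -> EstimationResult:
    """Recursive bivariate probit for a binary outcome with binary treatment.

    Two latent equations with jointly normal errors of correlation ``rho``:
    the outcome equation contains the treatment and all exogenous regressors;
    the treatment equation contains the instruments and the same exogenous
    regressors.  Estimated by maximum likelihood over the four observed
    quadrants (bivariate-normal CDF likelihood), started from two independent
    probits.  The reported effect is the sample-average treatment effect

        ATE = mean_i[ Phi(x_i'b + g) - Phi(x_i'b) ].

    Standard errors come from the inverse observed information with a delta
    method for the ATE.  Raises :class:`ConvergenceError` (with the final
    gradient norm) on failure; flags the result when ``|rho|`` is pinned near
    the boundary.
    """
    if input.instruments is None:
        raise ValueError("biprobit_ate requires instruments in the treatment equation")
    y, X, Z, clusters, n_dropped = input.design(include_eta=False)
    w = y.astype(float)
    if not np.isin(w, (0.0, 1.0)).all():
        raise ValueError("biprobit outcome must be binary")
    t = X["treatment"].to_numpy()
    Xo = X.drop(columns=["treatment"])  # outcome eq. exogenous part
    Xt = Z  # treatment eq.: instruments + exogenous
    Xo_a, Xt_a = Xo.to_numpy(dtype=float), Xt.to_numpy(dtype=float)
    ko, kt = Xo_a.shape[1], Xt_a.shape[1]
    q1, q2 = 2.0 * w - 1.0, 2.0 * t - 1.0

    est_rho = fix_rho is None

    def unpack(theta):
        bo = theta[:ko]
        g = theta[ko]
        bt = theta[ko + 1 : ko + 1 + kt]
        r = np.tanh(theta[-1]) if est_rho else float(fix_rho)
        return bo, g, bt, r

    def nll(theta):
        bo, g, bt, r = unpack(theta)
        idx1 = Xo_a @ bo + g * t
        idx2 = Xt_a @ bt
        p = bvn_cdf(q1 * idx1, q2 * idx2, (q1 * q2) * r)
        return -np.log(np.clip(p, 1e-300, None)).sum()

    # starting values: independent probits
    pr_out = sm.Probit(w, pd.concat([Xo, X[["treatment"]]], axis=1)).fit(disp=0)
    pr_tr = sm.Probit(t, Xt).fit(disp=0)
    x0 = np.concatenate(
        [
            pr_out.params.drop("treatment").to_numpy(),
            [pr_out.params["treatment"]],
            pr_tr.params.to_numpy(),
            [0.0] if est_rho else [],
        ]
    )

    res = minimize(nll, x0, method="BFGS", options={"gtol": gtol, "maxiter": maxiter})
    gnorm = float(np.linalg.norm(res.jac))
    if not res.success and gnorm > 1e-3 * max(1.0, abs(res.fun)):
        raise ConvergenceError(
            f"bivariate probit did not converge (gradient norm {gnorm:.3g})"
        )
    theta = res.x
    bo, g, bt, r = unpack(theta)
    boundary = bool(abs(r) > 0.99)

    def ate_fn(th):
        bo_, g_, _, _ = unpack(th)
        base = Xo_a @ bo_
        return float(np.mean(ndtr(base + g_) - ndtr(base)))

    ate = ate_fn(theta)
    H = numdiff.approx_hess(theta, nll)
    try:
        cov = np.linalg.inv(H)
        grad_ate = numdiff.approx_fprime(theta, lambda th: np.array([ate_fn(th)]))
        se_ate = float(np.sqrt(max(grad_ate @ cov @ grad_ate.T, 0.0)))
    except np.linalg.LinAlgError:
        se_ate, cov = np.nan, None

    names = (
        [f"out_{c}" for c in Xo.columns]
        + ["treatment"]
        + [f"treat_{c}" for c in Xt.columns]
        + ["atanh_rho"]
    )
    return EstimationResult(
        estimator="biprobit",
        coef_adoption=ate,
        se=se_ate if np.isfinite(se_ate) else 0.0,
        n_obs=len(w),
        cluster_var=None,
        n_dropped=n_dropped,
        weak_identification=boundary,
        params=dict(zip(names, theta)),
        diagnostics={
            "rho": float(r),
            "gamma_latent": float(g),
            "nll": float(res.fun),
            "gradient_norm": gnorm,
            "rho_boundary": boundary,
        },
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_se(
    estimator: Callable[[RegressionInput], EstimationResult],
    input: RegressionInput,
    B: int = 200,
    rng: np.random.Generator | None = None,
    max_failure_share: float = 0.10,
) -> float:
    """Bootstrap standard deviation of the adoption coefficient.

    Resamples whole clusters with replacement when cluster ids are present
    (otherwise plain row resampling), refits ``estimator`` on each draw and
    returns the standard deviation of the coefficient across draws.  Raises
    if more than 10% of the draws fail.
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    if rng is None:
        rng = np.random.default_rng(0)
    n = input.outcome.shape[0]
    coefs: list[float] = []
    failures = 0
    if input.clusters is not None:
        labels = pd.Series(input.clusters)
        groups = {c: np.flatnonzero(labels == c) for c in labels.unique()}
        keys = list(groups)
        for _ in range(B):
            pick = rng.integers(0, len(keys), size=len(keys))
            idx = np.concatenate([groups[keys[p]] for p in pick])
            new_clusters = np.concatenate(
                [np.full(groups[keys[p]].size, i) for i, p in enumerate(pick)]
            )
            try:
                coefs.append(estimator(input.take(idx, clusters=new_clusters)).coef_adoption)
            except Exception:
                failures += 1
    else:
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            try:
                coefs.append(estimator(input.take(idx)).coef_adoption)
            except Exception:
                failures += 1
    if failures > max_failure_share * B:
        raise RuntimeError(f"estimator failed in {failures}/{B} bootstrap draws")
    return float(np.std(coefs, ddof=1))
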