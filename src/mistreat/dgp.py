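"""Data-generating process for endogenously misclassified binary treatments.

The model links a continuous welfare outcome to a binary technology-adoption
treatment that the analyst observes only through an error-ridden self report:

.. math::

    W^*_i &= \\delta T^*_i + \\mu_i                      \\\\
    T^*_i &= \\mathbf{1}[\\varphi' z_i + \\omega_i > 0]   \\\\
    T_i   &= T^*_i + \\eta_i, \\qquad \\eta_i \\in \\{-1, 0, 1\\}

where :math:`\\eta_i = -1` marks a false negative (a true adopter reporting
non-adoption), :math:`\\eta_i = +1` a false positive, and 0 correct
classification.  Optionally the outcome itself is mismeasured,
:math:`W_i = W^*_i + \\Psi_i` with :math:`\\Psi_i = \\alpha W^*_i + \\nu_i`.

The latent errors :math:`(\\mu_i, \\omega_i, e_i)` are trivariate standard
normal with correlations ``sigma_mu_omega``, ``sigma_mu_eta`` and
``sigma_omega_eta``; :math:`e_i` is a latent misreporting propensity that is
discretised into :math:`\\eta_i` by stratum-wise quantile thresholding (see
:func:`misclassify`).  Non-zero correlations make adoption and misreporting
endogenous: the discrete misclassification code inherits the dependence of the
latent propensity on the outcome and selection errors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ErrorCorrelationSpec",
    "MisclassificationSpec",
    "ScenarioConfig",
    "SimulatedSample",
    "draw_errors",
    "gen_true_adoption",
    "misclassify",
    "gen_outcome",
    "contaminate_outcome",
    "simulate",
]


@dataclass(frozen=True)
class ErrorCorrelationSpec:
    """Correlation structure of the trivariate latent error vector.

    The three latent errors (outcome error ``mu``, adoption error ``omega``
    and misreporting propensity ``eta_latent``) have unit variances, so the
    three parameters are plain correlations in ``[-1, 1]``.  Construction
    fails if the implied 3x3 correlation matrix is not positive semidefinite.
    """

    sigma_mu_omega: float = 0.0
    sigma_mu_eta: float = 0.0
    sigma_omega_eta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_mu_omega", "sigma_mu_eta", "sigma_omega_eta"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        m = self.correlation_matrix()
        w = np.linalg.eigvalsh(m)
        if w.min() < -1e-10:
            raise ValueError(
                "correlation matrix is not positive semidefinite "
                f"(min eigenvalue {w.min():.4g}):\n{m}"
            )

    def correlation_matrix(self) -> np.ndarray:
        """Return the implied 3x3 correlation matrix, ordered (mu, omega, eta)."""
        return np.array(
            [
                [1.0, self.sigma_mu_omega, self.sigma_mu_eta],
                [self.sigma_mu_omega, 1.0, self.sigma_omega_eta],
                [self.sigma_mu_eta, self.sigma_omega_eta, 1.0],
            ]
        )

    def _factor(self) -> np.ndarray:
        # Eigen factor rather than Cholesky so PSD-singular specs still work.
        w, v = np.linalg.eigh(self.correlation_matrix())
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


@dataclass(frozen=True)
class MisclassificationSpec:
    """Target false-negative and false-positive rates of the self report.

    ``fn_rate`` is the share of true adopters reporting non-adoption,
    ``fp_rate`` the share of true non-adopters reporting adoption.
    """

    fn_rate: float = 0.0
    fp_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fn_rate", "fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: effect sizes, error structure and sample sizes.

    Parameters
    ----------
    delta
        True treatment effect of adoption on the outcome.
    n
        Sample size per replicate (``n >= 2``).
    reps
        Number of Monte Carlo replicates.
    seed
        Seed for the scenario's random stream.
    alpha
        Slope of the non-classical outcome measurement error
        ``Psi = alpha * W* + nu``; 0 disables outcome contamination.
    phi
        Instrument coefficient vector; instruments are drawn i.i.d. standard
        normal.  The default single instrument with unit coefficient gives a
        strong first stage and an adoption rate of one half.
    nu_sd
        Standard deviation of the idiosyncratic outcome-error noise ``nu``.
    """

    delta: float
    n: int
    reps: int = 1
    seed: int = 0
    alpha: float = 0.0
    phi: tuple[float, ...] = (1.0,)
    nu_sd: float = 0.0
    error_spec: ErrorCorrelationSpec = field(default_factory=ErrorCorrelationSpec)
    mis_spec: MisclassificationSpec = field(default_factory=MisclassificationSpec)

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if len(self.phi) < 1:
            raise ValueError("phi must contain at least one coefficient")
        object.__setattr__(self, "phi", tuple(float(p) for p in self.phi))

    # -- scenario files ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phi"] = list(self.phi)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "error_spec" in d and isinstance(d["error_spec"], dict):
            d["error_spec"] = ErrorCorrelationSpec(**d["error_spec"])
        if "mis_spec" in d and isinstance(d["mis_spec"], dict):
            d["mis_spec"] = MisclassificationSpec(**d["mis_spec"])
        if "phi" in d:
            d["phi"] = tuple(d["phi"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load a scenario from a JSON or YAML file mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class SimulatedSample:
    """One draw of the full data-generating process for ``n`` units."""

    z: np.ndarray  # (n, k) instruments
    mu: np.ndarray
    omega: np.ndarray
    eta_latent: np.ndarray
    t_star: np.ndarray
    t_obs: np.ndarray
    eta: np.ndarray
    w_star: np.ndarray
    w_obs: np.ndarray
    nu: np.ndarray

    def __post_init__(self) -> None:
        if not np.array_equal(self.t_obs, self.t_star + self.eta):
            raise ValueError("t_obs must equal t_star + eta elementwise")

    @property
    def n(self) -> int:
        return self.t_star.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        z = np.atleast_2d(self.z.T).T
        cols = {f"z{j}" if z.shape[1] > 1 else "z": z[:, j] for j in range(z.shape[1])}
        cols.update(
            mu=self.mu,
            omega=self.omega,
            eta_latent=self.eta_latent,
            t_star=self.t_star,
            t_obs=self.t_obs,
            eta=self.eta,
            w_star=self.w_star,
            w_obs=self.w_obs,
        )
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def draw_errors(
    spec: ErrorCorrelationSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` trivariate standard-normal errors with the spec's correlations.

    Returns the triple ``(mu, omega, eta_latent)`` of length-``n`` vectors,
    jointly Gaussian with zero means, unit variances and pairwise correlations
    ``(sigma_mu_omega, sigma_mu_eta, sigma_omega_eta)``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    x = rng.standard_normal((n, 3)) @ spec._factor().T
    return x[:, 0], x[:, 1], x[:, 2]


def gen_true_adoption(
    z: np.ndarray, phi: np.ndarray | tuple[float, ...] | float, omega: np.ndarray
) -> np.ndarray:
    """True adoption indicator ``T* = 1[phi'z + omega > 0]`` (strict inequality)."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[1] != phi.shape[0]:
        raise ValueError(f"z has {z.shape[1]} columns but phi has {phi.shape[0]}")
    omega = np.asarray(omega, dtype=float)
    if omega.shape[0] != z.shape[0]:
        raise ValueError("omega length does not match z")
    return (z @ phi + omega > 0).astype(np.int64)


def misclassify(
    t_star: np.ndarray, eta_latent: np.ndarray, mis: MisclassificationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Discretise the latent misreporting propensity into the code ``eta``.

    Within the stratum of true adopters, the ``round(fn_rate * n1)`` units with
    the *lowest* latent propensity are flipped to reported non-adoption
    (``eta = -1``); within the stratum of true non-adopters, the
    ``round(fp_rate * n0)`` units with the *highest* propensity are flipped to
    reported adoption (``eta = +1``).  Thresholding at the empirical stratum
    quantile keeps the realized false-negative/false-positive rates at their
    targets for any correlation structure of the latent errors, while the
    discrete code stays correlated with ``(mu, omega)`` through the latent
    ranking — which is what makes the misreporting endogenous.
    """
    t_star = np.asarray(t_star)
    eta_latent = np.asarray(eta_latent, dtype=float)
    if t_star.shape != eta_latent.shape:
        raise ValueError("t_star and eta_latent must have the same length")
    eta = np.zeros(t_star.shape[0], dtype=np.int64)

    adopters = np.flatnonzero(t_star == 1)
    k_fn = int(round(mis.fn_rate * adopters.size))
    if k_fn > 0:
        flip = adopters[np.argpartition(eta_latent[adopters], k_fn - 1)[:k_fn]]
        eta[flip] = -1

    non = np.flatnonzero(t_star == 0)
    k_fp = int(round(mis.fp_rate * non.size))
    if k_fp > 0:
        flip = non[np.argpartition(-eta_latent[non], k_fp - 1)[:k_fp]]
        eta[flip] = 1

    return np.asarray(t_star, dtype=np.int64) + eta, eta


def gen_outcome(t_star: np.ndarray, mu: np.ndarray, delta: float) -> np.ndarray:
    """True outcome ``W* = delta * T* + mu``."""
    t_star = np.asarray(t_star, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if t_star.shape != mu.shape:
        raise ValueError("t_star and mu must have the same length")
    return delta * t_star + mu


def contaminate_outcome(
    w_star: np.ndarray, alpha: float, nu: np.ndarray
) -> np.ndarray:
    """Observed outcome ``W = W* + alpha*W* + nu`` (mean-reverting for alpha<0)."""
    w_star = np.asarray(w_star, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if w_star.shape != nu.shape:
        raise ValueError("w_star and nu must have the same length")
    return (1.0 + alpha) * w_star + nu


def simulate(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> SimulatedSample:
    """Draw one full sample under ``config``.

    A fresh generator is seeded from ``config.seed`` unless ``rng`` is given,
    in which case the caller's stream is consumed (useful for replicates).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, k = config.n, len(config.phi)
    z = rng.standard_normal((n, k))
    mu, omega, eta_latent = draw_errors(config.error_spec, n, rng)
    t_star = gen_true_adoption(z, config.phi, omega)
    t_obs, eta = misclassify(t_star, eta_latent, config.mis_spec)
    w_star = gen_outcome(t_star, mu, config.delta)
    nu = (
        config.nu_sd * rng.standard_normal(n)
        if config.nu_sd > 0
        else np.zeros(n)
    )
    w_obs = contaminate_outcome(w_star, config.alpha, nu)
    return SimulatedSample(
        z=z,
        mu=mu,
        omega=omega,
        eta_latent=eta_latent,
        t_star=t_star,
        t_obs=t_obs,
        eta=eta,
        w_star=w_star,
        w_obs=w_obs,
        nu=nu,
    )
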