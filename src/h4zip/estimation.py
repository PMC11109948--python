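"""Maximum-likelihood calibration of the model families and AIC ranking.

Each model family is calibrated to replicate motif time courses by
multi-start bounded local optimization on log10-transformed parameters,
with an additive Gaussian noise model on the relative abundances.  Families
are then compared by the Akaike Information Criterion
``AIC = 2 k - 2 log L``; a family whose AIC exceeds the best by 10 or more
is rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import (
    IntegrationError,
    MassActionModel,
    MichaelisMentenModel,
    ProcessiveModel,
    simulate,
)
from .motifs import TransitionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourseDataset",
    "FamilySpec",
    "LikelihoodSpec",
    "FitResult",
    "ModelComparison",
    "negative_log_likelihood",
    "fit",
    "aic",
    "compare",
]

_LOG_2PI = np.log(2.0 * np.pi)
PENALTY_NLL = 1e10  # returned (plus a bounds-distance term) on solver failure


@dataclass
class TimeCourseDataset:
    """Replicate measurements of relative motif abundances over time.

    ``y`` has shape (n_motifs, n_times, n_replicates) in the motif order of
    ``motifs``; ``mask`` marks points to exclude from the likelihood
    (e.g. below the detection limit).
    """

    times: np.ndarray
    motifs: list[str]
    y: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape[0] != len(self.motifs) or self.y.shape[1] != len(self.times):
            raise ValueError("y must have shape (n_motifs, n_times, n_replicates)")
        if self.y.ndim != 3 or self.y.shape[2] < 1:
            raise ValueError("at least one replicate required")
        if np.any((self.y < 0) | (self.y > 1)):
            raise ValueError("relative abundances must lie in [0, 1]")
        if self.mask is None:
            self.mask = np.zeros_like(self.y, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.y.shape:
                raise ValueError("mask shape must match y")

    @property
    def n_points(self) -> int:
        return int((~self.mask).sum())

    def to_long_df(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.motifs):
            for j, t in enumerate(self.times):
                for r in range(self.y.shape[2]):
                    rows.append(
                        {"motif_label": m, "time_min": t, "replicate": r + 1,
                         "y": self.y[i, j, r], "masked": bool(self.mask[i, j, r])}
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_long_df().to_csv(path, index=False)

    @classmethod
    def from_long_df(cls, df: pd.DataFrame, motifs: list[str] | None = None) -> "TimeCourseDataset":
        """Build from the long CSV schema (motif_label, time_min, replicate, y[, masked])."""
        if motifs is None:
            motifs = list(dict.fromkeys(df["motif_label"]))
        times = np.sort(df["time_min"].unique())
        reps = sorted(df["replicate"].unique())
        y = np.zeros((len(motifs), len(times), len(reps)))
        mask = np.zeros_like(y, dtype=bool)
        has_mask = "masked" in df.columns
        t_idx = {t: j for j, t in enumerate(times)}
        r_idx = {r: k for k, r in enumerate(reps)}
        m_idx = {m: i for i, m in enumerate(motifs)}
        for row in df.itertuples(index=False):
            i = m_idx[row.motif_label]
            j = t_idx[row.time_min]
            k = r_idx[row.replicate]
            y[i, j, k] = row.y
            if has_mask:
                mask[i, j, k] = bool(row.masked)
        return cls(times=times, motifs=motifs, y=y, mask=mask)

    @classmethod
    def from_csv(cls, path, motifs: list[str] | None = None) -> "TimeCourseDataset":
        return cls.from_long_df(pd.read_csv(path), motifs)


@dataclass
class FamilySpec:
    """A fittable model family: which parameters are free and how a
    parameter vector maps to a concrete kinetic model.

    ``mode`` selects the parameterization: "site" shares one catalytic rate
    per site across all motifs (reduced, 4 rates wild-type); "edge" assigns
    one rate per lattice edge (full, 32 rates wild-type, needed for the
    per-motif site-preference profile).
    """

    family: str  # mass_action | michaelis_menten | processive
    network: TransitionNetwork
    mode: str = "site"
    e_tot: float = 0.25
    with_transfer: bool = False

    def __post_init__(self):
        if self.family not in ("mass_action", "michaelis_menten", "processive"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mode not in ("site", "edge"):
            raise ValueError(f"unknown parameterization mode {self.mode!r}")

    @property
    def rate_names(self) -> list[str]:
        if self.mode == "site":
            return [f"kcat_{s}" for s in self.network.sites]
        return [f"kcat_{e.source.label}__{e.site}" for e in self.network.edges]

    @property
    def param_names(self) -> list[str]:
        names = list(self.rate_names)
        if self.family == "michaelis_menten":
            names.append("Km")
        elif self.family == "processive":
            names += ["kon", "koff"]
            if self.with_transfer:
                names.append("k_transfer")
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def _edge_rates(self, rates: np.ndarray) -> np.ndarray:
        if self.mode == "edge":
            return rates
        by_site = dict(zip(self.network.sites, rates))
        return np.array([by_site[e.site] for e in self.network.edges])

    def build(self, theta: np.ndarray):
        """Instantiate the model at a natural-scale parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, got {theta.shape}")
        n_rates = len(self.rate_names)
        edge = self._edge_rates(theta[:n_rates])
        rest = theta[n_rates:]
        if self.family == "mass_action":
            return MassActionModel(self.network, edge)
        if self.family == "michaelis_menten":
            return MichaelisMentenModel(self.network, edge, Km=rest[0], e_tot=self.e_tot)
        kon, koff = rest[0], rest[1]
        k_transfer = rest[2] if self.with_transfer else 0.0
        return ProcessiveModel(
            self.network, edge, kon=kon, koff=koff, e_tot=self.e_tot, k_transfer=k_transfer
        )

    def restricted(self, site: str) -> "FamilySpec":
        """The same family on the lattice with ``site`` disabled."""
        from .motifs import restrict_site

        return replace(self, network=restrict_site(self.network, site))


@dataclass
class LikelihoodSpec:
    """Gaussian observation noise and the optimizer's parameter space.

    Three noise modes: ``sigma`` a float fixes one known scale;
    ``sigma=None`` with ``sigma_mode="single"`` profiles one scale
    analytically at its conditional MLE (one extra parameter in the AIC);
    ``sigma_mode="per_motif"`` profiles one scale per motif (floored at
    ``sigma_floor``), which absorbs the abundance-dependent noise that
    sum-normalization of relative abundances induces on high-abundance
    motifs.  Bounds are on the natural scale and shared by all parameters;
    optimization is on log10.
    """

    sigma: float | None = None
    sigma_mode: str = "single"  # "single" | "per_motif"; ignored if sigma is set
    sigma_floor: float = 1e-3
    bounds: tuple[float, float] = (1e-5, 1e3)
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-9

    def __post_init__(self):
        lo, hi = self.bounds
        if not (0 < lo < hi) or not np.isfinite(hi):
            raise ValueError("bounds must be finite and positive with lo < hi")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.sigma_mode not in ("single", "per_motif"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")

    @property
    def n_noise_params(self) -> int:
        """Noise parameters counted in the AIC (0 when sigma is fixed)."""
        if self.sigma is not None:
            return 0
        return 1 if self.sigma_mode == "single" else -1  # resolved per dataset

    @property
    def log_bounds(self) -> tuple[float, float]:
        return (np.log10(self.bounds[0]), np.log10(self.bounds[1]))


def _simulated_y(spec: FamilySpec, theta, data: TimeCourseDataset, lik: LikelihoodSpec):
    model = spec.build(theta)
    traj = simulate(model, data.times, rtol=lik.sim_rtol, atol=lik.sim_atol)
    order = [traj.network.index(m) for m in data.motifs]
    return traj.y[order]


def negative_log_likelihood(
    spec: FamilySpec, theta, data: TimeCourseDataset, lik: LikelihoodSpec
) -> float:
    """Gaussian NLL over all unmasked (motif, time, replicate) points.

    Integration failures return a large-but-finite penalty (plus a distance
    term pulling back toward the center of the log-bounds box) so that
    multi-start optimization survives pathological parameter regions; every
    penalty is logged at WARNING level.
    """
    theta = np.asarray(theta, dtype=float)
    try:
        y_sim = _simulated_y(spec, theta, data, lik)
    except (IntegrationError, FloatingPointError) as err:
        log_lo, log_hi = lik.log_bounds
        center = 0.5 * (log_lo + log_hi)
        with np.errstate(divide="ignore"):
            dist = np.nansum(np.abs(np.log10(np.maximum(theta, 1e-300)) - center))
        logger.warning("integration failure at theta=%s: %s", theta, err)
        return PENALTY_NLL + dist

    resid_full = data.y - y_sim[:, :, None]
    resid = resid_full[~data.mask]
    n = resid.size
    if n == 0:
        raise ValueError("no unmasked data points")
    if lik.sigma is not None:
        rss = float(resid @ resid)
        s2 = lik.sigma**2
        return 0.5 * rss / s2 + 0.5 * n * (np.log(s2) + _LOG_2PI)
    if lik.sigma_mode == "single":
        # profiled sigma: conditional MLE sigma^2 = RSS / n
        rss = float(resid @ resid)
        s2_hat = max(rss / n, 1e-300)
        return 0.5 * n * (np.log(s2_hat) + _LOG_2PI + 1.0)
    # per-motif profiled sigma, floored so empty-looking motifs cannot
    # drive the likelihood to infinity
    nll = 0.0
    floor2 = lik.sigma_floor**2
    for i in range(resid_full.shape[0]):
        r_i = resid_full[i][~data.mask[i]]
        n_i = r_i.size
        if n_i == 0:
            continue
        rss_i = float(r_i @ r_i)
        s2_i = max(rss_i / n_i, floor2)
        nll += 0.5 * rss_i / s2_i + 0.5 * n_i * (np.log(s2_i) + _LOG_2PI)
    return nll


def _residual_vector(
    spec: FamilySpec, theta, data: TimeCourseDataset, lik: LikelihoodSpec
) -> np.ndarray:
    """Unmasked residuals y_obs - y_sim; on solver failure, a large smooth
    penalty vector that still points back toward the log-bounds center."""
    try:
        y_sim = _simulated_y(spec, theta, data, lik)
    except (IntegrationError, FloatingPointError):
        log_lo, log_hi = lik.log_bounds
        center = 0.5 * (log_lo + log_hi)
        with np.errstate(divide="ignore"):
            dist = np.nansum(np.abs(np.log10(np.maximum(theta, 1e-300)) - center))
        logger.warning("integration failure during least-squares at theta=%s", theta)
        return np.full(data.n_points, 1e3 * (1.0 + dist / max(len(theta), 1)))
    return (data.y - y_sim[:, :, None])[~data.mask]


@dataclass
class FitResult:
    """Outcome of a multi-start maximum-likelihood fit."""

    family: str
    theta_hat: np.ndarray
    param_names: list[str]
    logL: float
    n_params: int
    aic: float
    n_starts: int
    n_converged: int
    seed: int
    start_rss: list[float] = field(default_factory=list, repr=False)

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.theta_hat))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "theta_hat": self.params_dict(),
            "logL": self.logL,
            "n_params": self.n_params,
            "aic": self.aic,
            "n_starts": self.n_starts,
            "n_converged": self.n_converged,
            "seed": self.seed,
        }


def fit(
    spec: FamilySpec,
    data: TimeCourseDataset,
    lik: LikelihoodSpec | None = None,
    n_starts: int = 10,
    seed: int = 0,
    maxiter: int = 150,
    diff_step: float = 1e-3,
    oversample: int = 10,
) -> FitResult:
    """Multi-start bounded MLE on log10-scale parameters.

    The Gaussian likelihood (fixed or profiled sigma) is maximized exactly
    where the residual sum of squares is minimized, so each local search is
    a bounded trust-region least-squares run (TRF), which copes far better
    with the saturated-rate plateaus of these objectives than a scalar
    quasi-Newton search.  Candidate starts are drawn uniformly in the log10
    bounds from a seeded RNG, ``oversample * n_starts`` of them; the
    objective is evaluated once at each and local optimization runs from
    the ``n_starts`` best.  The result is deterministic given
    (data, spec, n_starts, seed).

    ``diff_step`` is the relative finite-difference step for the residual
    Jacobian (log10 space); it must dominate the ODE solver's truncation
    noise, so steps far below 1e-4 degrade convergence.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    lik = lik or LikelihoodSpec()
    log_lo, log_hi = lik.log_bounds
    ndim = spec.n_params
    rng = np.random.default_rng(seed)
    pool = rng.uniform(log_lo, log_hi, size=(oversample * n_starts, ndim))
    if oversample > 1:
        pool_rss = np.array(
            [float(np.square(_residual_vector(spec, 10.0**x, data, lik)).sum()) for x in pool]
        )
        starts = pool[np.argsort(pool_rss, kind="stable")[:n_starts]]
    else:
        starts = pool

    def residuals(log_theta):
        return _residual_vector(spec, 10.0**log_theta, data, lik)

    best_x = None
    best_rss = np.inf
    n_converged = 0
    start_rss = []
    for x0 in starts:
        res = least_squares(
            residuals,
            x0,
            bounds=(log_lo, log_hi),
            method="trf",
            diff_step=diff_step,
            max_nfev=maxiter * (ndim + 1),
        )
        rss = 2.0 * float(res.cost)
        start_rss.append(rss)
        if res.status > 0:
            n_converged += 1
        if np.isfinite(rss) and rss < best_rss:
            best_rss, best_x = rss, res.x
    if best_x is None or not np.isfinite(best_rss):
        raise RuntimeError(
            f"no start converged to a finite optimum (per-start RSS: {start_rss})"
        )

    theta_hat = 10.0**best_x
    logL = -negative_log_likelihood(spec, theta_hat, data, lik)
    if lik.sigma is not None:
        n_noise = 0
    elif lik.sigma_mode == "single":
        n_noise = 1
    else:  # one profiled scale per motif with data
        n_noise = int(np.sum((~data.mask).sum(axis=(1, 2)) > 0))
    n_params = ndim + n_noise
    return FitResult(
        family=spec.family,
        theta_hat=theta_hat,
        param_names=spec.param_names,
        logL=logL,
        n_params=n_params,
        aic=aic(logL, n_params),
        n_starts=n_starts,
        n_converged=n_converged,
        seed=seed,
        start_rss=start_rss,
    )


def aic(logL: float, n_params: int) -> float:
    """Akaike Information Criterion: ``2 k - 2 log L``."""
    if not np.isfinite(logL):
        raise ValueError("logL must be finite")
    return 2.0 * n_params - 2.0 * logL


@dataclass
class ModelComparison:
    """AIC ranking of fitted families with the rejection rule applied."""

    fits: list[FitResult]
    threshold: float
    table: pd.DataFrame

    @property
    def best_family(self) -> str:
        return self.table.iloc[0]["family"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare(fits: list[FitResult], threshold: float = 10.0) -> ModelComparison:
    """Rank fits by AIC; reject families with delta AIC >= threshold.

    An exact tie in the minimum AIC is resolved toward the model with fewer
    parameters.  Permutation-invariant in the input order.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    if threshold <= 0:
        raise ValueError("rejection threshold must be positive")
    ordered = sorted(fits, key=lambda f: (f.aic, f.n_params, f.family))
    best_aic = ordered[0].aic
    rows = [
        {
            "family": f.family,
            "aic": f.aic,
            "delta_aic": f.aic - best_aic,
            "n_params": f.n_params,
            "logL": f.logL,
            "rejected": (f.aic - best_aic) >= threshold,
        }
        for f in ordered
    ]
    return ModelComparison(fits=ordered, threshold=threshold, table=pd.DataFrame(rows))
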