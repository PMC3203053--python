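"""One-site hyperbola (Michaelis-Menten) uptake kinetics.

Transport rate as a function of substrate (or co-ion) concentration is
fitted to

    v([S]) = V_max * [S] / (K_M + [S])

by damped least squares, with asymptotic standard errors from the Jacobian
and 95% confidence limits from the t distribution on n - 2 degrees of
freedom.  When the fitted K_M exceeds the largest tested concentration the
fit is flagged as unsaturated: the estimate is then an extrapolation and
any comparison against it should be reported as a lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import InsufficientDataError, UnitError

MAX_ITERATIONS = 500
REL_TOL = 1e-14  # solver runs to machine precision; cheap at n <= dozens


@dataclass
class KineticsDataset:
    """Concentration/rate observations, replicates allowed per concentration.

    ``experiment`` optionally tags each observation with an independent-
    experiment id, enabling per-experiment fitting for two-sample tests.
    """

    concentrations: np.ndarray
    rates: np.ndarray
    label: str = ""
    conc_units: str = "mM"
    rate_units: str = "a.u."
    experiment: Optional[np.ndarray] = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.concentrations.shape != self.rates.shape:
            raise ValueError("concentrations and rates must have equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.experiment is not None:
            self.experiment = np.asarray(self.experiment)
            if self.experiment.shape != self.rates.shape:
                raise ValueError("experiment tags must match data length")

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations).size)

    def subset(self, experiment_id) -> "KineticsDataset":
        if self.experiment is None:
            raise ValueError("dataset carries no experiment tags")
        m = self.experiment == experiment_id
        return KineticsDataset(
            self.concentrations[m], self.rates[m], label=f"{self.label}:{experiment_id}",
            conc_units=self.conc_units, rate_units=self.rate_units,
        )


@dataclass
class KineticsFit:
    """Fitted Michaelis-Menten parameters with uncertainties."""

    K_M: float
    V_max: float
    se_KM: float
    se_Vmax: float
    ci95_KM: tuple[float, float]
    ci95_Vmax: tuple[float, float]
    converged: bool
    saturation_flag: bool  # True when K_M exceeds the largest tested concentration
    conc_units: str = "mM"
    rate_units: str = "a.u."
    rss: float = np.nan
    n_obs: int = 0
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "K_M": self.K_M, "V_max": self.V_max,
            "se_KM": self.se_KM, "se_Vmax": self.se_Vmax,
            "ci95_KM": list(self.ci95_KM), "ci95_Vmax": list(self.ci95_Vmax),
            "converged": self.converged, "saturation_flag": self.saturation_flag,
            "conc_units": self.conc_units, "rate_units": self.rate_units,
            "rss": self.rss, "n_obs": self.n_obs,
        }


def michaelis_menten(conc, K_M, V_max):
    conc = np.asarray(conc, dtype=float)
    return V_max * conc / (K_M + conc)


def fit_michaelis_menten(data: KineticsDataset) -> KineticsFit:
    """Least-squares fit of the one-site hyperbola to a dataset.

    Initialisation: V_max0 = max observed rate, K_M0 = the concentration
    whose rate is nearest half-max.  At least 4 distinct concentrations are
    required.  Non-convergence within the iteration cap returns the last
    iterate with ``converged=False`` instead of raising.
    """
    if data.n_distinct < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations, got {data.n_distinct}"
        )
    conc, rates = data.concentrations, data.rates
    # fit on rates normalised by their maximum: makes the solver path, and
    # hence the estimate, exactly equivariant under rescaling the rates
    rscale = float(np.abs(rates).max())
    if rscale <= 0:
        rscale = 1.0
    v = rates / rscale
    v0 = float(v.max()) if v.max() > 0 else 1.0
    km0 = float(conc[np.argmin(np.abs(v - v0 / 2.0))])
    if km0 <= 0:
        km0 = float(np.median(conc[conc > 0]))

    def residuals(p):
        return michaelis_menten(conc, p[0], p[1]) - v

    def jacobian(p):
        km_, vm_ = p
        denom = km_ + conc
        return np.column_stack([-vm_ * conc / denom**2, conc / denom])

    res = optimize.least_squares(
        residuals, x0=[km0, v0], jac=jacobian, method="lm",
        xtol=REL_TOL, ftol=REL_TOL, gtol=REL_TOL,
        max_nfev=MAX_ITERATIONS * 2,
    )
    # Gauss-Newton polish to the normal-equation fixed point, so the
    # estimate depends on the objective alone, not the solver path
    x = res.x.copy()
    for _ in range(20):
        j = jacobian(x)
        try:
            step = np.linalg.solve(j.T @ j, -j.T @ residuals(x))
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        x_new = x + step
        if np.linalg.norm(residuals(x_new)) > np.linalg.norm(residuals(x)) + 1e-15:
            break
        x = x_new
        if np.max(np.abs(step) / np.maximum(np.abs(x), 1e-30)) < 1e-14:
            break
    res.x = x
    km, vmax = float(res.x[0]), float(res.x[1]) * rscale
    n = conc.size
    dof = max(n - 2, 1)
    rss_norm = float(np.sum(residuals(res.x) ** 2))
    rss = rss_norm * rscale**2
    s2_norm = rss_norm / dof  # variance on the normalised scale
    jtj = jacobian(res.x).T @ jacobian(res.x)
    try:
        cov = np.linalg.inv(jtj) * s2_norm
        se_km = float(np.sqrt(cov[0, 0]))
        se_vmax = float(np.sqrt(cov[1, 1])) * rscale
    except np.linalg.LinAlgError:
        se_km = se_vmax = np.nan
    tcrit = float(stats.t.ppf(0.975, dof))
    return KineticsFit(
        K_M=km, V_max=vmax, se_KM=se_km, se_Vmax=se_vmax,
        ci95_KM=(km - tcrit * se_km, km + tcrit * se_km),
        ci95_Vmax=(vmax - tcrit * se_vmax, vmax + tcrit * se_vmax),
        converged=bool(res.status > 0),
        saturation_flag=bool(km > conc.max()),
        conc_units=data.conc_units, rate_units=data.rate_units,
        rss=rss, n_obs=int(n), label=data.label,
    )


def fit_per_experiment(data: KineticsDataset) -> list[KineticsFit]:
    """Fit each tagged independent experiment separately."""
    if data.experiment is None:
        raise ValueError("dataset carries no experiment tags")
    return [fit_michaelis_menten(data.subset(e)) for e in np.unique(data.experiment)]


@dataclass
class FitComparison:
    """K_M fold change (b relative to a) and an optional two-sample test."""

    fold_change: float
    fold_is_lower_bound: bool
    t_statistic: Optional[float] = None
    p_value: Optional[float] = None
    km_a: list = field(default_factory=list)
    km_b: list = field(default_factory=list)


def compare_fits(
    a: KineticsFit,
    b: KineticsFit,
    data_a: Optional[KineticsDataset] = None,
    data_b: Optional[KineticsDataset] = None,
) -> FitComparison:
    """Compare two fitted K_M values: fold change b/a plus unpaired t test.

    The t test runs when both datasets carry experiment tags (each
    experiment fitted separately and the per-experiment K_M samples
    compared).  If either fit is saturation-flagged, its K_M is an
    extrapolated floor, so the fold change is reported as a lower bound.
    """
    if a.conc_units != b.conc_units:
        raise UnitError(
            f"cannot compare K_M in {a.conc_units!r} with {b.conc_units!r}"
        )
    fold = b.K_M / a.K_M
    bound = a.saturation_flag or b.saturation_flag
    t_stat = p_val = None
    km_a: list = []
    km_b: list = []
    if (
        data_a is not None and data_b is not None
        and data_a.experiment is not None and data_b.experiment is not None
    ):
        km_a = [f.K_M for f in fit_per_experiment(data_a)]
        km_b = [f.K_M for f in fit_per_experiment(data_b)]
        if len(km_a) >= 2 and len(km_b) >= 2:
            if np.ptp(km_a) == 0 and np.ptp(km_b) == 0 and km_a[0] == km_b[0]:
                t_stat, p_val = 0.0, 1.0  # identical constant samples
            else:
                t_stat, p_val = stats.ttest_ind(km_a, km_b, equal_var=True)
                t_stat, p_val = float(t_stat), float(p_val)
    return FitComparison(
        fold_change=float(fold), fold_is_lower_bound=bool(bound),
        t_statistic=t_stat, p_value=p_val, km_a=km_a, km_b=km_b,
    )
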