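"""Model evaluation: goodness-of-fit tables, CWRES outlier screening,
nonparametric bootstrap, and normalized prediction distribution errors.

The bootstrap resamples whole subjects (preserving within-subject
correlation) and warm-starts each refit from the point estimates.  NPDE
decorrelates observed and simulated vectors per subject with the Cholesky
factor of the empirical simulation covariance, converts mid-ranks to
standard-normal quantiles, and applies the three reference tests (t-test
for mean zero, a variance-one test, Shapiro–Wilk normality) with a
Bonferroni global decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.special import ndtri

from .foce_engine import FitResult, compile_dataset, fit, simulate_dv
from .pk_structural import PopModel
from .types import PopulationDataset, RunConfig

CWRES_BOUND = 6.0


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def gof_tables(fit_result: FitResult) -> pd.DataFrame:
    """Long-format diagnostic table: one row per observation with DV, PRED,
    IPRED, CWRES and time after dose; plotting layers consume this."""
    return fit_result.obs_table.copy()


def flag_outliers(fit_result: FitResult, bound: float = CWRES_BOUND) -> pd.DataFrame:
    """Observations with |CWRES| beyond the bound (rows of the GoF table)."""
    table = fit_result.obs_table
    return table[np.abs(table["CWRES"].to_numpy()) > bound].copy()


def save_gof_plots(fit_result: FitResult, path) -> None:
    """Four-panel scatter layout (DV–IPRED, DV–PRED, CWRES–PRED, CWRES–TAD)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = fit_result.obs_table
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    panels = [
        ("IPRED", "DV", axes[0, 0]),
        ("PRED", "DV", axes[0, 1]),
        ("PRED", "CWRES", axes[1, 0]),
        ("TAD", "CWRES", axes[1, 1]),
    ]
    for x, y, ax in panels:
        ax.plot(t[x], t[y], "o", ms=3, alpha=0.6)
        if y == "DV":
            lim = [0, max(t[x].max(), t[y].max()) * 1.05]
            ax.plot(lim, lim, "k-", lw=1)
        else:
            ax.axhline(0.0, color="k", lw=1)
        ax.set_xlabel(x)
        ax.set_ylabel(y)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapSummary:
    parameters: list
    point: dict  # name -> point estimate
    median: dict
    ci_low: dict  # 2.5th percentile
    ci_high: dict  # 97.5th percentile
    bias_percent: dict  # (median - estimate)/estimate * 100
    n_resamples: int
    n_success: int
    seed: int
    unreliable: bool = False
    samples: Optional[pd.DataFrame] = None

    @property
    def success_fraction(self) -> float:
        return self.n_success / self.n_resamples if self.n_resamples else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameters,
                "estimate": [self.point[p] for p in self.parameters],
                "median": [self.median[p] for p in self.parameters],
                "p2.5": [self.ci_low[p] for p in self.parameters],
                "p97.5": [self.ci_high[p] for p in self.parameters],
                "bias_percent": [self.bias_percent[p] for p in self.parameters],
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "n_resamples": self.n_resamples,
            "n_success": self.n_success,
            "success_fraction": self.success_fraction,
            "seed": self.seed,
            "unreliable": self.unreliable,
            "summary": self.to_frame().to_dict(orient="records"),
        }


def bootstrap(
    dataset: PopulationDataset,
    model: PopModel,
    n_resamples: int,
    seed: int,
    config: Optional[RunConfig] = None,
    residual_form: str = "proportional",
    point_fit: Optional[FitResult] = None,
) -> BootstrapSummary:
    """Subject-level nonparametric bootstrap of a model fit."""
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    if point_fit is None:
        point_fit = fit(dataset, model, residual_form=residual_form, config=config)

    names = list(point_fit.estimates.keys())
    point = dict(point_fit.estimates)
    n = dataset.n_subjects
    draws = {name: [] for name in names}
    n_success = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        resampled = dataset.subset(idx, relabel=True)
        try:
            fr = fit(
                resampled,
                model,
                residual_form=residual_form,
                config=config,
                x0_override=point_fit.x_hat,
                compute_se=False,
            )
        except Exception:
            continue
        if not np.isfinite(fr.ofv):
            continue
        n_success += 1
        for name in names:
            draws[name].append(fr.estimates[name])

    median, lo, hi, bias = {}, {}, {}, {}
    for name in names:
        arr = np.asarray(draws[name], dtype=float)
        if arr.size == 0:
            median[name] = lo[name] = hi[name] = bias[name] = float("nan")
            continue
        median[name] = float(np.median(arr))
        lo[name] = float(np.percentile(arr, 2.5))
        hi[name] = float(np.percentile(arr, 97.5))
        denom = point[name]
        bias[name] = float((median[name] - denom) / denom * 100.0) if denom else float("nan")
    return BootstrapSummary(
        parameters=names,
        point=point,
        median=median,
        ci_low=lo,
        ci_high=hi,
        bias_percent=bias,
        n_resamples=n_resamples,
        n_success=n_success,
        seed=seed,
        unreliable=(n_success < 0.5 * n_resamples),
        samples=pd.DataFrame(draws),
    )


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------


@dataclass
class NpdeSummary:
    npde: np.ndarray
    p_mean: float  # t-test, mean 0
    p_variance: float  # variance-one test
    p_normality: float  # Shapiro–Wilk
    alpha: float = 0.05
    n_sim: int = 0
    seed: int = 0

    @property
    def p_global(self) -> float:
        return min(1.0, 3.0 * min(self.p_mean, self.p_variance, self.p_normality))

    @property
    def rejected(self) -> bool:
        return self.p_global < self.alpha

    def to_json_dict(self) -> dict:
        return {
            "p_mean": self.p_mean,
            "p_variance": self.p_variance,
            "p_normality": self.p_normality,
            "p_global": self.p_global,
            "rejected": self.rejected,
            "alpha": self.alpha,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "npde_mean": float(np.mean(self.npde)),
            "npde_var": float(np.var(self.npde, ddof=1)),
        }


def _variance_one_pvalue(x: np.ndarray) -> float:
    """Two-sided test of Var = 1 via the scaled chi-square statistic."""
    n = len(x)
    s2 = np.var(x, ddof=1)
    stat = (n - 1) * s2
    p = 2.0 * min(stats.chi2.cdf(stat, n - 1), stats.chi2.sf(stat, n - 1))
    return float(min(p, 1.0))


def npde(
    dataset: PopulationDataset,
    fit_result: FitResult,
    n_sim: int = 1000,
    seed: int = 1,
    alpha: float = 0.05,
    observed: Optional[np.ndarray] = None,
) -> NpdeSummary:
    """Normalized prediction distribution errors under the fitted model.

    ``observed`` overrides the dataset's DV vector (used by calibration
    experiments that test simulated replicates against the same fit).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    compiled = compile_dataset(dataset, fit_result.model.covariate_names())
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, compiled.n_obs))
    for k in range(n_sim):
        sims[k] = simulate_dv(
            compiled,
            fit_result.model,
            fit_result.theta,
            fit_result.omega2_cl,
            fit_result.residual_spec,
            rng,
        )
    y = np.asarray(observed, dtype=float) if observed is not None else compiled.y

    npde_vals = np.empty(compiled.n_obs)
    eps = 1.0 / (2.0 * n_sim)
    for i in range(compiled.n_subjects):
        idx = compiled.subject_observation_indices(i)
        if idx.size == 0:
            continue
        S = sims[:, idx]
        m = S.mean(axis=0)
        cov = np.cov(S, rowvar=False)
        cov = np.atleast_2d(cov)
        ridge = 1e-10 * np.trace(cov) / cov.shape[0]
        for _ in range(8):
            try:
                L = np.linalg.cholesky(cov + ridge * np.eye(cov.shape[0]))
                break
            except np.linalg.LinAlgError:
                ridge *= 100.0
        yd = solve_triangular(L, y[idx] - m, lower=True)
        Sd = solve_triangular(L, (S - m).T, lower=True).T
        # mid-rank of the decorrelated observation among its simulations
        less = (Sd < yd).sum(axis=0)
        equal = (Sd == yd).sum(axis=0)
        pde = (less + 0.5 * equal + 0.5) / (n_sim + 1)
        pde = np.clip(pde, eps, 1.0 - eps)
        npde_vals[idx] = ndtri(pde)

    t_p = float(stats.ttest_1samp(npde_vals, 0.0).pvalue)
    v_p = _variance_one_pvalue(npde_vals)
    sw_p = float(stats.shapiro(npde_vals).pvalue)
    return NpdeSummary(
        npde=npde_vals,
        p_mean=t_p,
        p_variance=v_p,
        p_normality=sw_p,
        alpha=alpha,
        n_sim=n_sim,
        seed=seed,
    )
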