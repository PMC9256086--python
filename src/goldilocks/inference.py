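"""Regression and GAM analyses of gaze measures against surprisal.

The analysis asks whether attention follows the U-shaped (Goldilocks)
pattern: engagement highest — reactions fastest, look-aways rarest — at
intermediate surprisal. Concretely, for each ideal-observer model (unigram
or transitional), surprisal is standardized and entered as linear +
quadratic terms into mixed-effects regressions with a per-subject random
intercept:

* log RT          — linear mixed model (statsmodels ``MixedLM``),
* look-away       — random-intercept logistic model (adaptive Gauss-Hermite
  maximum likelihood, :mod:`goldilocks.mixed_logit`),
* predictive look — random-intercept logistic model with a *linear*
  surprisal term only, on first-appearance events.

A U shape appears as a negative linear plus positive quadratic coefficient.
"Raw" fits contain only the surprisal terms; "controlled" fits add repeat
status, the standardized inter-event pop-up distance, and standardized
trial number. p-values use the normal approximation to the Wald statistic
throughout.

Penalized-spline GAM smooths (statsmodels ``GLMGam``/``BSplines``, penalty
weight by generalized cross-validation) visualize the same relationships
without assuming the quadratic form, along with raw means of three evenly
spaced surprisal bins.

Rows with RT = 0 (gaze already on the box at onset, i.e. a predictive look)
are excluded from log-RT fits: the log transform is undefined at 0 and such
looks are anticipatory rather than reactive, and are analyzed separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from .mixed_logit import fit_mixed_logit

__all__ = [
    "RegressionSpec",
    "ModelFitResult",
    "GamFit",
    "standardize_surprisal",
    "fit_mixed_linear",
    "fit_mixed_logistic",
    "fit_gam",
    "run_analysis",
    "results_to_frame",
]

COVARIATES = ["is_repeat", "distance_z", "trial_z"]


@dataclass(frozen=True)
class RegressionSpec:
    outcome: str  # rt | lookaway | predictive
    model: str = "unigram"  # unigram | transitional
    controlled: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in ("rt", "lookaway", "predictive"):
            raise ValueError("outcome must be rt, lookaway or predictive")
        if self.model not in ("unigram", "transitional"):
            raise ValueError("model must be unigram or transitional")

    @property
    def quadratic(self) -> bool:
        # predictive-looking is modelled with a linear surprisal term only
        return self.outcome != "predictive"


@dataclass
class ModelFitResult:
    spec: RegressionSpec
    coefficients: pd.DataFrame  # term, estimate, se, statistic, p
    random_intercept_variance: float
    n_obs: int
    n_groups: int
    converged: bool
    method: str = ""
    message: str = ""

    def coef(self, term: str) -> pd.Series:
        return self.coefficients.set_index("term").loc[term]


@dataclass
class GamFit:
    outcome: str
    model: str
    controlled: bool
    grid: np.ndarray  # surprisal values (bits)
    mean: np.ndarray  # fitted mean on the response scale
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    se: np.ndarray  # pointwise SE on the response scale
    bin_centers: np.ndarray  # 3 evenly spaced surprisal bins
    bin_means: np.ndarray
    bin_sems: np.ndarray
    alpha: float  # selected penalty weight
    n_obs: int

    def interior_minimum(self, edge_frac: float = 0.05) -> float | None:
        """Location of the curve minimum if strictly inside the range."""
        i = int(np.argmin(self.mean))
        lo = self.grid[0] + edge_frac * (self.grid[-1] - self.grid[0])
        hi = self.grid[-1] - edge_frac * (self.grid[-1] - self.grid[0])
        x = float(self.grid[i])
        return x if lo < x < hi else None


def standardize_surprisal(
    table: pd.DataFrame,
    model: str = "unigram",
    scope: str = "included",
) -> pd.DataFrame:
    """Add ``z`` and ``z2`` columns (standardized surprisal and its square).

    ``scope`` picks the rows that define the standardization: "included"
    (default, the analysis convention — pooled over included rows across
    subjects) or "all" (every row, which matches the simulator's event-pool
    convention and is the right scale for parameter-recovery comparisons).
    """
    col = f"{model}_surprisal_bits"
    if col not in table.columns:
        raise ValueError(f"missing surprisal column {col}")
    if scope == "included":
        ref = table.loc[table["included"].astype(bool), col].to_numpy(dtype=float)
    elif scope == "all":
        ref = table[col].to_numpy(dtype=float)
    else:
        raise ValueError("scope must be 'included' or 'all'")
    if ref.size == 0:
        raise ValueError("no rows available to standardize over")
    mu, sd = ref.mean(), ref.std()
    if sd == 0:
        raise ValueError("surprisal column has zero variance")
    out = table.copy()
    out["z"] = (out[col].to_numpy(dtype=float) - mu) / sd
    out["z2"] = out["z"] ** 2
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _design(df: pd.DataFrame, spec: RegressionSpec) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Design matrix (with intercept) and term names; controlled fits drop
    rows without a previous event (distance undefined)."""
    if spec.controlled:
        df = df[df["distance_px"].notna()].copy()
        df["distance_z"] = _zscore(df["distance_px"].to_numpy(dtype=float))
        df["trial_z"] = _zscore(df["trial_number"].to_numpy(dtype=float))
    cols = [np.ones(len(df)), df["z"].to_numpy(dtype=float)]
    terms = ["intercept", "z"]
    if spec.quadratic:
        cols.append(df["z2"].to_numpy(dtype=float))
        terms.append("z2")
    if spec.controlled:
        cols.append(df["is_repeat"].to_numpy(dtype=float))
        cols.append(df["distance_z"].to_numpy(dtype=float))
        cols.append(df["trial_z"].to_numpy(dtype=float))
        terms += COVARIATES
    X = np.column_stack(cols)
    # a covariate can be constant on a sub-analysis (e.g. is_repeat on
    # first-appearance rows, which are never repeats): drop it rather than
    # hand the optimizer a singular design
    keep = [i for i in range(X.shape[1]) if i == 0 or X[:, i].std() > 0]
    return X[:, keep], [terms[i] for i in keep], df


def _coef_frame(terms: list[str], est: np.ndarray, se: np.ndarray) -> pd.DataFrame:
    stat = est / se
    p = 2 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame({"term": terms, "estimate": est, "se": se, "statistic": stat, "p": p})


def _analysis_rows(table: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    df = table[table["included"].astype(bool)]
    if spec.outcome == "rt":
        df = df[df["rt_ms"].notna()]
        df = df[df["rt_ms"].astype(float) > 0]  # predictive (RT=0) looks analyzed separately
    elif spec.outcome == "predictive":
        df = df[df["predictive_look"].notna()]
    return df.copy()


def fit_mixed_linear(table: pd.DataFrame, spec: RegressionSpec | None = None, **kw) -> ModelFitResult:
    """Linear mixed model of log RT with a subject random intercept."""
    spec = spec or RegressionSpec(outcome="rt", **kw)
    if spec.outcome != "rt":
        raise ValueError("fit_mixed_linear handles the rt outcome")
    df = _analysis_rows(table, spec)
    X, terms, df = _design(df, spec)
    if len(df) == 0:
        raise ValueError("no analyzable RT rows")
    y = np.log(df["rt_ms"].to_numpy(dtype=float))
    groups = df["subject_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    k = X.shape[1]
    est = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    return ModelFitResult(
        spec=spec,
        coefficients=_coef_frame(terms, est[:k], se[:k]),
        random_intercept_variance=float(np.asarray(res.cov_re)[0, 0]),
        n_obs=len(df),
        n_groups=df["subject_id"].nunique(),
        converged=bool(res.converged),
        method="MixedLM-REML",
    )


def fit_mixed_logistic(table: pd.DataFrame, spec: RegressionSpec | None = None, **kw) -> ModelFitResult:
    """Random-intercept logistic model for look-away or predictive-looking.

    Fitted by adaptive Gauss-Hermite maximum likelihood; if that fails, a
    cluster-robust ordinary logistic fit is reported and flagged
    (``converged=False``, ``method="GLM-cluster-robust"``). A degenerate
    outcome (all 0 or all 1) yields an empty, flagged result.
    """
    spec = spec or RegressionSpec(**kw)
    if spec.outcome not in ("lookaway", "predictive"):
        raise ValueError("fit_mixed_logistic handles lookaway or predictive outcomes")
    df = _analysis_rows(table, spec)
    X, terms, df = _design(df, spec)
    ycol = "look_away" if spec.outcome == "lookaway" else "predictive_look"
    y = df[ycol].to_numpy(dtype=float)
    groups = df["subject_id"].to_numpy()
    n_groups = df["subject_id"].nunique()
    if len(y) == 0 or y.sum() == 0 or y.sum() == len(y):
        return ModelFitResult(
            spec=spec,
            coefficients=_coef_frame(terms, np.full(len(terms), np.nan), np.full(len(terms), np.nan)),
            random_intercept_variance=np.nan,
            n_obs=len(y),
            n_groups=n_groups,
            converged=False,
            method="degenerate",
            message="outcome constant: no information for a logistic fit",
        )
    try:
        res = fit_mixed_logit(y, X, groups)
        if res.converged:
            return ModelFitResult(
                spec=spec,
                coefficients=_coef_frame(terms, res.params, res.bse),
                random_intercept_variance=res.random_intercept_variance,
                n_obs=res.n_obs,
                n_groups=res.n_groups,
                converged=True,
                method="AGQ-ML",
            )
        message = res.message
    except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover - fallback path
        message = str(exc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        res2 = glm.fit(cov_type="cluster", cov_kwds={"groups": groups})
    return ModelFitResult(
        spec=spec,
        coefficients=_coef_frame(terms, np.asarray(res2.params), np.asarray(res2.bse)),
        random_intercept_variance=0.0,
        n_obs=len(y),
        n_groups=n_groups,
        converged=False,
        method="GLM-cluster-robust",
        message=f"AGQ fit failed ({message}); cluster-robust logistic fallback",
    )


def fit_gam(
    table: pd.DataFrame,
    spec: RegressionSpec | None = None,
    df_spline: int = 10,
    n_grid: int = 100,
    min_rows: int = 50,
    **kw,
) -> GamFit:
    """Penalized-spline smooth of an outcome against raw surprisal (bits).

    Identity link for log RT, logit link for the binary outcomes; the
    penalty weight is chosen by GCV. Controlled variants add the covariates
    as linear terms. Returns the fitted curve with pointwise 95% band and
    SEs (both on the response scale) plus raw means of three evenly spaced
    surprisal bins.
    """
    spec = spec or RegressionSpec(**kw)
    df = _analysis_rows(table, spec)
    scol = f"{spec.model}_surprisal_bits"
    if spec.controlled:
        df = df[df["distance_px"].notna()].copy()
        df["distance_z"] = _zscore(df["distance_px"].to_numpy(dtype=float))
        df["trial_z"] = _zscore(df["trial_number"].to_numpy(dtype=float))
    if len(df) < min_rows:
        raise ValueError(f"need at least {min_rows} rows for a GAM fit, got {len(df)}")
    x = df[scol].to_numpy(dtype=float)
    if spec.outcome == "rt":
        y = np.log(df["rt_ms"].to_numpy(dtype=float))
        family = sm.families.Gaussian()
    else:
        ycol = "look_away" if spec.outcome == "lookaway" else "predictive_look"
        y = df[ycol].to_numpy(dtype=float)
        family = sm.families.Binomial()
    if spec.controlled:
        exog = np.column_stack(
            [
                np.ones(len(df)),
                df["is_repeat"].to_numpy(dtype=float),
                df["distance_z"].to_numpy(dtype=float),
                df["trial_z"].to_numpy(dtype=float),
            ]
        )
    else:
        exog = np.ones((len(df), 1))
    smoother = BSplines(x[:, None], df=[df_spline], degree=[3])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gam = GLMGam(y, exog=exog, smoother=smoother, alpha=[1.0], family=family)
        gam.fit()  # select_penweight needs a prior fit on the same object
        # GCV is the gaussian criterion; its statsmodels implementation
        # degenerates under a binomial family, where AIC is the standard choice
        criterion = "gcv" if spec.outcome == "rt" else "aic"
        try:
            alpha_opt = np.atleast_1d(gam.select_penweight(criterion=criterion)[0])
        except Exception:
            alpha_opt = np.array([1.0])
        res = GLMGam(y, exog=exog, smoother=smoother, alpha=alpha_opt, family=family).fit()
    grid = np.linspace(x.min(), x.max(), n_grid)
    basis = smoother.transform(grid[:, None])
    # covariates held at their means (is_repeat at its observed rate)
    exog_grid = np.tile(exog.mean(axis=0), (n_grid, 1))
    Xg = np.column_stack([exog_grid, basis])
    eta = Xg @ res.params
    C = res.cov_params()
    se_eta = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", Xg, C, Xg), 0, None))
    link = family.link
    mean = link.inverse(eta)
    lo = link.inverse(eta - 1.96 * se_eta)
    hi = link.inverse(eta + 1.96 * se_eta)
    se_resp = np.abs(link.inverse(eta + se_eta) - link.inverse(eta - se_eta)) / 2
    edges = np.linspace(x.min(), x.max(), 4)
    bin_idx = np.clip(np.digitize(x, edges[1:-1]), 0, 2)
    centers = (edges[:-1] + edges[1:]) / 2
    means = np.array([y[bin_idx == b].mean() if np.any(bin_idx == b) else np.nan for b in range(3)])
    sems = np.array(
        [
            y[bin_idx == b].std(ddof=1) / np.sqrt((bin_idx == b).sum()) if (bin_idx == b).sum() > 1 else np.nan
            for b in range(3)
        ]
    )
    return GamFit(
        outcome=spec.outcome,
        model=spec.model,
        controlled=spec.controlled,
        grid=grid,
        mean=np.asarray(mean),
        ci_lower=np.asarray(lo),
        ci_upper=np.asarray(hi),
        se=np.asarray(se_resp),
        bin_centers=centers,
        bin_means=means,
        bin_sems=sems,
        alpha=float(np.atleast_1d(alpha_opt)[0]),
        n_obs=len(df),
    )


def run_analysis(
    event_table: pd.DataFrame,
    scope: str = "included",
    with_gams: bool = True,
    out_dir=None,
    make_figures: bool = False,
) -> dict:
    """All 12 regression fits (3 outcomes x 2 models x raw/controlled) + GAMs.

    Per-fit errors are collected, never raised, so one failing combination
    cannot abort the bundle. Returns ``{"fits": {...}, "gams": {...},
    "errors": {...}}`` keyed by (outcome, model, controlled).
    """
    if len(event_table) == 0:
        raise ValueError("empty event table")
    fits: dict = {}
    gams: dict = {}
    errors: dict = {}
    for model in ("unigram", "transitional"):
        tab = standardize_surprisal(event_table, model=model, scope=scope)
        for outcome in ("rt", "lookaway", "predictive"):
            for controlled in (False, True):
                key = (outcome, model, controlled)
                spec = RegressionSpec(outcome=outcome, model=model, controlled=controlled)
                try:
                    if outcome == "rt":
                        fits[key] = fit_mixed_linear(tab, spec)
                    else:
                        fits[key] = fit_mixed_logistic(tab, spec)
                except Exception as exc:
                    errors[key] = str(exc)
                if with_gams:
                    try:
                        gams[key] = fit_gam(tab, spec)
                    except Exception as exc:
                        errors[("gam",) + key] = str(exc)
    bundle = {"fits": fits, "gams": gams, "errors": errors}
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results_to_frame(fits).to_csv(out / "coefficients.csv", index=False)
        if make_figures and gams:
            _write_figures(gams, out)
    return bundle


def results_to_frame(fits: dict) -> pd.DataFrame:
    rows = []
    for (outcome, model, controlled), res in fits.items():
        for _, row in res.coefficients.iterrows():
            rows.append(
                {
                    "outcome": outcome,
                    "model": model,
                    "controlled": controlled,
                    "term": row["term"],
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "statistic": row["statistic"],
                    "p": row["p"],
                    "n_obs": res.n_obs,
                    "n_groups": res.n_groups,
                    "random_intercept_variance": res.random_intercept_variance,
                    "converged": res.converged,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)


def _write_figures(gams: dict, out_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (outcome, model, controlled), gf in gams.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.fill_between(gf.grid, gf.ci_lower, gf.ci_upper, alpha=0.25, lw=0)
        ax.plot(gf.grid, gf.mean, lw=2)
        ax.errorbar(gf.bin_centers, gf.bin_means, yerr=gf.bin_sems, fmt="o", color="k", capsize=3)
        label = {"rt": "log RT", "lookaway": "P(look-away)", "predictive": "P(predictive look)"}[outcome]
        ax.set_xlabel(f"{model} surprisal (bits)")
        ax.set_ylabel(label)
        ax.set_title(f"{outcome} ~ s({model}){' + covariates' if controlled else ''}")
        fig.tight_layout()
        tag = "controlled" if controlled else "raw"
        fig.savefig(f"{out_dir}/gam_{outcome}_{model}_{tag}.png", dpi=120)
        plt.close(fig)
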