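"""Species-distribution modelling of site persistence.

The response is the number of survey months with at least one detection at
a site (0-36 annually; 0-9 for the three January-March winters), treated
as a binomial count.  Covariates are landscape summaries in a buffer
around each site; the buffer radius that best explains persistence (the
scale of effect) is chosen by AIC weight across radii.  Models are
binomial GLMs (logit link) fitted by IRLS via statsmodels, reduced by
backward stepwise-AIC, optionally pruned post hoc by Wald p-value, and
checked with deviance explained, overdispersion, k-fold cross-validation
and Moran's I of residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .landscape import SiteCovariateTable
from .occupancy import ModelRanking
from .survey import DetectionHistory, SurveyDesign

__all__ = [
    "PersistenceResponse",
    "PreparedCovariates",
    "PersistenceModel",
    "PersistenceResults",
    "ScaleScanResult",
    "DiagnosticsReport",
    "prepare_covariates",
    "fit_binomial_glm",
    "stepwise_reduce",
    "scan_scales",
    "rank_candidate_models",
    "prune_by_pvalue",
    "diagnostics",
    "deviance_explained",
    "morans_i",
]


@dataclass
class PersistenceResponse:
    """Per-site successes (months with a detection) out of surveyed months."""

    site_ids: list[str]
    successes: np.ndarray
    trials: np.ndarray
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.successes = np.asarray(self.successes, dtype=float)
        self.trials = np.asarray(self.trials, dtype=float)
        if np.any(self.successes < 0) or np.any(self.successes > self.trials):
            raise ValueError("need 0 <= successes <= trials")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @classmethod
    def from_history(
        cls,
        history: DetectionHistory,
        design: SurveyDesign | None = None,
        winter_only: bool = False,
    ) -> "PersistenceResponse":
        """Collapse a detection history to per-site counts.

        ``winter_only`` restricts to the January-March seasons (0-9 response
        over three study winters rather than 0-36).
        """
        if winter_only:
            if design is None:
                raise ValueError("winter_only requires the survey design")
            m = history.winter_columns(design)
        else:
            m = history.matrix
        return cls(
            site_ids=list(history.site_ids),
            successes=np.nansum(m, axis=1),
            trials=np.sum(~np.isnan(m), axis=1).astype(float),
            coordinates=history.coordinates.copy(),
        )


@dataclass
class PreparedCovariates:
    """Standardized covariate matrix at one radius, after sparse-combining
    and correlation pruning."""

    X: pd.DataFrame  # sites x retained variables, mean 0 / sd 1
    radius_m: float
    scaling: pd.DataFrame  # variable, mean, sd
    dropped_correlated: list[tuple[str, str, float]]  # (dropped, kept, |r|)
    combined_members: list[str]
    dropped_zero_variance: list[str] = field(default_factory=list)


def prepare_covariates(
    table: SiteCovariateTable,
    radius: float,
    r_max: float = 0.7,
    sparse_cutoff_pct: float = 2.0,
    combined_name: str = "combined_sparse",
) -> PreparedCovariates:
    """Sparse-combine, correlation-prune and standardize covariates.

    Percent-cover variables whose landscape-wide mean cover is below
    ``sparse_cutoff_pct`` are summed into a single combination variable.
    Then, while any retained pair has |r| > ``r_max``, the member of the
    worst pair with the larger mean |r| to all other variables is dropped.
    Survivors are rescaled to mean 0, sd 1 so effect sizes are comparable.
    """
    wide = table.wide(radius)
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    sparse = [
        v
        for v in wide.columns
        if table.kinds.get(v, "percent") == "percent" and wide[v].mean() < sparse_cutoff_pct
    ]
    combined = []
    if sparse:
        wide = wide.copy()
        wide[combined_name] = wide[sparse].sum(axis=1)
        wide = wide.drop(columns=sparse)
        combined = sparse

    zero_var = [v for v in wide.columns if wide[v].std(ddof=1) == 0 or wide[v].isna().any()]
    if zero_var:
        warnings.warn(f"dropping zero-variance covariates at {radius:.0f} m: {zero_var}", stacklevel=2)
        wide = wide.drop(columns=zero_var)
    if wide.shape[1] == 0:
        raise ValueError(f"no usable covariates at radius {radius}")

    dropped: list[tuple[str, str, float]] = []
    while wide.shape[1] > 1:
        corr = wide.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst <= r_max:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.columns[i], corr.columns[j]
        # drop the member with larger mean |r| to everything else
        loser, keeper = (a, b) if corr[a].mean() >= corr[b].mean() else (b, a)
        dropped.append((loser, keeper, float(worst)))
        wide = wide.drop(columns=loser)

    mu = wide.mean()
    sd = wide.std(ddof=1)
    X = (wide - mu) / sd
    scaling = pd.DataFrame({"variable": wide.columns, "mean": mu.values, "sd": sd.values})
    return PreparedCovariates(
        X=X,
        radius_m=float(radius),
        scaling=scaling,
        dropped_correlated=dropped,
        combined_members=combined,
        dropped_zero_variance=zero_var,
    )


class PersistenceModel:
    """Binomial GLM (logit link) of persistence counts on landscape terms."""

    def __init__(
        self,
        response: PersistenceResponse,
        covariates: PreparedCovariates | pd.DataFrame,
        terms: list[str] | None = None,
    ):
        X = covariates.X if isinstance(covariates, PreparedCovariates) else covariates
        if isinstance(covariates, PreparedCovariates):
            # align covariate rows to the response's site order
            X = X.reindex([str(s) for s in response.site_ids])
            if X.isna().any().any():
                missing = [s for s in response.site_ids if str(s) not in covariates.X.index]
                raise ValueError(f"covariates missing for sites: {missing}")
        self.response = response
        self.X = X.reset_index(drop=True)
        self.terms = list(self.X.columns) if terms is None else list(terms)
        unknown = [t for t in self.terms if t not in self.X.columns]
        if unknown:
            raise KeyError(f"unknown model terms: {unknown}")
        if response.n_sites <= len(self.terms) + 1:
            raise ValueError("more terms than sites can support")

    def fit(self) -> "PersistenceResults":
        endog = np.column_stack(
            [self.response.successes, self.response.trials - self.response.successes]
        )
        exog = sm.add_constant(self.X[self.terms].to_numpy(), has_constant="add")
        glm = sm.GLM(endog, exog, family=sm.families.Binomial())
        flagged = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = glm.fit()
            except Exception as exc:  # perfect separation and friends
                raise RuntimeError(f"binomial GLM failed: {exc}") from exc
            # materialise lazily evaluated statistics while warnings are caught
            with np.errstate(all="ignore"):
                _ = res.aic, res.bse, res.pvalues, res.null_deviance, res.pearson_chi2
        if any("separation" in str(w.message).lower() for w in caught):
            flagged = True
        if not getattr(res, "converged", True):
            flagged = True
        return PersistenceResults(model=self, _sm=res, flagged=flagged)


@dataclass
class PersistenceResults:
    """Fitted binomial GLM with Wald inference and deviance accounting.

    The per-term statistic is the Wald z (estimate / SE) referred to the
    standard normal — the quantity GLM software prints in the t-value
    column for binomial families.
    """

    model: PersistenceModel
    _sm: object
    flagged: bool = False

    @property
    def term_names(self) -> list[str]:
        return ["(Intercept)"] + self.model.terms

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self._sm.params)

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._sm.bse)

    @property
    def tvalues(self) -> np.ndarray:
        return np.asarray(self._sm.tvalues)

    @property
    def pvalues(self) -> np.ndarray:
        return np.asarray(self._sm.pvalues)

    @property
    def aic(self) -> float:
        return float(self._sm.aic)

    @property
    def k_params(self) -> int:
        return len(self.term_names)

    @property
    def null_deviance(self) -> float:
        return float(self._sm.null_deviance)

    @property
    def null_df(self) -> int:
        return self.model.response.n_sites - 1

    @property
    def deviance(self) -> float:
        return float(self._sm.deviance)

    @property
    def df_resid(self) -> int:
        return int(self._sm.df_resid)

    @property
    def fitted_probs(self) -> np.ndarray:
        return np.asarray(self._sm.fittedvalues)

    @property
    def resid_response(self) -> np.ndarray:
        """Observed minus fitted detection proportion per site."""
        obs = self.model.response.successes / self.model.response.trials
        return obs - self.fitted_probs

    def predict_probs(self, X: pd.DataFrame) -> np.ndarray:
        exog = sm.add_constant(X[self.model.terms].to_numpy(), has_constant="add")
        return np.asarray(self._sm.predict(exog))

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_names,
                "beta": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def refit(self, terms: list[str]) -> "PersistenceResults":
        return PersistenceModel(self.model.response, self.model.X, terms).fit()

    def summary(self) -> str:
        lines = [
            "Binomial GLM of site persistence (logit link)",
            f"  sites: {self.model.response.n_sites}"
            f"   trials/site: {int(self.model.response.trials.max())}"
            f"   AIC: {self.aic:.2f}" + ("   [flagged]" if self.flagged else ""),
            f"  null deviance {self.null_deviance:.2f} on {self.null_df} df; "
            f"residual deviance {self.deviance:.2f} on {self.df_resid} df",
            f"  deviance explained: {100 * deviance_explained(self.null_deviance, self.deviance):.1f}%",
            "",
            f"  {'term':<26}{'beta':>9}{'SE':>8}{'t':>8}{'p':>9}",
        ]
        for _, r in self.coefficients().iterrows():
            lines.append(
                f"  {r['term']:<26}{r['beta']:9.2f}{r['se']:8.2f}{r['t']:8.2f}{r['p']:9.4f}"
            )
        return "\n".join(lines)


def fit_binomial_glm(
    response: PersistenceResponse,
    covariates: PreparedCovariates | pd.DataFrame,
    terms: list[str] | None = None,
) -> PersistenceResults:
    """Fit successes/trials on an intercept plus ``terms`` by IRLS."""
    return PersistenceModel(response, covariates, terms).fit()


def stepwise_reduce(fit: PersistenceResults) -> PersistenceResults:
    """Backward stepwise-AIC: drop single terms while AIC improves."""
    best = fit
    while best.model.terms:
        candidates = []
        for t in best.model.terms:
            reduced = best.refit([x for x in best.model.terms if x != t])
            candidates.append(reduced)
        challenger = min(candidates, key=lambda r: r.aic)
        if challenger.aic < best.aic:
            best = challenger
        else:
            break
    return best


def prune_by_pvalue(fit: PersistenceResults, alpha: float = 0.2) -> PersistenceResults:
    """Post hoc parsimony: iteratively drop the worst term with p > alpha."""
    best = fit
    while best.model.terms:
        pv = pd.Series(best.pvalues[1:], index=best.model.terms)  # skip intercept
        worst = pv.idxmax()
        if pv[worst] <= alpha:
            break
        best = best.refit([t for t in best.model.terms if t != worst])
    if not best.model.terms:
        warnings.warn("all terms pruned; returning intercept-only model", stacklevel=2)
    return best


@dataclass
class ScaleScanResult:
    """AIC-weight profile of the reduced model across buffer radii."""

    table: pd.DataFrame  # radius_m, aic, weight, n_terms
    winning_radius: float
    reduced_fits: dict[float, PersistenceResults] = field(default_factory=dict)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        ax.plot(self.table["radius_m"], self.table["weight"], marker="o", color="k")
        ax.axvline(self.winning_radius, ls="--", color="grey")
        ax.set_xlabel("buffer radius (m)")
        ax.set_ylabel("AIC weight")
        return ax


def scan_scales(
    response: PersistenceResponse,
    table: SiteCovariateTable,
    radii=None,
    r_max: float = 0.7,
    sparse_cutoff_pct: float = 2.0,
) -> ScaleScanResult:
    """Find the scale of effect: per radius, fit the full model, reduce it
    by stepwise-AIC, then normalise AIC weights across radii."""
    radii = table.radii() if radii is None else np.asarray(radii, dtype=float)
    if radii.size < 2:
        raise ValueError("need at least two radii to compare scales")
    rows = []
    fits: dict[float, PersistenceResults] = {}
    for r in radii:
        try:
            prep = prepare_covariates(table, r, r_max=r_max, sparse_cutoff_pct=sparse_cutoff_pct)
        except ValueError as exc:
            warnings.warn(f"radius {r:.0f} m excluded: {exc}", stacklevel=2)
            continue
        reduced = stepwise_reduce(fit_binomial_glm(response, prep))
        fits[float(r)] = reduced
        rows.append((float(r), reduced.aic, len(reduced.model.terms)))
    if not rows:
        raise ValueError("no radius yielded a usable model")
    df = pd.DataFrame(rows, columns=["radius_m", "aic", "n_terms"])
    delta = df["aic"] - df["aic"].min()
    w = np.exp(-delta / 2.0)
    df["weight"] = w / w.sum()
    winner = float(df.loc[df["weight"].idxmax(), "radius_m"])
    return ScaleScanResult(table=df, winning_radius=winner, reduced_fits=fits)


def rank_candidate_models(
    response: PersistenceResponse,
    prepared: PreparedCovariates,
    model_specs: dict[str, list[str]],
) -> tuple[ModelRanking, dict[str, PersistenceResults]]:
    """AIC-rank a named candidate set of term subsets at one radius."""
    if not model_specs:
        raise ValueError("need at least one candidate model")
    fits = {}
    for name, terms in model_specs.items():
        unknown = [t for t in terms if t not in prepared.X.columns]
        if unknown:
            raise KeyError(f"candidate model {name!r} references unknown terms {unknown}")
        fits[name] = fit_binomial_glm(response, prepared, terms)
    aics = np.array([fits[n].aic for n in model_specs])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    tab = pd.DataFrame(
        {
            "model": list(model_specs),
            "K": [fits[n].k_params for n in model_specs],
            "aic": aics,
            "delta_aic": delta,
            "weight": w,
        }
    ).sort_values("aic", kind="stable", ignore_index=True)
    return ModelRanking(table=tab), fits


def deviance_explained(null_deviance: float, residual_deviance: float) -> float:
    """Fraction of the null deviance explained, 1 - D_res / D_null."""
    if null_deviance < -1e-8:
        raise ValueError("null deviance must be non-negative")
    if null_deviance <= 1e-12:
        return 0.0  # constant response: nothing to explain
    return 1.0 - residual_deviance / null_deviance


def morans_i(
    values: np.ndarray,
    coords: np.ndarray,
    permutations: int = 0,
    seed: int | None = None,
) -> dict:
    """Moran's I with inverse-distance weights w_ij = 1/d_ij.

    Returns I, its null expectation -1/(n-1), the standard deviation under
    the normality assumption and a two-sided normal p-value; optionally a
    permutation p-value from ``permutations`` random relabellings.
    """
    from scipy.spatial.distance import squareform, pdist
    from scipy.stats import norm

    z = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 sites")
    d = squareform(pdist(coords))
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident sites (zero distance) not allowed")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]

    zc = z - z.mean()
    s0 = w.sum()
    num = float(zc @ w @ zc)
    den = float(zc @ zc)
    if den == 0.0:
        # constant values: autocorrelation undefined
        return {"I": np.nan, "expected": -1.0 / (n - 1), "sd": np.nan, "p": np.nan}
    I = (n / s0) * (num / den)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / ((n * n - 1.0) * s0 * s0) - e_i * e_i
    sd = float(np.sqrt(var))
    p = float(2.0 * norm.sf(abs((I - e_i) / sd)))
    out = {"I": I, "expected": e_i, "sd": sd, "p": p}
    if permutations:
        rng = np.random.default_rng(seed)
        ref = abs(I - e_i)
        hits = 0
        for _ in range(permutations):
            zp = zc[rng.permutation(n)]
            Ip = (n / s0) * float(zp @ w @ zp) / den
            if abs(Ip - e_i) >= ref - 1e-15:
                hits += 1
        out["p_perm"] = (hits + 1.0) / (permutations + 1.0)
    return out


@dataclass
class DiagnosticsReport:
    """Model-adequacy summary for a fitted persistence GLM."""

    deviance_explained: float
    dispersion: float  # Pearson chi^2 / residual df
    cv_error: float  # k-fold MSE on the proportion scale
    cv_k: int
    cv_seed: int | None
    moran: dict

    def to_dict(self) -> dict:
        return {
            "deviance_explained": self.deviance_explained,
            "dispersion": self.dispersion,
            "cv_error": self.cv_error,
            "cv_k": self.cv_k,
            "cv_seed": self.cv_seed,
            "moran": self.moran,
        }


def diagnostics(
    fit: PersistenceResults,
    response: PersistenceResponse | None = None,
    coords: np.ndarray | None = None,
    k: int = 10,
    seed: int | None = None,
    moran_permutations: int = 0,
) -> DiagnosticsReport:
    """Deviance explained, overdispersion, k-fold CV error and Moran's I.

    CV error is the mean squared difference between held-out observed
    detection proportions and predicted probabilities, over a seeded random
    k-fold partition of sites.
    """
    response = response or fit.model.response
    coords = response.coordinates if coords is None else np.asarray(coords, dtype=float)
    if coords is None:
        raise ValueError("site coordinates required for Moran's I")
    n = response.n_sites
    if k > n:
        raise ValueError(f"k={k} folds exceed {n} sites")

    dev_expl = deviance_explained(fit.null_deviance, fit.deviance)
    pearson = float(fit._sm.pearson_chi2) / fit.df_resid

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    obs = response.successes / response.trials
    sq_errs = np.empty(n)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        sub_resp = PersistenceResponse(
            site_ids=[response.site_ids[i] for i in train],
            successes=response.successes[train],
            trials=response.trials[train],
        )
        sub_X = fit.model.X.iloc[train]
        sub_fit = PersistenceModel(sub_resp, sub_X, fit.model.terms).fit()
        pred = sub_fit.predict_probs(fit.model.X.iloc[fold])
        sq_errs[fold] = (obs[fold] - pred) ** 2
    cv_error = float(sq_errs.mean())

    moran = morans_i(fit.resid_response, coords, permutations=moran_permutations, seed=seed)
    return DiagnosticsReport(
        deviance_explained=dev_expl,
        dispersion=pearson,
        cv_error=cv_error,
        cv_k=k,
        cv_seed=seed,
        moran=moran,
    )
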