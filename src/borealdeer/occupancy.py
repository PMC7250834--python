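"""Multi-season (dynamic) occupancy models for detection-nondetection data.

The model is a two-state hidden Markov chain per site.  A site starts
occupied with probability ``psi1``; between consecutive primary seasons an
occupied site goes extinct with probability ``epsilon_t`` and an empty site
is colonized with probability ``gamma_t``.  Within a season, each secondary
survey is a Bernoulli trial with detection probability ``p_tj`` given
occupancy, and detections are impossible at unoccupied sites.  The
likelihood is computed by the forward algorithm over the latent chain;
missing surveys simply drop their Bernoulli factor.

Because seasonal occupancy of this vagile ungulate is interpreted as site
*use*, the within-season closure assumption is relaxed in interpretation
only: zeros in a season at a used site reflect movement in and out of the
camera's detection zone, absorbed by ``p``.

Parameters are estimated by maximum likelihood on the logit scale
(:class:`DynamicOccupancyModel`), with AIC-based ranking of competing
parameter structures and derived per-season quantities: occupancy
``psi_t``, spatial growth rate ``lambda_t = psi_{t+1}/psi_t`` and the
probability of false absence ``PFA_t = prod_j (1 - p_tj)``.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, xlogy
from statsmodels.tools.numdiff import approx_hess2

from .survey import DetectionHistory, SurveyDesign

__all__ = [
    "OccupancyModelSpec",
    "OccupancyParams",
    "DynamicOccupancyModel",
    "DynamicOccupancyResults",
    "DerivedTrajectory",
    "ModelRanking",
    "negative_log_likelihood",
    "brute_force_site_likelihood",
    "fit_occupancy",
    "derive_trajectory",
    "rank_models_aic",
    "default_candidate_specs",
]

#: Hard clamp on logit-scale parameters; expit(15) ~ 1 - 3e-7.
LOGIT_CLAMP = 15.0
#: |logit| beyond which an estimate is treated as a boundary estimate.
BOUNDARY_LOGIT = 10.0

_EPS_STRUCTURES = ("constant", "by-season")
_P_STRUCTURES = ("constant", "by-season", "by-survey")


@dataclass(frozen=True)
class OccupancyModelSpec:
    """Which parameters are constant vs varying over seasons/surveys."""

    epsilon: str = "constant"
    gamma: str = "constant"
    p: str = "constant"

    def __post_init__(self) -> None:
        if self.epsilon not in _EPS_STRUCTURES:
            raise ValueError(f"epsilon structure must be one of {_EPS_STRUCTURES}")
        if self.gamma not in _EPS_STRUCTURES:
            raise ValueError(f"gamma structure must be one of {_EPS_STRUCTURES}")
        if self.p not in _P_STRUCTURES:
            raise ValueError(f"p structure must be one of {_P_STRUCTURES}")

    def n_params(self, design: SurveyDesign) -> int:
        """Number of free parameters K for this structure."""
        T, J = design.n_seasons, design.surveys_per_season
        k = 1  # psi1
        if T > 1:
            k += (T - 1) if self.epsilon == "by-season" else 1
            k += (T - 1) if self.gamma == "by-season" else 1
        k += {"constant": 1, "by-season": T, "by-survey": T * J}[self.p]
        return k

    def param_names(self, design: SurveyDesign) -> list[str]:
        T, J = design.n_seasons, design.surveys_per_season
        names = ["psi1"]
        if T > 1:
            if self.epsilon == "by-season":
                names += [f"epsilon[{t + 1}->{t + 2}]" for t in range(T - 1)]
            else:
                names += ["epsilon"]
            if self.gamma == "by-season":
                names += [f"gamma[{t + 1}->{t + 2}]" for t in range(T - 1)]
            else:
                names += ["gamma"]
        if self.p == "by-survey":
            names += [f"p[{t + 1},{j + 1}]" for t in range(T) for j in range(J)]
        elif self.p == "by-season":
            names += [f"p[{t + 1}]" for t in range(T)]
        else:
            names += ["p"]
        return names

    def label(self) -> str:
        def s(x):
            return {"constant": ".", "by-season": "t", "by-survey": "t,j"}[x]

        return f"psi1, eps({s(self.epsilon)}), gam({s(self.gamma)}), p({s(self.p)})"


@dataclass
class OccupancyParams:
    """Full parameter set on the probability scale.

    ``epsilon`` and ``gamma`` have length ``n_seasons - 1`` (transition t ->
    t+1); ``p`` is (n_seasons, surveys_per_season).
    """

    psi1: float
    epsilon: np.ndarray
    gamma: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.epsilon = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.p = np.atleast_2d(np.asarray(self.p, dtype=float))
        for name, arr in (
            ("psi1", np.array([self.psi1])),
            ("epsilon", self.epsilon),
            ("gamma", self.gamma),
            ("p", self.p),
        ):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} outside [0, 1]")

    def validate_against(self, design: SurveyDesign) -> None:
        T, J = design.n_seasons, design.surveys_per_season
        if self.epsilon.shape != (max(T - 1, 1),) and self.epsilon.shape != (T - 1,):
            if T > 1 or self.epsilon.size != 1:
                raise ValueError(f"epsilon must have length {T - 1}")
        if T > 1 and (self.epsilon.shape != (T - 1,) or self.gamma.shape != (T - 1,)):
            raise ValueError(f"epsilon/gamma must have length {T - 1}")
        if self.p.shape != (T, J):
            raise ValueError(f"p must have shape {(T, J)}")


# ---------------------------------------------------------------------------
# parameter packing: free logit-scale vector <-> full probability arrays


def _expand(theta: np.ndarray, spec: OccupancyModelSpec, design: SurveyDesign):
    """Free logit vector -> (psi1, epsilon[T-1], gamma[T-1], p[T,J]) probs."""
    T, J = design.n_seasons, design.surveys_per_season
    th = np.clip(np.asarray(theta, dtype=float), -LOGIT_CLAMP, LOGIT_CLAMP)
    pos = 0

    psi1 = expit(th[pos])
    pos += 1
    if T > 1:
        ne = (T - 1) if spec.epsilon == "by-season" else 1
        eps = expit(th[pos : pos + ne])
        eps = eps if ne == T - 1 else np.repeat(eps, T - 1)
        pos += ne
        ng = (T - 1) if spec.gamma == "by-season" else 1
        gam = expit(th[pos : pos + ng])
        gam = gam if ng == T - 1 else np.repeat(gam, T - 1)
        pos += ng
    else:
        eps = np.zeros(0)
        gam = np.zeros(0)
    np_ = {"constant": 1, "by-season": T, "by-survey": T * J}[spec.p]
    praw = expit(th[pos : pos + np_])
    pos += np_
    if spec.p == "constant":
        p = np.full((T, J), praw[0])
    elif spec.p == "by-season":
        p = np.repeat(praw[:, None], J, axis=1)
    else:
        p = praw.reshape(T, J)
    if pos != th.size:
        raise ValueError(f"theta has {th.size} entries, spec needs {pos}")
    return psi1, eps, gam, p


def _pack(params: OccupancyParams, spec: OccupancyModelSpec, design: SurveyDesign) -> np.ndarray:
    """Full probability arrays -> free logit vector (inverse of _expand)."""
    params.validate_against(design)
    T, J = design.n_seasons, design.surveys_per_season

    def lg(x):
        return np.clip(logit(np.clip(x, 1e-12, 1 - 1e-12)), -LOGIT_CLAMP, LOGIT_CLAMP)

    parts = [np.atleast_1d(lg(params.psi1))]
    if T > 1:
        parts.append(lg(params.epsilon) if spec.epsilon == "by-season" else np.atleast_1d(lg(params.epsilon[0])))
        parts.append(lg(params.gamma) if spec.gamma == "by-season" else np.atleast_1d(lg(params.gamma[0])))
    if spec.p == "by-survey":
        parts.append(lg(params.p).ravel())
    elif spec.p == "by-season":
        parts.append(lg(params.p[:, 0]))
    else:
        parts.append(np.atleast_1d(lg(params.p[0, 0])))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# likelihood


class _LikelihoodData:
    """History collapsed to unique site rows with multiplicities."""

    def __init__(self, history: DetectionHistory, design: SurveyDesign):
        v = history.season_view(design)  # (n, T, J)
        flat = history.matrix.copy()
        codes = np.where(np.isnan(flat), 2, flat).astype(np.int8)
        uniq, counts = np.unique(codes, axis=0, return_counts=True)
        T, J = design.n_seasons, design.surveys_per_season
        u = uniq.reshape(-1, T, J).astype(float)
        self.weights = counts.astype(float)
        self.mask = u != 2  # observed survey
        self.d = np.where(self.mask, u, 0.0)
        with np.errstate(invalid="ignore"):
            self.all_zero = ~np.any(self.mask & (self.d > 0), axis=2)  # (u, T)
        self.n_sites = history.n_sites

    def nll(self, psi1, eps, gam, p) -> float:
        # emission log-prob given occupied, per unique row and season;
        # xlogy keeps 0*log(0) = 0 so p = 0/1 stays a valid degenerate case
        ll = xlogy(self.d, p) + xlogy(1.0 - self.d, 1.0 - p)
        ll_occ = np.sum(np.where(self.mask, ll, 0.0), axis=2)
        e_occ = np.exp(ll_occ)  # (u, T)
        e_un = self.all_zero.astype(float)

        a_occ = psi1 * e_occ[:, 0]
        a_un = (1.0 - psi1) * e_un[:, 0]
        for t in range(1, e_occ.shape[1]):
            occ = (a_occ * (1.0 - eps[t - 1]) + a_un * gam[t - 1]) * e_occ[:, t]
            un = (a_occ * eps[t - 1] + a_un * (1.0 - gam[t - 1])) * e_un[:, t]
            a_occ, a_un = occ, un
        lik = a_occ + a_un
        if np.any(lik <= 0.0) or not np.all(np.isfinite(lik)):
            return np.inf
        return float(-np.sum(self.weights * np.log(lik)))


def negative_log_likelihood(
    params: OccupancyParams,
    history: DetectionHistory,
    design: SurveyDesign,
    spec: OccupancyModelSpec | None = None,
) -> float:
    """-log L of the full data under the dynamic occupancy model.

    Returns ``+inf`` when an observed history has probability zero under
    ``params`` (e.g. a detection with p = 0).
    """
    params.validate_against(design)
    data = _LikelihoodData(history, design)
    eps = params.epsilon if design.n_seasons > 1 else np.zeros(0)
    gam = params.gamma if design.n_seasons > 1 else np.zeros(0)
    return data.nll(params.psi1, eps, gam, params.p)


def brute_force_site_likelihood(
    params: OccupancyParams,
    site_history: np.ndarray,
    design: SurveyDesign,
) -> float:
    """Single-site likelihood by exhaustive enumeration of latent states.

    Sums over all 2**T occupancy-state sequences; the independent oracle for
    the forward recursion.  Refuses T > 12.
    """
    T, J = design.n_seasons, design.surveys_per_season
    if T > 12:
        raise ValueError("enumeration over 2**T latent sequences: T > 12 refused")
    params.validate_against(design)
    h = np.asarray(site_history, dtype=float).reshape(T, J)
    total = 0.0
    for z in itertools.product((0, 1), repeat=T):
        prob = params.psi1 if z[0] == 1 else 1.0 - params.psi1
        for t in range(1, T):
            if z[t - 1] == 1:
                prob *= params.epsilon[t - 1] if z[t] == 0 else 1.0 - params.epsilon[t - 1]
            else:
                prob *= params.gamma[t - 1] if z[t] == 1 else 1.0 - params.gamma[t - 1]
        for t in range(T):
            for j in range(J):
                d = h[t, j]
                if np.isnan(d):
                    continue
                if z[t] == 1:
                    prob *= params.p[t, j] if d == 1 else 1.0 - params.p[t, j]
                elif d == 1:
                    prob *= 0.0
        total += prob
    return total


# ---------------------------------------------------------------------------
# model / results


class DynamicOccupancyModel:
    """Dynamic occupancy model bound to a detection history and design.

    Parameters
    ----------
    history : DetectionHistory
    design : SurveyDesign
    spec : OccupancyModelSpec
        Which of epsilon, gamma, p vary by season/survey (psi1 is a single
        initial-occupancy parameter; spatial homogeneity is assumed, so
        psi_t is a landscape average of the proportion of area used).
    """

    def __init__(
        self,
        history: DetectionHistory,
        design: SurveyDesign,
        spec: OccupancyModelSpec = OccupancyModelSpec(),
    ):
        history.validate_against(design)
        if np.all(np.isnan(history.matrix)):
            raise ValueError("all-missing detection history")
        self.history = history
        self.design = design
        self.spec = spec
        self._data = _LikelihoodData(history, design)
        self.data_fingerprint = hashlib.sha256(
            np.nan_to_num(history.matrix, nan=2.0).tobytes()
        ).hexdigest()

    @property
    def k_params(self) -> int:
        return self.spec.n_params(self.design)

    def nll(self, theta: np.ndarray) -> float:
        """Negative log-likelihood at a free logit-scale parameter vector."""
        psi1, eps, gam, p = _expand(theta, self.spec, self.design)
        return self._data.nll(psi1, eps, gam, p)

    def _naive_start(self) -> np.ndarray:
        v = self.history.season_view(self.design)
        obs = ~np.isnan(v)
        det = np.nansum(v) / max(obs.sum(), 1)
        p0 = float(np.clip(det, 0.05, 0.95))
        with np.errstate(invalid="ignore"):
            any1 = np.nanmax(v[:, 0, :], axis=1)
        psi0 = float(np.clip(np.nanmean(any1), 0.05, 0.95))
        params = OccupancyParams(
            psi1=psi0,
            epsilon=np.full(max(self.design.n_seasons - 1, 1), 0.2),
            gamma=np.full(max(self.design.n_seasons - 1, 1), 0.6),
            p=np.full((self.design.n_seasons, self.design.surveys_per_season), p0),
        )
        if self.design.n_seasons == 1:
            params.epsilon = np.zeros(0)
            params.gamma = np.zeros(0)
        return _pack(params, self.spec, self.design)

    def fit(
        self,
        n_starts: int = 10,
        tol: float = 1e-8,
        seed: int | None = None,
        compute_vcov: bool = True,
    ) -> "DynamicOccupancyResults":
        """Maximize the likelihood from multiple starts; quasi-Newton on logits.

        One start uses empirical detection frequencies; ``n_starts`` further
        starts draw logits from N(0, 1.5^2).  Standard errors come from the
        inverse numerical Hessian; estimates with |logit| > 10 are flagged as
        boundary estimates and their SEs suppressed (printed as 0.00), the
        behaviour dynamic occupancy fits show when colonization saturates.
        """
        rng = np.random.default_rng(seed)
        k = self.k_params
        starts = [self._naive_start()]
        starts += [rng.normal(0.0, 1.5, size=k) for _ in range(n_starts)]
        best = None
        any_converged = False
        bounds = [(-LOGIT_CLAMP, LOGIT_CLAMP)] * k
        for x0 in starts:
            res = minimize(
                self.nll,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": tol, "gtol": 1e-7, "maxiter": 1000},
            )
            if not np.isfinite(res.fun):
                continue
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None:
            raise RuntimeError("likelihood not finite at any start")

        theta = np.asarray(best.x, dtype=float)
        boundary = np.abs(theta) > BOUNDARY_LOGIT
        vcov = np.full((k, k), np.nan)
        se = np.full(k, np.nan)
        if compute_vcov:
            free = ~boundary
            try:
                H = approx_hess2(theta, self.nll)
                Hf = H[np.ix_(free, free)]
                vf = np.linalg.pinv(Hf)
                vcov[np.ix_(free, free)] = vf
                diag = np.diag(vcov).copy()
                with np.errstate(invalid="ignore"):
                    se = np.sqrt(np.where(diag > 0, diag, np.nan))
            except (np.linalg.LinAlgError, ValueError):
                pass
        se = np.where(boundary, 0.0, se)
        return DynamicOccupancyResults(
            model=self,
            theta=theta,
            loglik=-float(best.fun),
            converged=any_converged,
            vcov=vcov,
            se_logit=se,
            boundary_flags=boundary,
        )


@dataclass
class DerivedTrajectory:
    """Per-season occupancy, growth rate and false-absence probability."""

    psi: np.ndarray  # (T,)
    se_psi: np.ndarray
    lam: np.ndarray  # (T-1,), lambda_t = psi_{t+1} / psi_t
    se_lam: np.ndarray
    pfa: np.ndarray  # (T,)
    season_labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        T = self.psi.size
        lam = np.concatenate([self.lam, [np.nan]]) if T else self.lam
        se_lam = np.concatenate([self.se_lam, [np.nan]]) if T else self.se_lam
        return pd.DataFrame(
            {
                "season": np.arange(1, T + 1),
                "label": list(self.season_labels),
                "psi": self.psi,
                "se_psi": self.se_psi,
                "lambda": lam,
                "se_lambda": se_lam,
                "pfa": self.pfa,
            }
        )


@dataclass
class DynamicOccupancyResults:
    """MLE fit of a :class:`DynamicOccupancyModel`."""

    model: DynamicOccupancyModel
    theta: np.ndarray  # free params, logit scale
    loglik: float
    converged: bool
    vcov: np.ndarray  # logit scale
    se_logit: np.ndarray
    boundary_flags: np.ndarray

    name: str = field(default="", compare=False)

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    @property
    def estimates(self) -> OccupancyParams:
        psi1, eps, gam, p = _expand(self.theta, self.model.spec, self.model.design)
        return OccupancyParams(psi1=psi1, epsilon=eps, gamma=gam, p=p)

    @property
    def params_prob(self) -> np.ndarray:
        """Free parameters mapped to the probability scale."""
        return expit(np.clip(self.theta, -LOGIT_CLAMP, LOGIT_CLAMP))

    @property
    def se_prob(self) -> np.ndarray:
        """Delta-method SEs on the probability scale (0.0 at boundaries)."""
        pr = self.params_prob
        return np.where(self.boundary_flags, 0.0, self.se_logit * pr * (1.0 - pr))

    def _psi_path(self, theta: np.ndarray) -> np.ndarray:
        psi1, eps, gam, _ = _expand(theta, self.model.spec, self.model.design)
        T = self.model.design.n_seasons
        psi = np.empty(T)
        psi[0] = psi1
        for t in range(T - 1):
            psi[t + 1] = psi[t] * (1.0 - eps[t]) + (1.0 - psi[t]) * gam[t]
        return psi

    def trajectory(self) -> DerivedTrajectory:
        """Derived psi_t, lambda_t, PFA_t with delta-method standard errors."""
        design = self.model.design
        T = design.n_seasons
        psi = self._psi_path(self.theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(psi[:-1] > 0, psi[1:] / psi[:-1], np.nan)
        _, _, _, p = _expand(self.theta, self.model.spec, design)
        pfa = np.prod(1.0 - p, axis=1)

        # delta method through the recursion, central finite differences
        k = self.theta.size
        h = 1e-5
        Jpsi = np.zeros((T, k))
        for i in range(k):
            tp = self.theta.copy()
            tm = self.theta.copy()
            tp[i] += h
            tm[i] -= h
            Jpsi[:, i] = (self._psi_path(tp) - self._psi_path(tm)) / (2 * h)
        V = np.nan_to_num(self.vcov, nan=0.0)
        cov_psi = Jpsi @ V @ Jpsi.T
        se_psi = np.sqrt(np.clip(np.diag(cov_psi), 0.0, None))
        # lambda_t = psi_{t+1}/psi_t: gradient by quotient rule on Jpsi rows
        se_lam = np.full(max(T - 1, 0), np.nan)
        for t in range(T - 1):
            if psi[t] <= 0:
                continue
            g = Jpsi[t + 1] / psi[t] - psi[t + 1] * Jpsi[t] / psi[t] ** 2
            se_lam[t] = float(np.sqrt(max(g @ V @ g, 0.0)))
        return DerivedTrajectory(
            psi=psi,
            se_psi=se_psi,
            lam=lam,
            se_lam=se_lam,
            pfa=pfa,
            season_labels=design.season_labels,
        )

    def summary(self) -> str:
        names = self.model.spec.param_names(self.model.design)
        pr = self.params_prob
        se = self.se_prob
        lines = [
            "Dynamic occupancy model (two-state latent Markov chain, MLE)",
            f"  structure : {self.model.spec.label()}",
            f"  sites     : {self.model.history.n_sites}"
            f"   seasons: {self.model.design.n_seasons}"
            f"   surveys/season: {self.model.design.surveys_per_season}",
            f"  logLik    : {self.loglik:.3f}   K: {self.k_params}   AIC: {self.aic:.2f}",
            f"  converged : {self.converged}",
            "",
            f"  {'parameter':<18}{'estimate':>10}{'SE':>8}",
        ]
        for i, nm in enumerate(names):
            flag = " (boundary)" if self.boundary_flags[i] else ""
            se_txt = f"{se[i]:8.2f}" if np.isfinite(se[i]) else "      NA"
            lines.append(f"  {nm:<18}{pr[i]:10.3f}{se_txt}{flag}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serialisable fit report (probability scale)."""
        names = self.model.spec.param_names(self.model.design)
        traj = self.trajectory().to_frame()
        return {
            "structure": self.model.spec.label(),
            "loglik": self.loglik,
            "K": self.k_params,
            "aic": self.aic,
            "converged": self.converged,
            "estimates": {
                nm: {
                    "estimate": float(self.params_prob[i]),
                    "se": (float(self.se_prob[i]) if np.isfinite(self.se_prob[i]) else None),
                    "boundary": bool(self.boundary_flags[i]),
                }
                for i, nm in enumerate(names)
            },
            "trajectory": traj.replace({np.nan: None}).to_dict(orient="records"),
        }

    def plot_trajectory(self, ax=None):
        """Plot psi_t with SE bars and the lambda = 1 stability reference."""
        import matplotlib.pyplot as plt

        traj = self.trajectory()
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = np.arange(1, traj.psi.size + 1)
        ax.errorbar(t, traj.psi, yerr=traj.se_psi, marker="o", color="k", label=r"$\psi_t$")
        ax.set_xlabel("season")
        ax.set_ylabel("occupancy probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax


def fit_occupancy(
    history: DetectionHistory,
    design: SurveyDesign,
    spec: OccupancyModelSpec = OccupancyModelSpec(),
    n_starts: int = 10,
    tol: float = 1e-8,
    seed: int | None = None,
    compute_vcov: bool = True,
) -> DynamicOccupancyResults:
    """Fit a dynamic occupancy model (functional wrapper over the Model class)."""
    return DynamicOccupancyModel(history, design, spec).fit(
        n_starts=n_starts, tol=tol, seed=seed, compute_vcov=compute_vcov
    )


def derive_trajectory(fit: DynamicOccupancyResults, design: SurveyDesign | None = None) -> DerivedTrajectory:
    """Seasonal psi/lambda/PFA trajectory with delta-method SEs."""
    if design is not None and design is not fit.model.design:
        if design.n_seasons != fit.model.design.n_seasons:
            raise ValueError("design does not match the fitted model")
    return fit.trajectory()


@dataclass
class ModelRanking:
    """AIC ranking of competing fits of the same data."""

    table: pd.DataFrame  # columns: model, K, aic, delta_aic, weight

    def evidence_ratio(self, i, j) -> float:
        w = self.table.set_index("model")["weight"]
        return float(w[i] / w[j])

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])


def rank_models_aic(fits: Sequence[DynamicOccupancyResults]) -> ModelRanking:
    """Rank fits by AIC; Akaike weights w_i = exp(-delta_i/2) / sum."""
    if not fits:
        raise ValueError("need at least one fit")
    fps = {f.model.data_fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("fits are not all on the same data")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    names = [f.name or f.model.spec.label() for f in fits]
    tab = pd.DataFrame(
        {"model": names, "K": [f.k_params for f in fits], "aic": aics, "delta_aic": delta, "weight": w}
    ).sort_values("aic", kind="stable", ignore_index=True)
    return ModelRanking(table=tab)


def default_candidate_specs() -> dict[str, OccupancyModelSpec]:
    """The default temporal candidate set: {eps, gam} x {p} structures.

    The cross of constant/seasonal extinction and colonization with
    constant/seasonal/monthly detection (12 models), which contains the
    structure with seasonal dynamics and monthly detection.
    """
    out = {}
    for e in _EPS_STRUCTURES:
        for g in _EPS_STRUCTURES:
            for pp in _P_STRUCTURES:
                spec = OccupancyModelSpec(epsilon=e, gamma=g, p=pp)
                out[spec.label()] = spec
    return out
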