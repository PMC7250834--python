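"""Synthetic camera-trap studies with the structure the analyses assume.

The generator emulates a boreal deer camera grid: a classified landscape
raster (smoothed-noise patches), linear disturbance features, a
stratified site placement with a minimum spacing, a winter snow-depth
regime classified by days above a severity threshold, latent first-order
Markov occupancy dynamics whose winter extinction depends on that
severity class, and imperfect monthly detection.  A separate spatial mode
couples per-site persistence counts to landscape covariates at a chosen
effect radius through a logistic link, giving the distribution-model
stage a true generating model.

All outputs are bit-reproducible from (config, seed); one global seed is
expanded into independent substreams for landscape, snow, dynamics and
detection so components can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

from .landscape import LandscapeRaster, LinearFeatures, SiteCovariateTable, extract_covariates
from .persistence import PersistenceResponse, PreparedCovariates
from .survey import DetectionHistory, SurveyDesign, build_design

__all__ = [
    "SimulationConfig",
    "SnowSeries",
    "simulate_landscape_and_sites",
    "simulate_snow_and_classify",
    "simulate_occupancy_dynamics",
    "simulate_detections",
    "simulate_persistence_counts",
    "simulate_study",
]

#: landcover legend used by the default generator
DEFAULT_LEGEND = {
    1: "conifer",
    2: "muskeg",
    3: "upland deciduous",
    4: "cutblock",
    5: "well site",
    6: "industrial block",
}

DEFAULT_MIXTURE = {
    "conifer": 0.45,
    "muskeg": 0.25,
    "upland deciduous": 0.18,
    "cutblock": 0.09,
    "well site": 0.015,
    "industrial block": 0.015,
}

DEFAULT_LINE_DENSITY = {"road": 0.3, "OHV trail": 0.5, "seismic line": 1.5}  # km/km^2

SEVERITY_CLASSES = ("mild", "moderate", "severe")


def _default_design() -> SurveyDesign:
    return build_design(datetime(2011, 10, 1), 12, 3)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the deer study: 62 cameras on a >=2-km-spaced
    stratified grid sampled monthly for 12 three-month seasons starting
    October 2011 (36 surveys/site); one mild, one severe and one
    moderately severe winter; winter extinction set by severity class;
    near-total spring recolonization; monthly detection probabilities
    lowest in late winter/spring and highest in summer.
    """

    n_sites: int = 62
    design: SurveyDesign = field(default_factory=_default_design)
    psi1: float = 0.95

    # transition regime
    epsilon_by_severity: Mapping[str, float] = field(
        default_factory=lambda: {"mild": 0.15, "moderate": 0.30, "severe": 0.40}
    )
    epsilon_other: float = 0.05
    gamma_spring: float = 0.95
    gamma_other: float = 0.60
    winter_severities: tuple[str, ...] = ("mild", "severe", "moderate")

    # detection: per-season-label base p plus within-season survey offsets
    p_by_label: Mapping[str, float] = field(
        default_factory=lambda: {
            "rut": 0.90,
            "post-rut": 0.80,
            "pre/early-fawning": 0.75,
            "post-fawning": 0.92,
        }
    )
    p_survey_offsets: tuple[float, ...] = (-0.05, 0.0, 0.05)

    # landscape
    extent_m: float = 40000.0
    cell_size_m: float = 50.0
    class_mixture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    patch_scale_m: float = 400.0
    line_density_km_per_km2: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINE_DENSITY)
    )
    site_spacing_m: float = 2000.0
    edge_buffer_m: float = 5000.0
    strata_cell_m: float = 1000.0

    # snow regime
    snow_threshold_cm: float = 30.0
    winter_window_days: int = 166  # November through mid-April
    peak_depth_by_severity: Mapping[str, float] = field(
        default_factory=lambda: {"mild": 15.0, "moderate": 45.0, "severe": 65.0}
    )
    severity_cutpoints_days: tuple[int, int] = (10, 100)  # <=10 mild, <=100 moderate

    # spatial (persistence) coupling
    effect_radius_m: float = 1000.0
    persistence_beta: Mapping[str, float] = field(
        default_factory=lambda: {
            "pct_upland deciduous": 0.03,
            "pct_cutblock": 0.07,
            "pct_well site": 0.24,
            "density_OHV trail": -0.88,
            "pct_industrial block": 0.41,
        }
    )
    persistence_intercept: float = -0.16

    def __post_init__(self) -> None:
        probs = [self.psi1, self.epsilon_other, self.gamma_spring, self.gamma_other]
        probs += list(self.epsilon_by_severity.values()) + list(self.p_by_label.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.site_spacing_m >= self.extent_m:
            raise ValueError("site spacing must be smaller than the extent")
        for s in self.winter_severities:
            if s not in self.epsilon_by_severity:
                raise ValueError(f"no epsilon for severity class {s!r}")

    # -- derived true parameters -------------------------------------------

    def transition_rates(
        self, severities: Sequence[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """True (epsilon_t, gamma_t) vectors over season transitions.

        The transition *into* a winter season uses that winter's severity
        epsilon; the transition *out of* a winter (into spring) uses the
        spring colonization rate.
        """
        design = self.design
        T = design.n_seasons
        sev = list(severities if severities is not None else self.winter_severities)
        winters = sorted(design.winter_season_indices)
        if len(sev) < len(winters):
            raise ValueError("a severity class is required for every winter season")
        eps = np.full(max(T - 1, 0), self.epsilon_other)
        gam = np.full(max(T - 1, 0), self.gamma_other)
        for w, s in zip(winters, sev):
            if w - 1 >= 0:
                eps[w - 1] = self.epsilon_by_severity[s]
            if w < T - 1:
                gam[w] = self.gamma_spring
        return eps, gam

    def detection_matrix(self) -> np.ndarray:
        """True p_{t,j} (season x survey)."""
        design = self.design
        J = design.surveys_per_season
        offs = np.asarray(self.p_survey_offsets[:J], dtype=float)
        if offs.size < J:
            offs = np.resize(offs, J)
        p = np.empty((design.n_seasons, J))
        for t, lab in enumerate(design.season_labels):
            p[t] = np.clip(self.p_by_label[lab] + offs, 0.0, 1.0)
        return p


def _substream(seed: int | None, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed)
    return np.random.default_rng(ss.spawn(index + 1)[index])


# ---------------------------------------------------------------------------
# landscape, lines, site placement


def simulate_landscape_and_sites(
    config: SimulationConfig, seed: int | None = None
) -> tuple[LandscapeRaster, LinearFeatures, pd.DataFrame]:
    """Raster + trails + a constrained stratified random camera grid.

    The raster is smoothed Gaussian noise cut at the mixture's quantiles;
    1x1-km cells are classified by their dominant landcover and sampled
    evenly across classes, rejecting candidates within the minimum
    spacing of an accepted site.
    """
    rng = _substream(seed, 0)
    n_cells = int(round(config.extent_m / config.cell_size_m))
    sigma = config.patch_scale_m / config.cell_size_m
    noise = gaussian_filter(rng.normal(size=(n_cells, n_cells)), sigma=sigma, mode="wrap")

    names = list(DEFAULT_LEGEND.values())
    mix = np.array([config.class_mixture.get(nm, 0.0) for nm in names])
    mix = mix / mix.sum()
    cuts = np.quantile(noise, np.cumsum(mix)[:-1])
    data = np.digitize(noise, cuts) + 1  # codes 1..n_classes
    raster = LandscapeRaster(
        data=data, cell_size=config.cell_size_m, origin=(0.0, 0.0), legend=dict(DEFAULT_LEGEND)
    )

    # random polyline trails per class, total length set by density
    feats = []
    area_km2 = (config.extent_m / 1000.0) ** 2
    for cls, dens in config.line_density_km_per_km2.items():
        target_m = dens * area_km2 * 1000.0
        placed = 0.0
        while placed < target_m:
            x0, y0 = rng.uniform(0, config.extent_m, size=2)
            ang = rng.uniform(0, 2 * np.pi)
            seg_len = rng.uniform(2000.0, 5000.0)
            x1 = np.clip(x0 + seg_len * np.cos(ang), 0, config.extent_m)
            y1 = np.clip(y0 + seg_len * np.sin(ang), 0, config.extent_m)
            line = LineString([(x0, y0), (x1, y1)])
            if line.length < 1.0:
                continue
            feats.append((cls, line))
            placed += line.length
    lines = LinearFeatures(features=feats)

    sites = _place_sites(config, raster, rng)
    return raster, lines, sites


def _place_sites(config: SimulationConfig, raster: LandscapeRaster, rng) -> pd.DataFrame:
    cell = int(round(config.strata_cell_m / config.cell_size_m))
    n_big = raster.data.shape[0] // cell
    lo = config.edge_buffer_m
    hi = config.extent_m - config.edge_buffer_m
    # dominant class per 1-km cell (strata), keeping only interior cells
    strata: dict[int, list[tuple[float, float]]] = {}
    for bi in range(n_big):
        for bj in range(n_big):
            cx = (bj + 0.5) * config.strata_cell_m
            cy = config.extent_m - (bi + 0.5) * config.strata_cell_m
            if not (lo <= cx <= hi and lo <= cy <= hi):
                continue
            block = raster.data[bi * cell : (bi + 1) * cell, bj * cell : (bj + 1) * cell]
            dom = int(np.bincount(block.ravel()).argmax())
            strata.setdefault(dom, []).append((cx, cy))
    classes = sorted(strata)
    if not classes:
        raise RuntimeError("no strata cells inside the edge buffer; enlarge the extent")

    chosen: list[tuple[int, float, float]] = []
    for _restart in range(30):
        chosen = []
        order = {c: rng.permutation(len(strata[c])) for c in classes}
        pointers = {c: 0 for c in classes}
        exhausted = False
        while len(chosen) < config.n_sites and not exhausted:
            progressed = False
            for c in classes:
                if len(chosen) >= config.n_sites:
                    break
                cells = strata[c]
                while pointers[c] < len(cells):
                    cx, cy = cells[order[c][pointers[c]]]
                    pointers[c] += 1
                    jx = cx + rng.uniform(-200, 200)
                    jy = cy + rng.uniform(-200, 200)
                    ok = all(
                        (jx - x) ** 2 + (jy - y) ** 2 >= config.site_spacing_m**2
                        for _, x, y in chosen
                    )
                    if ok:
                        chosen.append((c, jx, jy))
                        progressed = True
                        break
            exhausted = not progressed
        if len(chosen) >= config.n_sites:
            break
    else:
        raise RuntimeError(
            f"could not place {config.n_sites} sites at {config.site_spacing_m:.0f}-m "
            "spacing; reduce n_sites or enlarge the extent"
        )
    df = pd.DataFrame(
        [(f"site{i + 1:03d}", x, y, raster.legend[c]) for i, (c, x, y) in enumerate(chosen)],
        columns=["site_id", "x", "y", "stratum"],
    )
    return df


# ---------------------------------------------------------------------------
# snow


@dataclass
class SnowSeries:
    """Daily snow-on-ground per winter, with severity classification."""

    depths: list[np.ndarray]  # cm, one array per winter window
    threshold_cm: float
    cutpoints_days: tuple[int, int]

    def __post_init__(self) -> None:
        for d in self.depths:
            if np.any(d < 0):
                raise ValueError("snow depths must be non-negative")

    @property
    def exceedance_days(self) -> list[int]:
        return [int(np.sum(d > self.threshold_cm)) for d in self.depths]

    @property
    def classes(self) -> list[str]:
        return [self.classify_count(c) for c in self.exceedance_days]

    def classify_count(self, count: int) -> str:
        lo, hi = self.cutpoints_days
        if count <= lo:
            return "mild"
        if count <= hi:
            return "moderate"
        return "severe"


def simulate_snow_and_classify(config: SimulationConfig, seed: int | None = None) -> SnowSeries:
    """Seasonal sinusoid + autocorrelated noise per winter, classified by
    days with snow-on-ground above the severity threshold (30 cm)."""
    rng = _substream(seed, 1)
    n_w = len(config.winter_severities)
    days = config.winter_window_days
    t = np.arange(days)
    depths = []
    for w in range(n_w):
        peak = config.peak_depth_by_severity[config.winter_severities[w]]
        base = peak * np.sin(np.pi * (t + 1) / (days + 1))
        ar = np.empty(days)
        ar[0] = rng.normal(0, 2.5)
        for i in range(1, days):
            ar[i] = 0.9 * ar[i - 1] + rng.normal(0, 2.5)
        depths.append(np.clip(base + ar, 0.0, None))
    return SnowSeries(
        depths=depths,
        threshold_cm=config.snow_threshold_cm,
        cutpoints_days=config.severity_cutpoints_days,
    )


# ---------------------------------------------------------------------------
# occupancy dynamics and detection


def simulate_occupancy_dynamics(
    config: SimulationConfig,
    seed: int | None = None,
    severities: Sequence[str] | None = None,
    epsilon: np.ndarray | None = None,
    gamma: np.ndarray | None = None,
) -> np.ndarray:
    """Latent site x season occupancy states from the Markov regime.

    ``epsilon``/``gamma`` override the severity-derived transition rates
    with explicit per-transition vectors.
    """
    rng = _substream(seed, 2)
    T = config.design.n_seasons
    n = config.n_sites
    eps, gam = config.transition_rates(severities)
    if epsilon is not None:
        eps = np.asarray(epsilon, dtype=float)
    if gamma is not None:
        gam = np.asarray(gamma, dtype=float)
    if eps.shape != (max(T - 1, 0),) or gam.shape != (max(T - 1, 0),):
        raise ValueError(f"epsilon/gamma must have length {T - 1}")
    z = np.zeros((n, T), dtype=int)
    z[:, 0] = rng.random(n) < config.psi1
    for t in range(1, T):
        u = rng.random(n)
        z[:, t] = np.where(z[:, t - 1] == 1, u >= eps[t - 1], u < gam[t - 1])
    return z


def simulate_detections(
    states: np.ndarray,
    config: SimulationConfig,
    seed: int | None = None,
    sites: pd.DataFrame | None = None,
    missing_rate: float = 0.0,
) -> DetectionHistory:
    """Bernoulli(p_tj) detections at occupied site-seasons; structural
    zeros elsewhere; optional independent missingness per survey window."""
    rng = _substream(seed, 3)
    design = config.design
    n, T = states.shape
    J = design.surveys_per_season
    p = config.detection_matrix()
    det = (rng.random((n, T, J)) < p[None, :, :]) & (states[:, :, None] == 1)
    mat = det.reshape(n, T * J).astype(float)
    if missing_rate > 0:
        miss = rng.random(mat.shape) < missing_rate
        # keep at least one surveyed window per site
        full_rows = miss.all(axis=1)
        miss[full_rows, 0] = False
        mat[miss] = np.nan
    if sites is not None:
        ids = sites["site_id"].tolist()[:n]
        coords = sites[["x", "y"]].to_numpy()[:n]
    else:
        ids = [f"site{i + 1:03d}" for i in range(n)]
        coords = np.zeros((n, 2))
    return DetectionHistory(site_ids=ids, coordinates=coords, matrix=mat)


def simulate_persistence_counts(
    prepared: PreparedCovariates,
    config: SimulationConfig,
    seed: int | None = None,
    trials: int | None = None,
    coordinates: np.ndarray | None = None,
) -> PersistenceResponse:
    """Persistence counts from a logistic model on standardized covariates.

    successes_i ~ Binomial(trials, expit(b0 + x_i . beta)) with the
    configured effect vector at the effect radius; the generating model
    for the spatial analysis stage.
    """
    rng = _substream(seed, 4)
    X = prepared.X
    beta = np.zeros(X.shape[1])
    for k, v in config.persistence_beta.items():
        if k in X.columns:
            beta[X.columns.get_loc(k)] = v
    eta = config.persistence_intercept + X.to_numpy() @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    trials = trials if trials is not None else config.design.n_surveys
    succ = rng.binomial(trials, prob)
    return PersistenceResponse(
        site_ids=list(X.index.astype(str)),
        successes=succ.astype(float),
        trials=np.full(X.shape[0], float(trials)),
        coordinates=coordinates,
    )


def simulate_study(config: SimulationConfig, seed: int | None = None) -> dict:
    """End-to-end synthetic study: landscape, sites, snow, dynamics,
    detections; returns all pieces plus the true parameter vectors."""
    raster, lines, sites = simulate_landscape_and_sites(config, seed)
    snow = simulate_snow_and_classify(config, seed)
    severities = snow.classes
    states = simulate_occupancy_dynamics(config, seed, severities=severities)
    history = simulate_detections(states, config, seed, sites=sites)
    eps, gam = config.transition_rates(severities)
    return {
        "config": config,
        "raster": raster,
        "lines": lines,
        "sites": sites,
        "snow": snow,
        "severities": severities,
        "states": states,
        "history": history,
        "true_epsilon": eps,
        "true_gamma": gam,
        "true_p": config.detection_matrix(),
    }
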