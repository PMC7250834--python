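"""Survey designs and camera-trap detection histories.

A multi-season camera survey is described by a :class:`SurveyDesign`: a
sequence of primary seasons (three months each in the deer study), each
split into equal-length secondary survey windows (one month, taken as
30.4 days).  Raw camera records are collapsed to a site x survey binary
detection matrix (:class:`DetectionHistory`), with ``NaN`` marking survey
windows in which a camera was never active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEASON_CYCLE",
    "SurveyDesign",
    "DetectionHistory",
    "build_design",
    "collapse_to_monthly",
    "read_history",
    "write_history",
]

#: Quarterly behavioural seasons, in calendar order starting from October.
SEASON_CYCLE = ("rut", "post-rut", "pre/early-fawning", "post-fawning")

#: Nominal length of one secondary (monthly) survey window, in days.
SURVEY_LENGTH_DAYS = 30.4


class InvalidDesignError(ValueError):
    """Raised when a survey design is internally inconsistent."""


def _quarter_index(month: int) -> int:
    # quarter 0 = Oct-Dec (rut), 1 = Jan-Mar, 2 = Apr-Jun, 3 = Jul-Sep
    return ((month - 10) % 12) // 3


@dataclass(frozen=True)
class SurveyDesign:
    """Primary-season / secondary-survey layout of a camera study."""

    n_seasons: int
    surveys_per_season: int
    survey_length_days: float
    season_labels: tuple[str, ...]
    season_calendar: tuple[tuple[datetime, datetime], ...]
    winter_season_indices: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_seasons < 1 or self.surveys_per_season < 1:
            raise InvalidDesignError("n_seasons and surveys_per_season must be >= 1")
        if len(self.season_labels) != self.n_seasons:
            raise InvalidDesignError("one label per season required")
        if len(self.season_calendar) != self.n_seasons:
            raise InvalidDesignError("one calendar interval per season required")
        for t, (a, b) in enumerate(self.season_calendar):
            if b <= a:
                raise InvalidDesignError(f"season {t + 1} interval is empty")
            if t and a != self.season_calendar[t - 1][1]:
                raise InvalidDesignError("season intervals must be contiguous")
        if any(i < 0 or i >= self.n_seasons for i in self.winter_season_indices):
            raise InvalidDesignError("winter index out of range")

    @property
    def n_surveys(self) -> int:
        """Total secondary surveys per site (seasons x surveys/season)."""
        return self.n_seasons * self.surveys_per_season

    def survey_window(self, season: int, survey: int) -> tuple[datetime, datetime]:
        """Time interval of survey ``survey`` (0-based) within ``season``."""
        start0, _ = self.season_calendar[season]
        a = start0 + timedelta(days=self.survey_length_days * survey)
        return a, a + timedelta(days=self.survey_length_days)

    def flat_windows(self) -> list[tuple[datetime, datetime]]:
        """All survey windows in chronological order."""
        return [
            self.survey_window(t, j)
            for t in range(self.n_seasons)
            for j in range(self.surveys_per_season)
        ]


def build_design(
    start_date: datetime,
    n_seasons: int,
    surveys_per_season: int,
    survey_length_days: float = SURVEY_LENGTH_DAYS,
) -> SurveyDesign:
    """Build a survey design on a fixed arithmetic grid from ``start_date``.

    Seasons are ``surveys_per_season * survey_length_days`` long, laid end to
    end; labels follow the quarterly behavioural cycle (rut, post-rut,
    pre/early-fawning, post-fawning) starting at the quarter containing
    ``start_date``.  Seasons falling in the January-March quarter are flagged
    as winters.
    """
    if n_seasons < 1 or surveys_per_season < 1:
        raise InvalidDesignError("counts must be positive")
    season_days = surveys_per_season * survey_length_days
    calendar = []
    for t in range(n_seasons):
        a = start_date + timedelta(days=season_days * t)
        calendar.append((a, a + timedelta(days=season_days)))
    q0 = _quarter_index(start_date.month)
    labels = tuple(SEASON_CYCLE[(q0 + t) % 4] for t in range(n_seasons))
    winters = frozenset(t for t, lab in enumerate(labels) if lab == "post-rut")
    return SurveyDesign(
        n_seasons=n_seasons,
        surveys_per_season=surveys_per_season,
        survey_length_days=survey_length_days,
        season_labels=labels,
        season_calendar=tuple(calendar),
        winter_season_indices=winters,
    )


@dataclass
class DetectionHistory:
    """Site x survey detection-nondetection matrix.

    ``matrix`` entries are 1.0 (detected), 0.0 (surveyed, not detected) or
    ``NaN`` (camera inactive for the whole window).
    """

    site_ids: list[str]
    coordinates: np.ndarray  # (n_sites, 2), metres in a projected CRS
    matrix: np.ndarray  # (n_sites, n_surveys) of {0.0, 1.0, NaN}

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.site_ids)
        if self.coordinates.shape != (n, 2):
            raise ValueError("coordinates must be (n_sites, 2)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite (projected metres)")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != n:
            raise ValueError("matrix rows must match site_ids")
        vals = self.matrix[~np.isnan(self.matrix)]
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("matrix entries must be 0, 1 or NaN")
        if n and np.any(np.all(np.isnan(self.matrix), axis=1)):
            bad = [self.site_ids[i] for i in np.where(np.all(np.isnan(self.matrix), axis=1))[0]]
            raise ValueError(f"sites with no surveyed window: {bad}")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_surveys(self) -> int:
        return self.matrix.shape[1]

    def validate_against(self, design: SurveyDesign) -> None:
        if self.n_surveys != design.n_surveys:
            raise ValueError(
                f"history has {self.n_surveys} surveys, design expects {design.n_surveys}"
            )

    def season_view(self, design: SurveyDesign) -> np.ndarray:
        """Matrix reshaped to (n_sites, n_seasons, surveys_per_season)."""
        self.validate_against(design)
        return self.matrix.reshape(self.n_sites, design.n_seasons, design.surveys_per_season)

    def winter_columns(self, design: SurveyDesign) -> np.ndarray:
        """Detection matrix restricted to winter-season surveys."""
        v = self.season_view(design)
        idx = sorted(design.winter_season_indices)
        return v[:, idx, :].reshape(self.n_sites, -1)


def collapse_to_monthly(
    records: Iterable[tuple[str, datetime]],
    design: SurveyDesign,
    deployments: Mapping[str, Sequence[tuple[datetime, datetime]]],
    coordinates: Mapping[str, tuple[float, float]] | None = None,
) -> DetectionHistory:
    """Collapse raw timestamped records to a monthly Bernoulli matrix.

    Each survey window is scored 1 if at least one record fell inside it
    while the camera was active, 0 if the camera was active at any point of
    the window without a record, and missing if the camera was inactive for
    the entire window.  Records outside all windows are ignored.
    """
    site_ids = sorted(deployments)
    index = {s: i for i, s in enumerate(site_ids)}
    windows = design.flat_windows()
    n, m = len(site_ids), len(windows)
    mat = np.full((n, m), np.nan)

    for i, sid in enumerate(site_ids):
        for k, (wa, wb) in enumerate(windows):
            active = any(a < wb and b > wa for a, b in deployments[sid])
            if active:
                mat[i, k] = 0.0

    for sid, ts in records:
        if sid not in index:
            raise ValueError(f"record for unknown site {sid!r}")
        i = index[sid]
        for k, (wa, wb) in enumerate(windows):
            if wa <= ts < wb:
                if any(a <= ts <= b for a, b in deployments[sid]):
                    mat[i, k] = 1.0
                break

    if coordinates is None:
        coords = np.zeros((n, 2))
    else:
        coords = np.array([coordinates[s] for s in site_ids], dtype=float)
    return DetectionHistory(site_ids=site_ids, coordinates=coords, matrix=mat)


def write_history(history: DetectionHistory, path) -> None:
    """Write a detection history as CSV (site_id, x, y, s01..sNN; 0/1/NA)."""
    cols = [f"s{k + 1:02d}" for k in range(history.n_surveys)]
    df = pd.DataFrame(history.matrix, columns=cols)
    df.insert(0, "y", history.coordinates[:, 1])
    df.insert(0, "x", history.coordinates[:, 0])
    df.insert(0, "site_id", history.site_ids)
    with open(path, "w") as fh:
        fh.write(",".join(df.columns) + "\n")
        for _, row in df.iterrows():
            cells = [str(row["site_id"]), repr(float(row["x"])), repr(float(row["y"]))]
            for c in cols:
                v = row[c]
                cells.append("NA" if math.isnan(v) else str(int(v)))
            fh.write(",".join(cells) + "\n")


def read_history(path) -> DetectionHistory:
    """Read a detection-history CSV written by :func:`write_history`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and not len(df.columns):
        raise ValueError(f"{path}: empty file is not a valid detection history")
    required = {"site_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    scols = [c for c in df.columns if c not in required]
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no site rows")
    mat = np.full((df.shape[0], len(scols)), np.nan)
    for j, c in enumerate(scols):
        for i, raw in enumerate(df[c]):
            cell = raw.strip()
            if cell in ("NA", ""):
                continue
            if cell not in ("0", "1"):
                raise ValueError(f"{path}: row {i + 2}, column {c}: invalid cell {raw!r}")
            mat[i, j] = float(cell)
    try:
        coords = df[["x", "y"]].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric coordinate: {exc}") from exc
    return DetectionHistory(site_ids=df["site_id"].tolist(), coordinates=coords, matrix=mat)
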