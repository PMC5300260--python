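"""Visual-quality trajectories of seedlings in low-temperature storage.

Seedlings of scion and rootstock cultivars are scored on an ordinal 1-5
visual-quality scale (5 = ideal, 3 = lowest marketable, 1 = dead) on
days 1, 7, 14, 21 and 28 of storage and on days 31 and 42, after return
to the greenhouse.  The packaged tables cover 11 cucurbit genotypes
stored at 12 degC and 11 solanaceous genotypes stored at 10 and at
12 degC.

The analyses here: the marketability threshold, the 6-week mean score,
Ward hierarchical clustering of the 7-day score trajectories into
tolerance groups (labelled A, B, ... from most to least tolerant), and a
storability rule giving the maximum whole weeks a genotype can be stored
while remaining marketable (including post-storage recovery after a full
4-week stay).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import floor

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

OBSERVATION_DAYS = (1, 7, 14, 21, 28, 31, 42)
MARKETABLE_THRESHOLD = 3.0
TABLES = ("cucurbit12", "solanaceous10", "solanaceous12")


class StorabilityError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreTrajectory:
    """Mean visual scores (with standard errors) of one cultivar over time."""

    cultivar: str
    common_name: str
    species: str
    role: str  # "scion" | "rootstock"
    storage_temp_C: float
    scores: tuple[tuple[int, float, float], ...]  # (day, mean score, se)

    def __post_init__(self) -> None:
        days = tuple(d for d, _, _ in self.scores)
        if days != OBSERVATION_DAYS:
            raise StorabilityError(
                f"{self.cultivar}: observation days {days} != {OBSERVATION_DAYS}"
            )
        for day, score, se in self.scores:
            if not (1.0 <= score <= 5.0):
                raise StorabilityError(f"{self.cultivar} day {day}: score {score} outside [1, 5]")
            if se < 0:
                raise StorabilityError(f"{self.cultivar} day {day}: negative se")
        if self.role not in ("scion", "rootstock"):
            raise StorabilityError(f"{self.cultivar}: role must be scion or rootstock")

    def score_on(self, day: int) -> float:
        for d, s, _ in self.scores:
            if d == day:
                return s
        raise StorabilityError(f"{self.cultivar}: no observation on day {day}")

    @property
    def vector(self) -> np.ndarray:
        return np.array([s for _, s, _ in self.scores])


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, str]  # cultivar -> cluster letter
    linkage_method: str
    n_clusters: int


def load_score_tables(table: str | None = None) -> list[ScoreTrajectory]:
    """Load the packaged visual-score tables (optionally one of TABLES)."""
    if table is not None and table not in TABLES:
        raise StorabilityError(f"unknown table {table!r}; expected one of {TABLES}")
    with resources.files("graftsim.data").joinpath("visual_scores.csv").open() as fh:
        df = pd.read_csv(fh)
    if table is not None:
        df = df[df["table"] == table]
    out = []
    for (cultivar, temp), grp in df.groupby(["cultivar", "storage_temp_C"], sort=False):
        grp = grp.sort_values("day")
        first = grp.iloc[0]
        out.append(
            ScoreTrajectory(
                cultivar=cultivar,
                common_name=first["common_name"],
                species=first["species"],
                role=first["role"],
                storage_temp_C=float(temp),
                scores=tuple(
                    (int(r.day), float(r.score), float(r.se)) for r in grp.itertuples()
                ),
            )
        )
    return out


def is_marketable(score: float) -> bool:
    """A seedling is marketable iff its visual score is >= 3.0."""
    if not (1.0 <= score <= 5.0):
        raise StorabilityError(f"score {score} outside the 1-5 scale")
    return score >= MARKETABLE_THRESHOLD


def trajectory_mean(traj: ScoreTrajectory) -> float:
    """Unweighted mean of the 7 observed scores, half-up to 1 decimal."""
    mean = float(np.mean(traj.vector))
    return floor(mean * 10.0 + 0.5) / 10.0


def cluster_trajectories(
    trajectories: list[ScoreTrajectory], n_clusters: int
) -> ClusterAssignment:
    """Ward clustering of the 7-day score vectors into tolerance groups.

    Labels are letters ordered by descending cluster-mean score, so "A"
    is always the most storage-tolerant group.  The partition depends
    only on the set of trajectories, not on their input order.
    """
    if len(trajectories) < 2:
        raise StorabilityError("clustering needs at least 2 trajectories")
    if not (1 <= n_clusters <= len(trajectories)):
        raise StorabilityError("n_clusters must lie in [1, n trajectories]")
    order = np.argsort([t.cultivar for t in trajectories], kind="stable")
    trajs = [trajectories[i] for i in order]
    X = np.vstack([t.vector for t in trajs])
    Z = linkage(X, method="ward")
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    means = {
        c: float(np.mean([X[i].mean() for i in range(len(trajs)) if flat[i] == c]))
        for c in set(flat)
    }
    ranked = sorted(means, key=lambda c: -means[c])
    letter = {c: chr(ord("A") + rank) for rank, c in enumerate(ranked)}
    return ClusterAssignment(
        labels={t.cultivar: letter[c] for t, c in zip(trajs, flat)},
        linkage_method="ward",
        n_clusters=n_clusters,
    )


def storability_weeks(traj: ScoreTrajectory) -> int:
    """Maximum whole storage weeks with marketable quality maintained.

    The largest k in {0..4} such that every in-storage score through day
    7k stays >= 3.0; a full 4-week stay additionally requires the final
    post-storage score (day 42) to have recovered to >= 3.0.
    """
    for k in range(4, 0, -1):
        in_storage_ok = all(
            traj.score_on(d) >= MARKETABLE_THRESHOLD
            for d in OBSERVATION_DAYS
            if d <= 7 * k
        )
        recovered = traj.score_on(42) >= MARKETABLE_THRESHOLD if k == 4 else True
        if in_storage_ok and recovered:
            return k
    return 0
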