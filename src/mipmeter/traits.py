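"""Baseline normalization and starvation-resistance trait extraction.

Pooled strain frequencies from a starvation time course (days 1, 9, 13, 17)
are divided by the same replicate's baseline (day-1 aliquot) frequency and
log2-transformed, so y = 0 means no change from the initial composition.
Two per-strain trait values summarize the trajectories:

* **Slope** — zero-intercept least-squares slope of the replicate-averaged
  log2 ratios over days 1, 9 and 13: ``slope = Σ t·ȳ(t) / Σ t²``. Positive
  slope = the strain gains frequency under starvation (resistant). The
  zero intercept is consistent with y(0) ≈ 0 after baseline normalization.
* **PC1** — the strain's score on the first principal component of the
  strain x day matrix (replicates averaged, columns mean-centered, no
  variance scaling), sign-oriented so that PC1 correlates positively with
  Slope. PC1 uses all four days and does not assume linearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

DEFAULT_TIMEPOINTS = (1, 9, 13, 17)
DEFAULT_SLOPE_DAYS = (1, 9, 13)


@dataclass
class TrajectorySet:
    """Long-format replicate x strain x timepoint log2 ratios.

    ``data`` columns: replicate, strain_id, day, y. Entries that could not be
    normalized (zero or missing baseline, zero frequency) are absent from
    ``data`` and listed in ``masked`` with a reason.
    """

    data: pd.DataFrame
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    baseline_day: int = 1
    masked: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["replicate", "strain_id", "day", "reason"]))

    def __post_init__(self):
        if len(self.data) and not np.isfinite(self.data["y"].astype(float)).all():
            raise ValueError("trajectory values must be finite; mask bad entries instead")

    def replicate_mean(self) -> pd.DataFrame:
        """Strain x day matrix of replicate-averaged y."""
        return self.data.pivot_table(index="strain_id", columns="day", values="y",
                                     aggfunc="mean")


def normalize_to_baseline(freq: pd.DataFrame, sample_map: pd.DataFrame) -> TrajectorySet:
    """log2(f(day) / f(baseline)) per replicate and strain.

    ``freq`` is a long table (sample_id, strain_id, frequency); ``sample_map``
    assigns each sample_id a replicate, day, and is_baseline flag. Each
    replicate must have exactly one baseline sample.
    """
    required = {"sample_id", "replicate", "day", "is_baseline"}
    if not required <= set(sample_map.columns):
        raise ConfigError(f"sample map needs columns {sorted(required)}")
    sample_map = sample_map.copy()
    sample_map["is_baseline"] = sample_map["is_baseline"].astype(bool)
    n_base = sample_map.groupby("replicate")["is_baseline"].sum()
    bad = n_base[n_base != 1]
    if len(bad):
        raise ConfigError(f"each replicate needs exactly one baseline sample; "
                          f"offending replicates: {list(bad.index)}")

    merged = freq.merge(sample_map, on="sample_id")
    baselines = (merged[merged["is_baseline"]]
                 .set_index(["replicate", "strain_id"])["frequency"])
    rows, masked = [], []
    course = merged[~merged["is_baseline"]]
    for row in course.itertuples(index=False):
        key = (row.replicate, row.strain_id)
        base = baselines.get(key)
        if base is None or pd.isna(base):
            masked.append({"replicate": row.replicate, "strain_id": row.strain_id,
                           "day": row.day, "reason": "missing-baseline"})
            continue
        if base == 0:
            masked.append({"replicate": row.replicate, "strain_id": row.strain_id,
                           "day": row.day, "reason": "zero-baseline"})
            continue
        if row.frequency == 0:
            masked.append({"replicate": row.replicate, "strain_id": row.strain_id,
                           "day": row.day, "reason": "zero-frequency"})
            continue
        rows.append({"replicate": row.replicate, "strain_id": row.strain_id,
                     "day": int(row.day), "y": float(np.log2(row.frequency / base))})
    timepoints = tuple(sorted(course["day"].unique()))
    return TrajectorySet(
        data=pd.DataFrame(rows, columns=["replicate", "strain_id", "day", "y"]),
        timepoints=timepoints,
        baseline_day=int(sample_map.loc[sample_map["is_baseline"], "day"].iloc[0]),
        masked=pd.DataFrame(masked, columns=["replicate", "strain_id", "day", "reason"]))


def slope_trait(traj: TrajectorySet, fit_days=DEFAULT_SLOPE_DAYS, *,
                per_replicate: bool = False) -> pd.DataFrame:
    """Zero-intercept slope of replicate-averaged y over ``fit_days``.

    Closed form: ``slope = Σ t·ȳ(t) / Σ t²``. Strains with fewer than two
    usable days get a missing (NaN) slope and are reported via a warning.
    With ``per_replicate`` the slope is instead fit per replicate and then
    averaged (sensitivity-analysis mode).

    Returns a frame indexed by strain with columns slope, n_days_used,
    n_replicates_used.
    """
    fit_days = sorted(fit_days)
    sub = traj.data[traj.data["day"].isin(fit_days)]
    out = []
    for strain, grp in sub.groupby("strain_id"):
        n_reps = grp["replicate"].nunique()
        if per_replicate:
            slopes = []
            for _, rep_grp in grp.groupby("replicate"):
                ybar = rep_grp.groupby("day")["y"].mean()
                if len(ybar) >= 2:
                    t = ybar.index.to_numpy(float)
                    slopes.append(float((t * ybar.to_numpy()).sum() / (t ** 2).sum()))
            slope = float(np.mean(slopes)) if slopes else np.nan
            n_days = grp["day"].nunique()
        else:
            ybar = grp.groupby("day")["y"].mean()
            n_days = len(ybar)
            if n_days < 2:
                slope = np.nan
            else:
                t = ybar.index.to_numpy(float)
                slope = float((t * ybar.to_numpy()).sum() / (t ** 2).sum())
        out.append({"strain_id": strain, "slope": slope, "n_days_used": n_days,
                    "n_replicates_used": n_reps})
    df = pd.DataFrame(out).set_index("strain_id")
    n_missing = int(df["slope"].isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} strain(s) lack >=2 usable days; slope missing")
    return df


def pc1_trait(traj: TrajectorySet, days=DEFAULT_TIMEPOINTS, *, center: bool = True,
              scale: bool = False):
    """Per-strain scores on the first principal component of the y matrix.

    The strain x day matrix of replicate-averaged y over ``days`` is column
    mean-centered (optionally variance-scaled) and decomposed by SVD; the
    first left-singular scores are the trait. Strains with any missing day are
    dropped (complete-case) and reported. The component's sign is fixed so
    that it correlates non-negatively with Slope.

    Returns ``(pc1, replicate_scores, dropped)``: a Series indexed by strain,
    a diagnostics frame of per-sample (replicate, day) scores on the
    sample-level first component, and the list of dropped strains.
    """
    days = sorted(days)
    wide = traj.replicate_mean().reindex(columns=days)
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if len(complete) < 2:
        raise ValueError("need at least 2 strains with complete trajectories")
    scores = _first_component_scores(complete.to_numpy(float), center, scale)
    pc1 = pd.Series(scores, index=complete.index, name="pc1")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        slope = slope_trait(traj)["slope"].reindex(complete.index)
    ok = slope.notna() & pc1.notna()
    if ok.sum() >= 2 and np.std(slope[ok]) > 0 and np.std(pc1[ok]) > 0:
        if np.corrcoef(pc1[ok], slope[ok])[0, 1] < 0:
            pc1 = -pc1

    replicate_scores = _replicate_level_scores(traj, days, center, scale)
    return pc1, replicate_scores, dropped


def _first_component_scores(X: np.ndarray, center: bool, scale: bool) -> np.ndarray:
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, 0] * s[0]


def _replicate_level_scores(traj: TrajectorySet, days, center, scale) -> pd.DataFrame:
    """Sample-level PCA (rows = replicate x day libraries, columns = strains)."""
    sub = traj.data[traj.data["day"].isin(days)]
    wide = sub.pivot_table(index=["replicate", "day"], columns="strain_id",
                           values="y").dropna(axis=1)
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        return pd.DataFrame(columns=["replicate", "day", "score"])
    scores = _first_component_scores(wide.to_numpy(float), center, scale)
    out = wide.index.to_frame(index=False)
    out["score"] = scores
    # orient so the component increases with starvation day
    if np.corrcoef(out["day"], out["score"])[0, 1] < 0:
        out["score"] = -out["score"]
    return out


def trait_table(traj: TrajectorySet, slope_days=DEFAULT_SLOPE_DAYS,
                pc_days=DEFAULT_TIMEPOINTS) -> pd.DataFrame:
    """Combine Slope and PC1 into one mapping-ready table (one row per strain)."""
    slope = slope_trait(traj, slope_days)
    pc1, _, _ = pc1_trait(traj, pc_days)
    out = slope.join(pc1, how="outer")
    out.index.name = "strain_id"
    return out.reset_index()[["strain_id", "slope", "pc1", "n_replicates_used"]]


def export_traits(traits: pd.DataFrame, path) -> None:
    """Write the trait table as TSV; missing trait values become empty cells."""
    if traits.empty:
        raise ValueError("trait table is empty")
    try:
        traits.to_csv(path, sep="\t", index=False, na_rep="")
    except OSError as exc:
        raise OSError(f"cannot write trait table to {path}: {exc}") from exc
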