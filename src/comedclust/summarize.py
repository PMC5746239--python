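"""Per-cluster descriptive summaries.

For each cluster: size, share of the cohort, mean medication exposure
(mean over members of the per-window average medication count), the
10-window exposure trajectory, the number of paracetamol-only members,
and — when a covariate table is supplied — count/percent
cross-tabulations per categorical covariate with per-variable missing
counts (percentages are computed on the non-missing denominator).

A cluster is flagged as dominated by a medication class when one ATC
therapeutic subgroup (level 2, e.g. ``R03`` or ``N06``) accounts for a
disproportionate share of its non-paracetamol exposure relative to the
cohort, which supports labels like "high intensity use, more asthma".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .exposure import ExposureProfile, PARACETAMOL, window_trajectory
from .hca import ClusterAssignment

__all__ = [
    "ClusterStats",
    "ClusterSummary",
    "summarize_clusters",
    "paracetamol_only_count",
    "write_covariate_table",
    "write_trajectories",
    "write_summary",
]

#: covariates whose yes/no status can be proxied from ATC classes when no
#: questionnaire covariate table exists (synthetic runs)
ATC_INDICATION_PROXIES = {"mental_illness": ("N06A", "N05"), "asthma": ("R03",)}


@dataclass(frozen=True)
class ClusterStats:
    label: int
    n: int
    percent: float
    mean_exposure: float
    trajectory: np.ndarray
    paracetamol_only: int
    dominant_class: Optional[str]


@dataclass(frozen=True)
class ClusterSummary:
    clusters: tuple[ClusterStats, ...]
    cohort_n: int
    cohort_mean_exposure: float
    covariate_counts: Optional[pd.DataFrame] = None  # variable, category, cluster, n, percent
    covariate_missing: Optional[pd.DataFrame] = None  # variable, cluster, n_missing
    percent_decimals: int = field(default=1)


def _class_exposure(profiles: Iterable[ExposureProfile]) -> dict[str, int]:
    """Window-hit counts per ATC level-2 class, paracetamol excluded."""
    counts: dict[str, int] = {}
    for p in profiles:
        for s in p.windows:
            for code in s:
                if code == PARACETAMOL:
                    continue
                cls = code[:3] if len(code) >= 3 else code
                counts[cls] = counts.get(cls, 0) + 1
    return counts


def paracetamol_only_count(
    profiles: Sequence[ExposureProfile],
    assignment: ClusterAssignment,
    cluster: int,
) -> int:
    """Members of ``cluster`` whose entire medication set is {paracetamol}."""
    if not 1 <= cluster <= assignment.k:
        raise DataError(f"unknown cluster label {cluster}; labels are 1..{assignment.k}")
    by_id = {p.pregnancy_id: p for p in profiles}
    members = assignment.members(cluster)
    missing = [m for m in members if m not in by_id]
    if missing:
        raise DataError(f"assignment ids missing from profiles: {missing[:5]}")
    return sum(
        1 for m in members if by_id[m].all_codes() == frozenset({PARACETAMOL})
    )


def _covariate_tables(covariates: pd.DataFrame, assignment: ClusterAssignment):
    cov = covariates.set_index("pregnancy_id") if "pregnancy_id" in covariates.columns else covariates
    label_of = assignment.as_dict()
    # covariate rows for pregnancies outside the assignment are ignored
    cov = cov.loc[[i for i in cov.index if str(i) in label_of]]
    clusters = pd.Series([label_of[str(i)] for i in cov.index], index=cov.index)
    count_rows, missing_rows = [], []
    for var in cov.columns:
        col = cov[var]
        for c in range(1, assignment.k + 1):
            sub = col[clusters == c]
            n_missing = int(sub.isna().sum())
            missing_rows.append((var, c, n_missing))
            valid = sub.dropna()
            denom = len(valid)
            for cat, n in valid.value_counts().sort_index().items():
                pct = 100.0 * n / denom if denom else float("nan")
                count_rows.append((var, str(cat), c, int(n), pct))
    counts = pd.DataFrame(
        count_rows, columns=["variable", "category", "cluster", "n", "percent"]
    )
    missing = pd.DataFrame(missing_rows, columns=["variable", "cluster", "n_missing"])
    return counts, missing


def summarize_clusters(
    profiles: Sequence[ExposureProfile],
    assignment: ClusterAssignment,
    covariates: Optional[pd.DataFrame] = None,
    dominance_ratio: float = 2.0,
    min_dominant_share: float = 0.25,
) -> ClusterSummary:
    """Deterministic per-cluster descriptive summary, clusters ordered by label.

    ``covariates`` is an optional one-row-per-pregnancy table with a
    ``pregnancy_id`` column and categorical fields; missing values stay
    out of the percentage denominators.

    A cluster's ``dominant_class`` is the ATC level-2 class holding the
    majority (>= 50%) of its non-paracetamol window-hits, or failing
    that, a class both enriched ``dominance_ratio``-fold over the cohort
    and holding at least ``min_dominant_share`` of the cluster's
    exposure.  Either way the class must average at least 0.1 window-hits
    per member-window, so sparse background use is never flagged.
    """
    by_id = {p.pregnancy_id: p for p in profiles}
    missing = [i for i in assignment.ids if i not in by_id]
    if missing:
        raise DataError(f"assignment ids missing from profiles: {missing[:5]}")
    if set(assignment.ids) != set(by_id):
        extra = sorted(set(by_id) - set(assignment.ids))
        raise DataError(f"profiles not covered by assignment: {extra[:5]}")

    cohort_n = len(profiles)
    cohort_me = float(np.mean([p.mean_exposure() for p in profiles]))
    cohort_class = _class_exposure(profiles)
    cohort_total = sum(cohort_class.values())

    stats = []
    for c in range(1, assignment.k + 1):
        members = assignment.members(c)
        mem_profiles = [by_id[m] for m in members]
        me = float(np.mean([p.mean_exposure() for p in mem_profiles]))
        traj = window_trajectory(mem_profiles)
        cls_counts = _class_exposure(mem_profiles)
        total = sum(cls_counts.values())
        dominant = None
        if total and cohort_total:
            # classes used heavily enough to matter (mean hits/member-window)
            heavy = {
                cls: cnt / total
                for cls, cnt in cls_counts.items()
                if cnt / (len(members) * 10) >= 0.1
            }
            if heavy:
                top = max(heavy, key=lambda cls: (heavy[cls], cls))
                enrichment = heavy[top] / (cohort_class[top] / cohort_total)
                if heavy[top] >= 0.5 or (
                    enrichment >= dominance_ratio and heavy[top] >= min_dominant_share
                ):
                    dominant = top
        stats.append(
            ClusterStats(
                label=c,
                n=len(members),
                percent=100.0 * len(members) / cohort_n,
                mean_exposure=me,
                trajectory=traj,
                paracetamol_only=paracetamol_only_count(profiles, assignment, c),
                dominant_class=dominant,
            )
        )

    cov_counts = cov_missing = None
    if covariates is not None:
        cov_counts, cov_missing = _covariate_tables(covariates, assignment)

    return ClusterSummary(
        clusters=tuple(stats),
        cohort_n=cohort_n,
        cohort_mean_exposure=cohort_me,
        covariate_counts=cov_counts,
        covariate_missing=cov_missing,
    )


def derive_indications_from_atc(profiles: Sequence[ExposureProfile]) -> pd.DataFrame:
    """ATC-derived yes/no proxy indications for synthetic runs.

    Real questionnaire indications come from illness prompts the pipeline
    does not possess; this proxy marks a pregnancy for an indication when
    any reported code falls in the associated ATC classes.
    """
    rows = []
    for p in profiles:
        codes = p.all_codes()
        row = {"pregnancy_id": p.pregnancy_id}
        for ind, prefixes in ATC_INDICATION_PROXIES.items():
            row[ind] = (
                "yes" if any(c.startswith(pre) for c in codes for pre in prefixes) else "no"
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_covariate_table(summary: ClusterSummary, path, delimiter: str = ",") -> None:
    """Cross-tab in the classic cohort-table shape: variable and category
    rows, one N and one % column per cluster (percent to 1 decimal)."""
    if summary.covariate_counts is None:
        raise DataError("summary has no covariate table")
    wide = summary.covariate_counts.pivot_table(
        index=["variable", "category"],
        columns="cluster",
        values=["n", "percent"],
        fill_value=0,
        sort=False,
    )
    k = len(summary.clusters)
    out = pd.DataFrame(index=wide.index)
    for c in range(1, k + 1):
        out[f"cluster{c}_n"] = wide[("n", c)].astype(int)
        out[f"cluster{c}_pct"] = wide[("percent", c)].round(summary.percent_decimals)
    out.reset_index().to_csv(path, sep=delimiter, index=False)


def write_trajectories(summary: ClusterSummary, path, delimiter: str = ",") -> None:
    rows = [
        {"cluster": s.label, **{f"w{w}": s.trajectory[w] for w in range(10)}}
        for s in summary.clusters
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False, float_format="%.6f")


def write_summary(summary: ClusterSummary, path) -> None:
    """Machine-readable structured summary (YAML)."""
    doc = {
        "cohort_n": summary.cohort_n,
        "cohort_mean_exposure": round(summary.cohort_mean_exposure, 6),
        "clusters": [
            {
                "label": s.label,
                "n": s.n,
                "percent": round(s.percent, summary.percent_decimals),
                "mean_exposure": round(s.mean_exposure, 6),
                "paracetamol_only": s.paracetamol_only,
                "dominant_class": s.dominant_class,
                "trajectory": [round(float(v), 6) for v in s.trajectory],
            }
            for s in summary.clusters
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
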