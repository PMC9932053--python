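"""Group comparison statistics across scales and gliding time windows.

Per (metric, scale) cell the workflow is: Tukey-fence outlier removal
within each group, then a two-sided Mann-Whitney U test (exact
enumeration for small tie-free samples, tie-corrected normal
approximation with continuity correction otherwise), then a
multiple-testing adjustment across scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .fluctuation import (
    compute_fluctuation_matrices,
    default_scale_grid,
    scale_correlations,
)
from .trajectory_io import TrajectorySet, as_series_matrix

__all__ = [
    "tukey_fence",
    "mann_whitney",
    "normality_report",
    "adjust_pvalues",
    "MetricSpec",
    "metric_profile",
    "collect_metric_samples",
    "scale_profile",
    "time_scale_map",
]

_EXACT_MAX_N = 8


def tukey_fence(values, k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Remove values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics (the
    numpy default).  Samples with fewer than 4 values are returned
    unfenced with a warning.  Returns ``(kept, removed)``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ParameterError("tukey_fence expects a 1-D sample")
    if values.size < 4:
        warnings.warn(
            f"only {values.size} values; Tukey fencing skipped", stacklevel=2
        )
        return values.copy(), np.empty(0)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], values[~keep]


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Exact enumeration when both samples have at most 8 values and no ties
    are present; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("both groups need at least 2 values")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def normality_report(values) -> dict:
    """Kolmogorov-Smirnov and Shapiro-Wilk normality p-values.

    KS compares against a normal with the sample's own mean/sd.  A
    (near-)constant sample is reported as non-testable (NaN p-values).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ParameterError("normality checks need at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return {"ks_p": float("nan"), "shapiro_p": float("nan"), "testable": False}
    ks = sps.kstest(values, "norm", args=(values.mean(), sd))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for n > 5000
        sw = sps.shapiro(values)
    return {"ks_p": float(ks.pvalue), "shapiro_p": float(sw.pvalue), "testable": True}


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Adjust a vector of p-values ('bonferroni' or 'fdr_bh')."""
    p = np.asarray(p, dtype=float)
    if method not in ("bonferroni", "fdr_bh"):
        raise ParameterError(f"unknown correction method {method!r}")
    ok = np.isfinite(p)
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method=method)[1]
    return out


# ---------------------------------------------------------------------------
# per-animal metric extraction

@dataclass(frozen=True)
class MetricSpec:
    """A scalar per-scale metric of one trajectory set.

    kind: 'R' (cross-correlation coefficient), 'P' (partial coefficient)
    or 'F' (log fluctuation function of series a; series b ignored).
    Same-axis pairs are the *specific* correlations, cross-axis pairs the
    *unspecific* baseline.
    """

    kind: str = "R"
    part_a: str = "front_left"
    axis_a: str = "x"
    part_b: str = "midpoint"
    axis_b: str = "x"

    def __post_init__(self) -> None:
        if self.kind not in ("R", "P", "F"):
            raise ParameterError(f"metric kind must be R, P or F, got {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "F":
            return f"F:{self.part_a}:{self.axis_a}"
        return f"{self.kind}:{self.part_a}:{self.axis_a}|{self.part_b}:{self.axis_b}"

    @property
    def specific(self) -> bool:
        return self.axis_a == self.axis_b


def metric_profile(
    traj: TrajectorySet,
    metric: MetricSpec,
    scales=None,
    order: int = 2,
) -> pd.DataFrame:
    """Evaluate one metric of one animal on a scale grid.

    'R' and 'P' metrics are computed from the full matrix over all parts
    and both axes, so partial coefficients condition on every other
    tracked series.  Returns columns metric, scale_frames, scale_s,
    value.
    """
    labels, series = as_series_matrix(traj)
    if scales is None:
        scales = default_scale_grid(series.shape[1], order=order)
    fm = compute_fluctuation_matrices(
        series, scales=scales, order=order, fps=traj.fps, labels=labels
    )
    la = f"{metric.part_a}:{metric.axis_a}"
    if metric.kind == "F":
        vals = np.log(fm.fluctuations()[:, labels.index(la)])
    else:
        sc = scale_correlations(fm)
        lb = f"{metric.part_b}:{metric.axis_b}"
        vals = sc.pair(metric.kind, la, lb)
    return pd.DataFrame(
        {
            "metric": metric.name,
            "scale_frames": np.asarray(scales, dtype=int),
            "scale_s": np.asarray(scales) / traj.fps,
            "value": vals,
        }
    )


def collect_metric_samples(
    labeled_trajectories,
    metrics,
    scales=None,
    order: int = 2,
) -> pd.DataFrame:
    """Tidy per-animal metric table for a labelled cohort.

    ``labeled_trajectories`` is an iterable of (group_label,
    TrajectorySet); returns columns group, animal, metric, scale_frames,
    scale_s, value.
    """
    frames = []
    for group, traj in labeled_trajectories:
        labels, series = as_series_matrix(traj)
        grid = (
            default_scale_grid(series.shape[1], order=order)
            if scales is None
            else scales
        )
        fm = compute_fluctuation_matrices(
            series, scales=grid, order=order, fps=traj.fps, labels=labels
        )
        sc = None
        for metric in metrics:
            la = f"{metric.part_a}:{metric.axis_a}"
            if metric.kind == "F":
                vals = np.log(fm.fluctuations()[:, labels.index(la)])
            else:
                if sc is None:
                    sc = scale_correlations(fm)
                vals = sc.pair(metric.kind, la, f"{metric.part_b}:{metric.axis_b}")
            frames.append(
                pd.DataFrame(
                    {
                        "group": group,
                        "animal": traj.animal_id,
                        "metric": metric.name,
                        "scale_frames": np.asarray(grid, dtype=int),
                        "scale_s": np.asarray(grid) / traj.fps,
                        "value": vals,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# scale profiles and time-scale maps

def scale_profile(
    samples: pd.DataFrame,
    group_a: str = "test",
    group_b: str = "control",
    fence_k: float = 1.5,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-scale group comparison of a tidy metric sample table.

    ``samples`` needs columns group, animal, metric, scale_frames,
    value (scale_s optional).  Within every (metric, scale) cell values
    outside the Tukey fence of the pooled sample are removed from both
    groups, the remainder is tested, and p-values are adjusted across
    scales within each metric.
    """
    required = {"group", "animal", "metric", "scale_frames", "value"}
    if not required.issubset(samples.columns):
        raise ParameterError(
            f"samples table must have columns {sorted(required)}"
        )
    groups = set(samples["group"])
    if not {group_a, group_b}.issubset(groups):
        raise ParameterError(
            f"need both groups {group_a!r} and {group_b!r}; found {sorted(groups)}"
        )
    rows = []
    for (metric, scale), cell in samples.groupby(["metric", "scale_frames"]):
        va = cell.loc[cell["group"] == group_a, "value"].to_numpy()
        vb = cell.loc[cell["group"] == group_b, "value"].to_numpy()
        if va.size < 2 or vb.size < 2:
            raise ParameterError(
                f"metric {metric!r} at scale {scale}: group sizes "
                f"{va.size}/{vb.size} too small (need >= 2)"
            )
        # fencing is label-blind: bounds come from the pooled sample, so
        # under the null the retained values stay exchangeable and the
        # rank test keeps its level (per-group fencing is anti-conservative
        # at these sample sizes)
        pooled = np.concatenate([va, vb])
        if pooled.size >= 4:
            q1, q3 = np.percentile(pooled, [25, 75])
            lo, hi = q1 - fence_k * (q3 - q1), q3 + fence_k * (q3 - q1)
            ka, ra = va[(va >= lo) & (va <= hi)], va[(va < lo) | (va > hi)]
            kb, rb = vb[(vb >= lo) & (vb <= hi)], vb[(vb < lo) | (vb > hi)]
            if ka.size < 2 or kb.size < 2:  # pathological cell; keep all
                ka, ra = va, np.empty(0)
                kb, rb = vb, np.empty(0)
        else:
            ka, ra = va, np.empty(0)
            kb, rb = vb, np.empty(0)
        u, p = mann_whitney(ka, kb)
        scale_s = (
            float(cell["scale_s"].iloc[0]) if "scale_s" in cell else float("nan")
        )
        rows.append(
            dict(
                metric=metric,
                scale_frames=int(scale),
                scale_s=scale_s,
                U=u,
                p=p,
                n_test=int(ka.size),
                n_control=int(kb.size),
                outliers_test=int(ra.size),
                outliers_control=int(rb.size),
            )
        )
    out = pd.DataFrame(rows).sort_values(["metric", "scale_frames"])
    out["p_adj"] = np.nan
    for metric, idx in out.groupby("metric").groups.items():
        out.loc[idx, "p_adj"] = adjust_pvalues(
            out.loc[idx, "p"].to_numpy(), method=correction
        )
    return out.reset_index(drop=True)


def time_scale_map(
    labeled_trajectories,
    metric: MetricSpec,
    window_seconds: float = 30.0,
    step_fraction: float = 0.5,
    scales=None,
    order: int = 2,
    fence_k: float = 1.5,
    correction: str = "bonferroni",
    group_a: str = "test",
    group_b: str = "control",
) -> pd.DataFrame:
    """Gliding-window group comparison in time-scale coordinates.

    The metric is recomputed per animal inside every window (default
    30 s, 50% overlap); each (window, scale) cell is fenced and tested.
    Scales above window/3 are truncated with a warning.  Returns a long
    table with columns window_index, window_start_s, scale_frames,
    scale_s, p, p_adj (adjustment across all cells), group sizes.
    """
    labeled_trajectories = list(labeled_trajectories)
    if not labeled_trajectories:
        raise ParameterError("no trajectories supplied")
    fps = labeled_trajectories[0][1].fps
    win = int(round(window_seconds * fps))
    n_min = min(t.n_frames for _, t in labeled_trajectories)
    if n_min < win:
        raise ParameterError(
            f"recordings ({n_min} frames) are shorter than one "
            f"{window_seconds:g}-s window"
        )
    if n_min < 2 * win:
        warnings.warn(
            "recording covers fewer than two windows; the time-scale map "
            "degenerates to a single scale profile",
            stacklevel=2,
        )
    if scales is None:
        scales = default_scale_grid(win, order=order, s_max=win // 3)
    scales = np.asarray(scales, dtype=int)
    if scales.max() > win // 3:
        warnings.warn(
            f"scales above window/3 = {win // 3} frames truncated", stacklevel=2
        )
        scales = scales[scales <= win // 3]
    if scales.size == 0:
        raise ParameterError("no usable scales below window/3")
    step = max(1, int(round(win * step_fraction)))
    starts = list(range(0, n_min - win + 1, step))

    frames = []
    for wi, start in enumerate(starts):
        sub_samples = collect_metric_samples(
            (
                (g, t.slice_frames(start, start + win))
                for g, t in labeled_trajectories
            ),
            [metric],
            scales=scales,
            order=order,
        )
        prof = scale_profile(
            sub_samples,
            group_a=group_a,
            group_b=group_b,
            fence_k=fence_k,
            correction="bonferroni",  # replaced by a global adjustment below
        )
        prof["window_index"] = wi
        prof["window_start_s"] = start / fps
        frames.append(prof.drop(columns=["p_adj"]))
    out = pd.concat(frames, ignore_index=True)
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method=correction)
    cols = [
        "window_index",
        "window_start_s",
        "metric",
        "scale_frames",
        "scale_s",
        "U",
        "p",
        "p_adj",
        "n_test",
        "n_control",
        "outliers_test",
        "outliers_control",
    ]
    return out[cols]


def plot_time_scale_map(grid: pd.DataFrame, path, value: str = "p") -> None:
    """Optional PNG heatmap of a :func:`time_scale_map` grid (log10 p)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = grid.pivot_table(index="scale_s", columns="window_start_s", values=value)
    fig, ax = plt.subplots(figsize=(8, 5))
    mesh = ax.pcolormesh(
        pivot.columns, pivot.index, np.log10(pivot.to_numpy()), cmap="viridis_r"
    )
    ax.set_yscale("log")
    ax.set_xlabel("window start [s]")
    ax.set_ylabel("scale [s]")
    fig.colorbar(mesh, ax=ax, label=f"log10 {value}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
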