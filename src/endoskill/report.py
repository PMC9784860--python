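"""Session scorecards, group comparison and report output.

``score_session`` runs all four metrics on one recorded trial and returns a
:class:`SessionScorecard`.  ``compare_groups`` reproduces the study's
statistical protocol: per-group Kolmogorov–Smirnov normality check at
alpha = 0.05, then an unpaired two-tailed t-test with significance declared
at p < 0.01 (Welch's variant by default; pooled-variance and Wilcoxon
rank-sum available).  ``movement_histogram`` bins the per-interval coverage
values (the scope-speed distribution) and fits a normal by maximum
likelihood for the velocity-distribution figure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig, StatsConfig
from .errors import ComputationError
from .exposure import ExposureTrace, visualization
from .motion import MotionTrace, fine_movement
from .tasks import SessionAnnotation, duration_score, efficiency, target_detection
from .video_io import FrameStream, open_stream

METRICS = ("target_detection", "fine_movement", "visualization", "efficiency")


@dataclass(frozen=True)
class SessionScorecard:
    """The four skill scores for one session."""

    session_id: str
    group: str
    trial_index: int
    target_detection: float
    fine_movement: float
    visualization: float
    efficiency: float
    session_time_min: float
    duration_score: float      # clamped Duration component
    duration_raw: float        # unclamped, for transparency
    efficiency_sum: float      # raw TD + Duration, for transparency

    def metric(self, name: str) -> float:
        if name not in METRICS:
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScoredSession:
    """Scorecard plus the per-frame traces that produced it."""

    scorecard: SessionScorecard
    motion_trace: MotionTrace
    exposure_trace: ExposureTrace


def score_session(video: "FrameStream | str | Path",
                  annotation: "SessionAnnotation | str | Path",
                  cfg: RunConfig | None = None) -> ScoredSession:
    """Score one session end to end; deterministic given inputs and config."""
    cfg = cfg or RunConfig()
    if not isinstance(video, FrameStream):
        video = open_stream(video, fps=None)
    if not isinstance(annotation, SessionAnnotation):
        annotation = SessionAnnotation.from_json(annotation)

    motion_trace = fine_movement(video, cfg.motion)
    exposure_trace = visualization(video, cfg.exposure)
    td = target_detection(annotation)
    t_min = annotation.session_time_min
    dur = duration_score(t_min, cfg.efficiency)
    raw_cfg = cfg.efficiency.model_copy(update={"clamp_negative": False})
    dur_raw = duration_score(t_min, raw_cfg)
    eff = efficiency(td, dur)

    card = SessionScorecard(
        session_id=annotation.session_id,
        group=annotation.subject_group,
        trial_index=annotation.trial_index,
        target_detection=td,
        fine_movement=motion_trace.session_score,
        visualization=exposure_trace.session_score,
        efficiency=eff,
        session_time_min=t_min,
        duration_score=dur,
        duration_raw=dur_raw,
        efficiency_sum=td + dur,
    )
    return ScoredSession(scorecard=card, motion_trace=motion_trace,
                         exposure_trace=exposure_trace)


def scorecards_to_frame(cards: Iterable[SessionScorecard]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in cards])


def write_scorecards(cards: Sequence[SessionScorecard], path: str | Path) -> None:
    path = Path(path)
    df = scorecards_to_frame(cards)
    if path.suffix == ".json":
        path.write_text(json.dumps([c.to_dict() for c in cards], indent=2))
    else:
        df.to_csv(path, index=False)


def read_scorecards(path: str | Path) -> list[SessionScorecard]:
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict(orient="records")
    return [SessionScorecard(**row) for row in rows]


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of one metric."""

    metric: str
    groups: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    stds: tuple[float, float]
    normality_p: tuple[float, float]
    normal: tuple[bool, bool]
    statistic: float
    p_value: float
    significant: bool
    test: str

    def to_dict(self) -> dict:
        return asdict(self)


def _normality_p(values: np.ndarray, method: str) -> float:
    # KS against a normal with sample-estimated parameters; approximate
    # unless the Lilliefors correction is requested.
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors
        return float(lilliefors(values, dist="norm")[1])
    return float(stats.kstest(values, "norm",
                              args=(values.mean(), sd)).pvalue)


def compare_groups(cards: Sequence[SessionScorecard], metric: str,
                   cfg: StatsConfig | None = None) -> GroupComparison:
    """Compare one metric between the two subject groups.

    Requires at least two sessions per group.  With identical samples in
    both groups the t statistic is 0 and p = 1.
    """
    cfg = cfg or StatsConfig()
    by_group: dict[str, list[float]] = {}
    for card in cards:
        by_group.setdefault(card.group, []).append(card.metric(metric))
    if len(by_group) != 2:
        raise ComputationError(
            f"need exactly two groups, got {sorted(by_group)}")
    names = tuple(sorted(by_group))
    a = np.asarray(by_group[names[0]], dtype=float)
    b = np.asarray(by_group[names[1]], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ComputationError("each group needs at least two sessions")

    if cfg.test == "ranksum":
        res = stats.ranksums(a, b)
    else:
        if np.array_equal(a, b):
            # identical samples: zero difference, no evidence
            res = type("R", (), {"statistic": 0.0, "pvalue": 1.0})()
        else:
            with warnings.catch_warnings():
                # a zero-variance group (e.g. every trial detecting 3/3)
                # triggers scipy's precision-loss warning; the test result
                # is still the correct degenerate one
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(a, b, equal_var=(cfg.test == "pooled"))

    p_norm = (_normality_p(a, cfg.normality), _normality_p(b, cfg.normality))
    return GroupComparison(
        metric=metric,
        groups=names,
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        stds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        normality_p=p_norm,
        normal=(p_norm[0] > cfg.alpha, p_norm[1] > cfg.alpha),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < cfg.p_threshold),
        test=cfg.test,
    )


def comparison_table(cards: Sequence[SessionScorecard],
                     cfg: StatsConfig | None = None,
                     metrics: Sequence[str] = METRICS) -> pd.DataFrame:
    rows = []
    for m in metrics:
        comp = compare_groups(cards, m, cfg)
        rows.append({
            "metric": m,
            "group_a": comp.groups[0], "group_b": comp.groups[1],
            "n_a": comp.n[0], "n_b": comp.n[1],
            "mean_a": comp.means[0], "mean_b": comp.means[1],
            "sd_a": comp.stds[0], "sd_b": comp.stds[1],
            "normality_p_a": comp.normality_p[0],
            "normality_p_b": comp.normality_p[1],
            "statistic": comp.statistic,
            "p_value": comp.p_value,
            "significant": comp.significant,
            "test": comp.test,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# movement-velocity histogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistogramFit:
    """Binned coverage distribution with an ML normal fit."""

    counts: np.ndarray
    bin_edges: np.ndarray
    mean: float
    std: float
    n_samples: int
    degenerate: bool = field(default=False)  # all samples equal; SD is 0


def movement_histogram(traces: Sequence[MotionTrace],
                       bins: int = 30,
                       range_: tuple[float, float] | None = None) -> HistogramFit:
    """Pool per-interval coverages across traces, bin them, fit a normal."""
    if not traces:
        raise ComputationError("no motion traces to histogram")
    values = np.concatenate([t.coverages for t in traces])
    counts, edges = np.histogram(values, bins=bins, range=range_)
    mu, sd = stats.norm.fit(values)
    return HistogramFit(counts=counts, bin_edges=edges,
                        mean=float(mu), std=float(sd),
                        n_samples=values.size, degenerate=bool(sd == 0.0))


# ---------------------------------------------------------------------------
# plots (pure presentation: no metric recomputation)
# ---------------------------------------------------------------------------

def plot_group_bars(cards: Sequence[SessionScorecard], path: str | Path,
                    cfg: StatsConfig | None = None) -> None:
    """Grouped bar chart of the four metrics with SD error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scorecards_to_frame(cards)
    groups = sorted(df["group"].unique())
    x = np.arange(len(METRICS))
    width = 0.8 / len(groups)
    fig, ax = plt.subplots(figsize=(7, 4))
    for gi, g in enumerate(groups):
        sub = df[df["group"] == g]
        means = [sub[m].mean() for m in METRICS]
        sds = [sub[m].std(ddof=1) if len(sub) > 1 else 0.0 for m in METRICS]
        ax.bar(x + gi * width, means, width, yerr=sds, capsize=4, label=g)
    ax.set_xticks(x + width * (len(groups) - 1) / 2)
    ax.set_xticklabels([m.replace("_", " ") for m in METRICS])
    ax.set_ylabel("score (%)")
    ax.set_ylim(0, 110)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_motion_trace(trace: MotionTrace, path: str | Path,
                      label: str = "") -> None:
    """Coverage-vs-time curve (the scope-velocity curve)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot([s.timestamp for s in trace.samples], trace.coverages, lw=1.2,
            label=label or None)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("coverage $A_i$ (%)")
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_histogram(fit: HistogramFit, path: str | Path,
                   label: str = "") -> None:
    """Histogram of coverages with the fitted normal overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (fit.bin_edges[1:] + fit.bin_edges[:-1])
    widths = np.diff(fit.bin_edges)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(centers, fit.counts, width=widths, alpha=0.6, label=label or None)
    if not fit.degenerate:
        xs = np.linspace(fit.bin_edges[0], fit.bin_edges[-1], 200)
        pdf = stats.norm.pdf(xs, fit.mean, fit.std)
        ax.plot(xs, pdf * fit.n_samples * widths.mean(), "r-",
                label=f"N({fit.mean:.1f}, {fit.std:.1f}²)")
    ax.set_xlabel("coverage $A_i$ (%)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
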