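"""Inter-model aggregation and method comparison.

Per-frame scores from several segmentation models and several
preprocessing methods are pooled into a long-format panel.  For a metric
``m`` and a method ``filt``:

* inter-model performance = mean over models of the per-model mean score;
* inter-model variability = standard deviation across the per-model means
  (population divisor — the model means *are* the population).

Method-by-metric matrices of these aggregates are min-max normalized per
metric so the best method maps to 1 and the worst to 0, with distance
metrics (HD, ASD) first replaced by their reciprocals so every column
shares a "higher is better" scale.  Pairwise method comparisons use the
two-sided Wilcoxon rank-sum (Mann-Whitney) test at p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .seg_metrics import HIGHER_IS_BETTER

PANEL_COLUMNS = ("model", "method", "metric", "frame_id", "value")
DISTANCE_METRICS = frozenset({"HD", "ASD"})


class IncompletePanelError(ValueError):
    """A model has no records for the requested (metric, method) cell."""


class InsufficientDataError(ValueError):
    """Too few per-frame scores for a statistical comparison."""


@dataclass
class ScorePanel:
    """Long-format per-frame records (model, method, metric, frame_id, value)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = set(PANEL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"panel is missing columns {sorted(missing)}")
        keys = ["model", "method", "metric", "frame_id"]
        if df.duplicated(subset=keys).any():
            raise ValueError("duplicate (model, method, metric, frame_id) keys")
        self.records = df.reset_index(drop=True)

    @property
    def models(self) -> list[str]:
        return sorted(self.records["model"].unique())

    @property
    def methods(self) -> list[str]:
        return sorted(self.records["method"].unique())

    @property
    def metrics(self) -> list[str]:
        return sorted(self.records["metric"].unique())

    def select(self, **eq) -> pd.DataFrame:
        df = self.records
        for col, val in eq.items():
            df = df[df[col] == val]
        return df

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScorePanel":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class AggregateMatrix:
    """Methods x metrics matrix of aggregate values."""

    table: pd.DataFrame  # rows: methods, cols: metrics
    normalized: bool = False


def _model_means(panel: ScorePanel, metric: str, method: str) -> pd.Series:
    sub = panel.select(metric=metric, method=method)
    present = set(sub["model"].unique())
    absent = set(panel.models) - present
    if absent:
        raise IncompletePanelError(
            f"models {sorted(absent)} have no records for ({metric}, {method})")
    return sub.groupby("model")["value"].mean()


def aggregate_performance(panel: ScorePanel, metric: str, method: str) -> float:
    """Mean over models of the per-model mean score."""
    return float(_model_means(panel, metric, method).mean())


def aggregate_variability(panel: ScorePanel, metric: str, method: str,
                          sample: bool = False) -> float:
    """Standard deviation across the per-model means.

    Population divisor N by default (the model means are the whole
    population); ``sample=True`` switches to the N-1 divisor.
    """
    means = _model_means(panel, metric, method)
    if len(means) < 2:
        raise InsufficientDataError("variability needs >= 2 models")
    return float(means.std(ddof=1 if sample else 0))


def aggregate_matrix(panel: ScorePanel, kind: str = "performance") -> AggregateMatrix:
    """Methods x metrics matrix of inter-model performance or variability."""
    agg = {"performance": aggregate_performance, "variability": aggregate_variability}[kind]
    table = pd.DataFrame(
        {m: {f: agg(panel, m, f) for f in panel.methods} for m in panel.metrics}
    )
    return AggregateMatrix(table=table, normalized=False)


def normalize_for_heatmap(
    matrix: AggregateMatrix,
    distance_metrics: frozenset[str] = DISTANCE_METRICS,
    kind: str = "performance",
    eps: float = 1e-12,
) -> AggregateMatrix:
    """Min-max normalize each metric column for heatmap display.

    For performance matrices, distance metrics are first replaced by
    their reciprocals (guarded by ``eps`` against zero distances) so that
    larger is better everywhere; each column is then scaled so the best
    method maps to 1 and the worst to 0 (lower-is-better columns such as
    REI are inverted).  For variability matrices a plain min-max puts the
    lowest variability at 0.  Constant columns map to all 0.
    """
    table = matrix.table.astype(float).copy()
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if kind == "performance":
            higher_better = HIGHER_IS_BETTER.get(col, True)
            if col in distance_metrics:
                x = 1.0 / np.maximum(x, eps)
                higher_better = True
        else:
            higher_better = True  # raw spread; lowest maps to 0
        lo, hi = x.min(), x.max()
        if hi == lo:
            table[col] = 0.0
            continue
        scaled = (x - lo) / (hi - lo)
        table[col] = scaled if higher_better else 1.0 - scaled
    return AggregateMatrix(table=table, normalized=True)


def wilcoxon_compare(
    panel: ScorePanel,
    model: str,
    metric: str,
    method_a: str,
    method_b: str,
    alpha: float = 0.05,
    min_frames: int = 5,
) -> dict:
    """Two-sided rank-sum comparison of two methods' per-frame scores.

    Returns ``{"p_value", "flag"}`` where the flag is ``"a_better"`` when
    p <= alpha and method_a's mean is favorable for the metric's direction
    (higher for overlap metrics, lower for distances/REI), ``"b_better"``
    symmetrically, else ``"ns"``.  The exact null distribution is used for
    small tie-free samples (< 8 per group), otherwise the normal
    approximation with tie correction.
    """
    a = panel.select(model=model, metric=metric, method=method_a)["value"].to_numpy()
    b = panel.select(model=model, metric=metric, method=method_b)["value"].to_numpy()
    if len(a) < min_frames or len(b) < min_frames:
        raise InsufficientDataError(
            f"need >= {min_frames} frames per method; got {len(a)} and {len(b)}")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return {"p_value": 1.0, "flag": "ns"}
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) < 8 and not has_ties) else "asymptotic"
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    flag = "ns"
    if p <= alpha:
        a_high = a.mean() > b.mean()
        a_favorable = a_high if HIGHER_IS_BETTER.get(metric, True) else not a_high
        flag = "a_better" if a_favorable else "b_better"
    return {"p_value": p, "flag": flag}


def compare_method_against_all(
    panel: ScorePanel, reference_method: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Rank-sum flags of a reference method vs every other method, per
    (model, metric) — the significance markers of a results table."""
    rows = []
    for model in panel.models:
        for metric in panel.metrics:
            for other in panel.methods:
                if other == reference_method:
                    continue
                res = wilcoxon_compare(panel, model, metric, reference_method, other, alpha)
                rows.append({"model": model, "metric": metric,
                             "vs_method": other, **res})
    return pd.DataFrame(rows)


def heatmap_figure(perf: AggregateMatrix, var: AggregateMatrix | None = None,
                   path: str | Path | None = None):
    """Render normalized performance (and optionally variability) matrices."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mats = [("Inter-model performance", perf)]
    if var is not None:
        mats.append(("Inter-model variability", var))
    fig, axes = plt.subplots(1, len(mats), figsize=(6 * len(mats), 4), squeeze=False)
    for ax, (title, mat) in zip(axes[0], mats):
        im = ax.imshow(mat.table.to_numpy(), cmap="viridis", vmin=0, vmax=1, aspect="auto")
        ax.set_xticks(range(len(mat.table.columns)), mat.table.columns)
        ax.set_yticks(range(len(mat.table.index)), mat.table.index)
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
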