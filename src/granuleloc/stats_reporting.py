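"""Statistical comparisons and tabular/graphical reports.

Transcript metrics are compared against a control transcript with
two-sample Welch t-tests per (transcript, stage, metric), adjusted for
multiple testing across the comparison family (Benjamini-Hochberg by
default; Holm and Bonferroni selectable).  Significance stars follow the
convention NS > 0.05 > * > 0.005 > ** > 0.0005 > *** > 0.00005 > ****.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "welch_test",
    "significance_stars",
    "compare_vs_control",
    "render_report",
]

_ADJUST_METHODS = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}


@dataclass
class ComparisonResult:
    metric: str
    stage: str
    group_a: str
    group_b: str
    t_statistic: float
    raw_p: float
    adjusted_p: float
    n_a: int
    n_b: int
    stars: str = "NS"
    degenerate: bool = False


def welch_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, bool]:
    """Welch two-sample t-test with Satterthwaite degrees of freedom.

    Returns ``(t, p, degenerate)``.  When both samples have zero variance
    the statistic is undefined; p = 1 is reported with the degenerate
    flag set (identical constant groups carry no evidence either way).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 0.0, 1.0, True
    t, p = ttest_ind(a, b, equal_var=False)
    return float(t), float(p), False


def significance_stars(p: float) -> str:
    """Map an adjusted p-value to the star convention used in figures."""
    if p > 0.05:
        return "NS"
    if p > 0.005:
        return "*"
    if p > 0.0005:
        return "**"
    if p > 0.00005:
        return "***"
    return "****"


def compare_vs_control(
    samples: Mapping[tuple[str, str, str], Sequence[float]],
    control: str,
    adjust: str = "bh",
) -> list[ComparisonResult]:
    """Welch t-tests of every (transcript, stage, metric) cell vs control.

    ``samples`` maps ``(transcript, stage, metric)`` to per-embryo metric
    values.  Each non-control cell is tested against the control
    transcript's cell at the same stage and metric; p-values are adjusted
    across the whole family of comparisons (one figure-equivalent batch).
    The adjustment is order-invariant.
    """
    if adjust not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {adjust!r}; choose from {sorted(_ADJUST_METHODS)}")
    comparisons: list[ComparisonResult] = []
    raw_ps: list[float] = []
    keys = sorted(k for k in samples if k[0] != control)
    for transcript, stage, metric in keys:
        ctrl_key = (control, stage, metric)
        if ctrl_key not in samples:
            continue
        a = np.asarray(samples[(transcript, stage, metric)], dtype=float)
        b = np.asarray(samples[ctrl_key], dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        t, p, degenerate = welch_test(a, b)
        comparisons.append(
            ComparisonResult(
                metric=metric,
                stage=stage,
                group_a=transcript,
                group_b=control,
                t_statistic=t,
                raw_p=p,
                adjusted_p=p,
                n_a=len(a),
                n_b=len(b),
                degenerate=degenerate,
            )
        )
        raw_ps.append(p)
    if raw_ps:
        _, adj, _, _ = multipletests(raw_ps, method=_ADJUST_METHODS[adjust])
        for c, q in zip(comparisons, adj):
            c.adjusted_p = float(max(q, c.raw_p))
            c.stars = significance_stars(c.adjusted_p)
    return comparisons


def comparisons_to_frame(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    cols = [
        "metric",
        "stage",
        "group_a",
        "group_b",
        "t_statistic",
        "raw_p",
        "adjusted_p",
        "n_a",
        "n_b",
        "stars",
        "degenerate",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in comparisons], columns=cols)


def render_report(
    out_dir: str | Path,
    per_embryo: Optional[pd.DataFrame] = None,
    aggregate: Optional[pd.DataFrame] = None,
    comparisons: Optional[Sequence[ComparisonResult]] = None,
    make_plots: bool = True,
) -> list[Path]:
    """Write tab-delimited report tables and mean ± s.d. per-stage plots.

    Deterministic: re-running on identical inputs produces byte-identical
    tables.  Empty inputs yield empty-but-valid (header-only) files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if per_embryo is None:
        per_embryo = pd.DataFrame()
    path = out_dir / "per_embryo.tsv"
    per_embryo.to_csv(path, sep="\t", index=False, float_format="%.6g")
    written.append(path)

    if aggregate is None:
        aggregate = pd.DataFrame(columns=["transcript", "stage_bin", "metric", "mean", "sd", "n_embryos"])
    path = out_dir / "aggregate.tsv"
    aggregate.to_csv(path, sep="\t", index=False, float_format="%.6g")
    written.append(path)

    comp_df = comparisons_to_frame(comparisons or [])
    path = out_dir / "comparisons.tsv"
    comp_df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    written.append(path)

    if make_plots and len(aggregate):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for metric, sub in aggregate.groupby("metric"):
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for transcript, tsub in sub.groupby("transcript"):
                x = np.arange(len(tsub))
                ax.plot(x, tsub["mean"], marker="o", label=str(transcript))
                ax.fill_between(
                    x,
                    tsub["mean"] - tsub["sd"],
                    tsub["mean"] + tsub["sd"],
                    alpha=0.25,
                )
                ax.set_xticks(x)
                ax.set_xticklabels(tsub["stage_bin"], rotation=45)
            ax.set_xlabel("stage (nuclei)")
            ax.set_ylabel(str(metric))
            ax.legend(fontsize=7)
            fig.tight_layout()
            ppath = out_dir / f"stage_{metric}.png"
            fig.savefig(ppath, dpi=120)
            plt.close(fig)
            written.append(ppath)
    return written
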