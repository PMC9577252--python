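"""Differential expression across flowering stages and qPCR validation.

Stage contrasts are tested with a two-sample t-test on
log2(FPKM + pseudocount) across replicates, with Benjamini-Hochberg
adjustment across all transcripts within a contrast. The default is the
pooled-variance (Student) test: with three replicates per stage the Welch
correction collapses the degrees of freedom toward two and costs most of the
power at realistic effect sizes, while group variances on the log scale are
comparable by construction. Welch remains available via ``equal_var=False``. A transcript is called up (down) when log2 fold change is
>= 1 (<= -1) and the adjusted p-value is < 0.05; the boundary |log2FC| = 1
counts as passing. Transcripts whose stage-mean expression stays below a
floor (default 0.5) in every stage are excluded as unexpressed. A "core"
lncRNA is one called in both successive contrasts; its temporal pattern is
up_down, down_up, or other.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

DEFAULT_CONTRASTS = (("EF", "SF"), ("SF", "LF"))


def _contrast_name(stage_a: str, stage_b: str) -> str:
    return f"{stage_a}_vs_{stage_b}"


def call_de(
    expr: ExpressionMatrix,
    contrast: tuple[str, str],
    pseudocount: float = 0.01,
    cultivar: Optional[str] = None,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Call differential expression between two stages.

    Returns a DataFrame with columns transcript_id, contrast, log2fc, p,
    p_adj, direction. log2fc = log2((mean_b + eps) / (mean_a + eps)) on the
    FPKM scale; the test is a two-sample t on log2(value + eps) per
    replicate (pooled variance by default; ``equal_var=False`` for Welch).
    Requires >= 2 replicates per stage.
    """
    stage_a, stage_b = contrast
    cols_a = expr.samples_for(stage=stage_a, cultivar=cultivar)
    cols_b = expr.samples_for(stage=stage_b, cultivar=cultivar)
    if not cols_a or not cols_b:
        raise ValueError(f"missing samples for contrast {stage_a} vs {stage_b}")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("call_de needs >= 2 replicates per stage")

    a = expr.values[cols_a].to_numpy(float)
    b = expr.values[cols_b].to_numpy(float)
    eps = pseudocount
    log2fc = np.log2((b.mean(axis=1) + eps) / (a.mean(axis=1) + eps))

    la, lb = np.log2(a + eps), np.log2(b + eps)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows trigger scipy's precision-loss warning; their
        # p-values are overwritten below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        _t, p = stats.ttest_ind(lb, la, axis=1, equal_var=equal_var)
    p = np.asarray(p, float)
    # zero variance in both groups: p undefined; identical means are null,
    # different means with zero spread are treated as maximally significant
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0

    p_adj = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        (log2fc >= fc_threshold) & (p_adj < alpha),
        "up",
        np.where((log2fc <= -fc_threshold) & (p_adj < alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "transcript_id": expr.values.index,
            "contrast": _contrast_name(stage_a, stage_b),
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    ).reset_index(drop=True)


def call_de_all(
    expr: ExpressionMatrix,
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
    **kwargs,
) -> pd.DataFrame:
    return pd.concat(
        [call_de(expr, c, **kwargs) for c in contrasts], ignore_index=True
    )


def expression_floor(
    transcript_ids: Iterable[str],
    expr: ExpressionMatrix,
    floor: float = 0.5,
    cultivar: Optional[str] = None,
) -> tuple[list[str], list[str]]:
    """Split ids into (retained, excluded) by the expression floor.

    A transcript is excluded iff its stage-mean expression is below the
    floor in *every* stage (AND semantics: one stage at or above the floor
    retains it).
    """
    ids = [t for t in transcript_ids]
    stage_means = {}
    for stage in expr.stages:
        cols = expr.samples_for(stage=stage, cultivar=cultivar)
        stage_means[stage] = expr.values.loc[ids, cols].mean(axis=1)
    means = pd.DataFrame(stage_means)
    below_everywhere = (means < floor).all(axis=1)
    retained = list(means.index[~below_everywhere])
    excluded = list(means.index[below_everywhere])
    return retained, excluded


def core_lncRNAs(
    de_results: pd.DataFrame,
    contrast_1: str = "EF_vs_SF",
    contrast_2: str = "SF_vs_LF",
) -> pd.DataFrame:
    """Identify core transcripts: differentially expressed in both contrasts.

    Pattern is up_down when up in the first contrast and down in the second,
    down_up for the reverse, other for any remaining core combination.
    Returns DataFrame (transcript_id, pattern).
    """
    wide = de_results.pivot(
        index="transcript_id", columns="contrast", values="direction"
    )
    for c in (contrast_1, contrast_2):
        if c not in wide.columns:
            raise ValueError(f"contrast {c!r} absent from DE results")
    d1, d2 = wide[contrast_1], wide[contrast_2]
    core = wide.index[(d1 != "ns") & (d2 != "ns") & d1.notna() & d2.notna()]
    patterns = []
    for tid in core:
        if d1[tid] == "up" and d2[tid] == "down":
            patterns.append("up_down")
        elif d1[tid] == "down" and d2[tid] == "up":
            patterns.append("down_up")
        else:
            patterns.append("other")
    return pd.DataFrame({"transcript_id": list(core), "pattern": patterns})


# ---------------------------------------------------------------------------
# qPCR validation utilities
# ---------------------------------------------------------------------------


def ddct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative quantity by the 2^-ddCt method.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control); RQ = 2 ** -ddCt.
    """
    delta_delta = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-delta_delta))


def concordance(
    fc_seq: Sequence[float], fc_qpcr: Sequence[float]
) -> tuple[float, float, float]:
    """OLS regression of qPCR fold changes on sequencing fold changes.

    Returns (slope, intercept, R^2). Raises on zero variance in fc_seq.
    """
    x = np.asarray(fc_seq, float)
    y = np.asarray(fc_qpcr, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("concordance needs two equal-length vectors, n >= 3")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in sequencing fold changes")
    result = stats.linregress(x, y)
    return float(result.slope), float(result.intercept), float(result.rvalue**2)
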