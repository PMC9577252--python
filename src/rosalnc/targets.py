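"""Target-gene prediction for lncRNAs: co-location and co-expression.

Cis (co-location): a lncRNA is paired with every protein-coding gene whose
interval lies within a window (default 100 kb, inclusive) of the lncRNA on
the same chromosome; the distance is the gap between the closest interval
edges (0 for overlap) and strand is ignored.

Trans (co-expression): a lncRNA is paired with every gene whose expression
profile correlates with it at Pearson r above a threshold (default 0.95,
signed), computed only when the shared sample count exceeds five.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import Gene, GeneAnnotation, TranscriptModel, ValidationError

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["lnc_id", "gene_id", "mechanism", "distance_bp", "pearson_r"]


@dataclass
class TargetParams:
    window_bp: int = 100_000
    r_threshold: float = 0.95
    min_samples: int = 6  # "more than five" samples
    absolute: bool = False  # rank/threshold on |r| instead of signed r

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be positive")
        if not (0 < self.r_threshold < 1):
            raise ValidationError("r_threshold must lie in (0, 1)")
        if self.min_samples < 3:
            raise ValidationError("min_samples must be >= 3")


def colocate(
    lncRNAs: Sequence[TranscriptModel],
    genes: Union[GeneAnnotation, Sequence[Gene]],
    params: TargetParams = TargetParams(),
) -> pd.DataFrame:
    """Pair each lncRNA with genes within ``window_bp`` on the same chromosome.

    The boundary is inclusive: a gene ending exactly window_bp away is
    paired. Overlapping features pair at distance 0.
    """
    gene_list = genes.protein_coding if isinstance(genes, GeneAnnotation) else list(genes)
    by_chrom: dict[str, list[Gene]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    rows = []
    for lnc in lncRNAs:
        for gene in by_chrom.get(lnc.chrom, []):
            gap = lnc.interval.gap_to(gene.interval)
            if gap is not None and gap <= params.window_bp:
                rows.append(
                    {
                        "lnc_id": lnc.transcript_id,
                        "gene_id": gene.gene_id,
                        "mechanism": "co_location",
                        "distance_bp": gap,
                        "pearson_r": np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def coexpress(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    params: TargetParams = TargetParams(),
) -> pd.DataFrame:
    """Pair lncRNAs with genes by expression correlation.

    ``lnc_expr`` and ``gene_expr`` are feature x sample DataFrames sharing
    sample columns. Pairs are emitted when Pearson r exceeds the threshold
    (signed by default; set ``params.absolute`` to threshold on |r|).
    Constant profiles have undefined correlation and yield no pairs.
    """
    shared = [c for c in lnc_expr.columns if c in set(gene_expr.columns)]
    if len(shared) < params.min_samples:
        raise ValueError(
            f"co-expression prediction needs more than five shared samples "
            f"(>= {params.min_samples}); got {len(shared)}"
        )
    L = lnc_expr[shared].to_numpy(float)
    G = gene_expr[shared].to_numpy(float)

    def _normalize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = M - M.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        constant = norms == 0
        norms[constant] = 1.0
        return centered / norms[:, None], constant

    Ln, l_const = _normalize(L)
    Gn, g_const = _normalize(G)
    if l_const.any() or g_const.any():
        logger.warning(
            "%d constant profiles excluded from co-expression",
            int(l_const.sum() + g_const.sum()),
        )
    R = Ln @ Gn.T
    R[l_const, :] = np.nan
    R[:, g_const] = np.nan

    score = np.abs(R) if params.absolute else R
    idx_l, idx_g = np.where(score > params.r_threshold)
    rows = [
        {
            "lnc_id": lnc_expr.index[i],
            "gene_id": gene_expr.index[j],
            "mechanism": "co_expression",
            "distance_bp": pd.NA,
            "pearson_r": float(R[i, j]),
        }
        for i, j in zip(idx_l, idx_g)
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def predict_targets(
    lncRNAs: Sequence[TranscriptModel],
    genes: Union[GeneAnnotation, Sequence[Gene]],
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    params: TargetParams = TargetParams(),
) -> pd.DataFrame:
    """Both mechanisms, concatenated."""
    return pd.concat(
        [colocate(lncRNAs, genes, params), coexpress(lnc_expr, gene_expr, params)],
        ignore_index=True,
    )


def intersect_gene_lists(
    pairs: pd.DataFrame,
    scent_genes: Iterable[str] = (),
    tf_homologs: Iterable[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate predicted pairs with curated gene lists.

    Pairs are partitioned into scent-synthase-linked, TF-linked and other
    (scent takes precedence when a gene appears in both lists). List ids not
    present among the paired genes are warned about and ignored. Returns
    (annotated pairs, per-lncRNA summary counts).
    """
    scent = {str(g) for g in scent_genes}
    tfs = {str(g) for g in tf_homologs}
    paired_genes = set(pairs["gene_id"].astype(str)) if len(pairs) else set()
    for name, ids in (("scent", scent), ("tf", tfs)):
        unknown = ids - paired_genes
        if unknown:
            logger.warning(
                "%d %s-list ids not among predicted target genes", len(unknown), name
            )
    annotated = pairs.copy()
    if len(annotated):
        gene_ids = annotated["gene_id"].astype(str)
        annotated["group"] = np.where(
            gene_ids.isin(scent), "scent", np.where(gene_ids.isin(tfs), "tf", "other")
        )
    else:
        annotated["group"] = pd.Series(dtype=object)
    summary = (
        annotated.groupby(["lnc_id", "group"]).size().unstack(fill_value=0)
        if len(annotated)
        else pd.DataFrame()
    )
    return annotated, summary
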