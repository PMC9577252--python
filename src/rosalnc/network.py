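"""Weighted co-expression network analysis of lncRNAs against volatiles.

The pipeline follows the classic weighted-network recipe: an unsigned
soft-threshold adjacency a_ij = |cor(x_i, x_j)|^beta, the topological
overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj,   k_i = sum_u a_iu,

average-linkage hierarchical clustering of 1 - TOM, branch cutting with a
deep-split refinement, module eigengenes by PCA, eigengene-similarity
merging, and module-trait correlation against per-sample volatile emission
rates, reporting the top three modules per compound.

Branch cutting here is a documented simplified variant of dynamic tree cut:
a static cut at ``cut_height`` followed by re-cutting each branch at
``cut_height - 0.05 * deep_split``, with clusters below ``min_module_size``
sent to grey. It is validated by planted-module recovery rather than
bit-equivalence with the reference implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ValidationError
from .volatiles import VolatileProfile

logger = logging.getLogger(__name__)

#: module colours in assignment order (largest module first); grey is
#: reserved for unassigned transcripts
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
GREY = "grey"


@dataclass
class NetworkParams:
    power: int = 6
    min_module_size: int = 6
    deep_split: int = 4
    me_diss_thresh: float = 0.15
    merge_cut_height: float = 0.10  # retained alias; merging uses me_diss_thresh
    cut_height: float = 0.99
    min_samples: int = 15

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValidationError("power must be >= 1")
        if not (0 <= self.deep_split <= 4):
            raise ValidationError("deep_split must be in 0..4")
        for name in ("me_diss_thresh", "merge_cut_height", "cut_height"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")


@dataclass
class ModuleAssignment:
    """Transcript -> module colour map with optional eigengenes."""

    labels: dict[str, str]
    eigengenes: Optional[pd.DataFrame] = None  # samples x modules

    @property
    def modules(self) -> list[str]:
        sizes = self.sizes
        return [m for m in sizes.index if m != GREY]

    @property
    def sizes(self) -> pd.Series:
        s = pd.Series(self.labels).value_counts()
        return s

    def members(self, module: str) -> list[str]:
        return [t for t, m in self.labels.items() if m == module]


# ---------------------------------------------------------------------------
# Adjacency and topological overlap
# ---------------------------------------------------------------------------


def adjacency(expr: pd.DataFrame | np.ndarray, power: int = 6) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^power with zero diagonal.

    ``expr`` is features x samples. Constant rows get zero correlation with
    everything (warned).
    """
    X = expr.to_numpy(float) if isinstance(expr, pd.DataFrame) else np.asarray(expr, float)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant rows: correlations set to 0", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.nan_to_num(R, nan=0.0)
    A = np.abs(R) ** power
    np.fill_diagonal(A, 0.0)
    return A


def tom(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency (zero diagonal)."""
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    if A.min() < 0 or A.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    L = A @ A  # diagonal of A is zero, so (A@A)_ij = sum_{u != i,j} a_iu a_uj
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    return T


def tom_dissimilarity(expr: pd.DataFrame, params: NetworkParams = NetworkParams()) -> np.ndarray:
    if expr.shape[1] < params.min_samples:
        raise ValueError(
            f"network analysis needs >= {params.min_samples} samples; "
            f"got {expr.shape[1]}"
        )
    return 1.0 - tom(adjacency(expr, params.power))


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------


def _cut_tree(diss: np.ndarray, height: float) -> np.ndarray:
    condensed = squareform(diss, checks=False)
    Z = linkage(condensed, method="average")
    return fcluster(Z, t=height, criterion="distance")


def detect_modules(
    diss_tom: np.ndarray,
    params: NetworkParams = NetworkParams(),
    ids: Optional[Sequence[str]] = None,
) -> ModuleAssignment:
    """Detect modules from a TOM dissimilarity matrix.

    Average-linkage clustering cut at ``cut_height``, then each branch is
    re-cut at ``cut_height - 0.05 * deep_split``; clusters smaller than
    ``min_module_size`` become grey. Colours are assigned by decreasing
    module size (ties broken by smallest member index).
    """
    n = diss_tom.shape[0]
    if ids is None:
        ids = [f"t{i}" for i in range(n)]
    ids = list(ids)
    if len(ids) != n:
        raise ValidationError("ids length must match matrix size")
    if n < params.min_module_size:
        logger.warning("fewer than min_module_size transcripts: all grey")
        return ModuleAssignment({t: GREY for t in ids})

    diss = np.asarray(diss_tom, float)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)

    branch = _cut_tree(diss, params.cut_height)
    clusters: list[list[int]] = []
    sub_height = params.cut_height - 0.05 * params.deep_split
    for b in np.unique(branch):
        members = np.where(branch == b)[0]
        if params.deep_split > 0 and len(members) > 1:
            sub = _cut_tree(diss[np.ix_(members, members)], sub_height)
            for s in np.unique(sub):
                clusters.append(list(members[sub == s]))
        else:
            clusters.append(list(members))

    keep = [c for c in clusters if len(c) >= params.min_module_size]
    keep.sort(key=lambda c: (-len(c), min(c)))
    labels = {t: GREY for t in ids}
    for rank, members in enumerate(keep):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        for i in members:
            labels[ids[i]] = color
    return ModuleAssignment(labels)


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------


def module_eigengene(expr_subset: pd.DataFrame) -> pd.Series:
    """First principal component of the standardized member x sample matrix.

    Scaled to unit variance and sign-oriented so the average correlation
    with member profiles is positive (ties orient toward the first member).
    """
    if expr_subset.shape[0] < 2:
        raise ValueError("eigengene needs >= 2 members")
    X = expr_subset.to_numpy(float)
    sd = X.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    if not np.any(Z):
        raise ValueError("rank-0 member matrix")
    _u, _s, vt = np.linalg.svd(Z, full_matrices=False)
    me = vt[0]
    me_sd = me.std(ddof=1)
    if me_sd > 0:
        me = (me - me.mean()) / me_sd
    cors = _row_correlations(Z, me)
    mean_cor = np.nanmean(cors)
    if mean_cor < 0 or (mean_cor == 0 and cors[0] < 0):
        me = -me
    return pd.Series(me, index=expr_subset.columns)


def _row_correlations(Z: np.ndarray, v: np.ndarray) -> np.ndarray:
    vc = v - v.mean()
    vn = np.linalg.norm(vc)
    Zc = Z - Z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Zc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (Zc @ vc) / (norms * vn)
    return out


def compute_eigengenes(
    expr: pd.DataFrame, assignment: ModuleAssignment
) -> pd.DataFrame:
    """Eigengene per (non-grey) module; returns samples x modules."""
    data = {}
    for module in sorted(set(assignment.labels.values()) - {GREY}):
        members = assignment.members(module)
        data[module] = module_eigengene(expr.loc[members])
    return pd.DataFrame(data, index=expr.columns)


def merge_modules(
    assignment: ModuleAssignment,
    expr: pd.DataFrame,
    params: NetworkParams = NetworkParams(),
) -> ModuleAssignment:
    """Iteratively merge modules with eigengene dissimilarity < threshold.

    Dissimilarity is 1 - cor(ME_i, ME_j); after each merge, eigengenes are
    recomputed. Re-running on merged output is a fixed point. Colours are
    re-assigned by decreasing size afterwards.
    """
    labels = dict(assignment.labels)
    while True:
        modules = sorted(set(labels.values()) - {GREY})
        if len(modules) < 2:
            break
        mes = compute_eigengenes(expr, ModuleAssignment(labels))
        C = np.corrcoef(mes.to_numpy(float).T)
        D = 1.0 - C
        np.fill_diagonal(D, np.inf)
        i, j = np.unravel_index(np.argmin(D), D.shape)
        if D[i, j] >= params.me_diss_thresh:
            break
        keep, absorb = mes.columns[i], mes.columns[j]
        for t, m in labels.items():
            if m == absorb:
                labels[t] = keep
    # recolour by decreasing size for the canonical ordering
    order = (
        pd.Series([m for m in labels.values() if m != GREY]).value_counts().index
    )
    rename = {
        old: (MODULE_COLORS[r] if r < len(MODULE_COLORS) else f"module_{r + 1}")
        for r, old in enumerate(order)
    }
    rename[GREY] = GREY
    relabelled = {t: rename[m] for t, m in labels.items()}
    merged = ModuleAssignment(relabelled)
    merged.eigengenes = compute_eigengenes(expr, merged)
    return merged


# ---------------------------------------------------------------------------
# Module-trait correlation
# ---------------------------------------------------------------------------


@dataclass
class ModuleTraitTable:
    correlations: pd.DataFrame  # modules x compounds
    top3: dict[str, list[tuple[str, float]]] = field(default_factory=dict)


def module_trait(
    eigengenes: pd.DataFrame,
    volatiles: VolatileProfile | pd.DataFrame,
    top_n: int = 3,
) -> ModuleTraitTable:
    """Correlate module eigengenes with per-sample volatile emission rates.

    Modules are ranked per compound by |r| (sign reported); the top three
    distinct modules are listed. Grey is never present in the eigengene
    table; compounds constant across samples are skipped with a warning.
    """
    rates = volatiles.rates if isinstance(volatiles, VolatileProfile) else volatiles
    shared = [s for s in eigengenes.index if s in set(rates.columns)]
    if len(shared) < 3:
        raise ValueError("module-trait correlation needs >= 3 shared samples")
    ME = eigengenes.loc[shared]
    corr = pd.DataFrame(index=ME.columns, columns=rates.index, dtype=float)
    for compound in rates.index:
        v = rates.loc[compound, shared].to_numpy(float)
        if np.allclose(v, v[0]):
            logger.warning("compound %s constant across samples: skipped", compound)
            corr.drop(columns=compound, inplace=True)
            continue
        vc = v - v.mean()
        vn = np.linalg.norm(vc)
        for module in ME.columns:
            m = ME[module].to_numpy(float)
            mc = m - m.mean()
            corr.loc[module, compound] = float(mc @ vc / (np.linalg.norm(mc) * vn))
    top3 = {
        compound: [
            (module, float(corr.loc[module, compound]))
            for module in corr[compound].abs().sort_values(ascending=False).index[:top_n]
        ]
        for compound in corr.columns
    }
    return ModuleTraitTable(correlations=corr, top3=top3)


def run_network(
    expr: pd.DataFrame,
    volatiles: Optional[VolatileProfile | pd.DataFrame] = None,
    params: NetworkParams = NetworkParams(),
) -> tuple[ModuleAssignment, Optional[ModuleTraitTable]]:
    """End-to-end: TOM, module detection, merging, module-trait table."""
    diss = tom_dissimilarity(expr, params)
    assignment = detect_modules(diss, params, ids=list(expr.index))
    if assignment.modules:
        assignment = merge_modules(assignment, expr, params)
    trait_table = None
    if volatiles is not None and assignment.eigengenes is not None:
        trait_table = module_trait(assignment.eigengenes, volatiles)
    return assignment, trait_table
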