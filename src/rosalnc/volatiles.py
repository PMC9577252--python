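"""GC-MS volatile quantification via an internal standard.

Headspace volatiles are quantified against a spiked internal standard
(ethyl caprate in the motivating experiments). The emission rate of a
compound, in ug per g fresh petal mass per hour, is

    rate = (peak_area / is_peak_area * is_concentration * is_volume)
           / sample_mass / extraction_time

which is exactly linear in the compound's peak area and invariant to
rescaling both peak areas together (detector gain cancels out).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPOUND_CLASSES = (
    "terpenoid",
    "phenylpropanoid_benzenoid",
    "fatty_acid_derivative",
    "non_scent",
)

#: classes counted toward floral-scent totals
SCENT_CLASSES = frozenset(COMPOUND_CLASSES) - {"non_scent"}


@dataclass(frozen=True)
class ChromatogramRecord:
    """One compound peak in one sample, with internal-standard context."""

    sample_id: str
    compound: str
    peak_area: float  # arbitrary units, >= 0
    is_peak_area: float  # internal standard peak area, > 0
    is_concentration: float  # ug/uL
    is_volume: float  # uL
    sample_mass: float  # g
    extraction_time: float  # h

    def __post_init__(self) -> None:
        if self.peak_area < 0:
            raise ValueError("negative peak area")
        for name in ("is_peak_area", "sample_mass", "extraction_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def emission_rate(rec: ChromatogramRecord) -> float:
    """Emission rate in ug.g-1.h-1 from one chromatogram record."""
    return (
        rec.peak_area / rec.is_peak_area * rec.is_concentration * rec.is_volume
    ) / rec.sample_mass / rec.extraction_time


@dataclass
class VolatileProfile:
    """Compound x sample emission-rate matrix with compound class labels."""

    rates: pd.DataFrame  # compounds x samples, ug.g-1.h-1
    compound_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.rates.values < 0).any():
            raise ValueError("negative emission rates")
        missing = set(self.rates.index) - set(self.compound_class)
        if missing:
            raise ValueError(f"compounds without class label: {sorted(missing)}")
        bad = set(self.compound_class.values()) - set(COMPOUND_CLASSES)
        if bad:
            raise ValueError(f"unknown compound classes: {sorted(bad)}")

    @property
    def scent_compounds(self) -> list[str]:
        return [
            c for c in self.rates.index if self.compound_class[c] in SCENT_CLASSES
        ]


GCMS_COLUMNS = [
    "sample_id",
    "compound",
    "peak_area",
    "is_peak_area",
    "is_concentration",
    "is_volume",
    "sample_mass",
    "extraction_time",
]


def profile_from_peaks(
    peaks: pd.DataFrame, compound_class: Mapping[str, str]
) -> VolatileProfile:
    """Build a VolatileProfile from a long-format GC-MS peak table."""
    missing = set(GCMS_COLUMNS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table lacks columns: {sorted(missing)}")
    records = peaks.assign(
        rate=lambda df: (
            df["peak_area"]
            / df["is_peak_area"]
            * df["is_concentration"]
            * df["is_volume"]
        )
        / df["sample_mass"]
        / df["extraction_time"]
    )
    rates = records.pivot_table(
        index="compound", columns="sample_id", values="rate", aggfunc="mean"
    )
    rates = rates.fillna(0.0)
    rates.columns.name = None
    rates.index.name = None
    return VolatileProfile(rates, dict(compound_class))


def read_compound_classes(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["compound", "class"], comment="#")
    if not df.empty and str(df.iloc[0, 0]) == "compound":
        df = df.iloc[1:]
    return dict(zip(df["compound"], df["class"]))


def aggregate_by_class(
    profile: VolatileProfile, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage scent totals and per-class shares.

    Non-scent compounds are excluded from all totals. Returns
    ``(stage_totals, class_shares)``:

    * stage_totals: index stage, columns total_mean / total_sd over the
      per-sample totals of that stage's replicates;
    * class_shares: one row per (stage, class) with the replicate-mean class
      total and its percentage share of the stage total. Shares sum to 100
      per stage; a stage with zero total is flagged with NaN shares.
    """
    scent = profile.rates.loc[profile.scent_compounds]
    sample_totals = scent.sum(axis=0)
    stages = meta.loc[list(scent.columns), "stage"]

    stage_rows, share_rows = [], []
    for stage in pd.unique(stages):
        cols = stages.index[stages == stage]
        totals = sample_totals[cols]
        stage_total = totals.mean()
        stage_rows.append(
            {
                "stage": stage,
                "total_mean": stage_total,
                "total_sd": totals.std(ddof=1) if len(totals) > 1 else 0.0,
            }
        )
        for cls in sorted(SCENT_CLASSES):
            members = [c for c in scent.index if profile.compound_class[c] == cls]
            class_total = scent.loc[members, cols].sum(axis=0).mean() if members else 0.0
            share = class_total / stage_total * 100 if stage_total > 0 else np.nan
            if stage_total <= 0:
                logger.warning("stage %s has zero scent total; shares undefined", stage)
            share_rows.append(
                {
                    "stage": stage,
                    "class": cls,
                    "class_total_mean": class_total,
                    "share_pct": share,
                }
            )
    return (
        pd.DataFrame(stage_rows).set_index("stage"),
        pd.DataFrame(share_rows),
    )


def stage_compare(
    profile: VolatileProfile,
    meta: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Welch two-sample t-tests between two stages.

    Per-compound tests on emission rates plus one test on the per-sample
    scent totals. Requires >= 2 replicates per stage. Returns
    (per_compound_df, total_result_dict); each entry carries the t statistic,
    the p-value and a significance flag at ``alpha``.
    """
    stages = meta.loc[list(profile.rates.columns), "stage"]
    cols_a = stages.index[stages == stage_a]
    cols_b = stages.index[stages == stage_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("stage_compare needs >= 2 replicates per stage")

    def welch(x, y) -> tuple[float, float]:
        x, y = np.asarray(x, float), np.asarray(y, float)
        if np.allclose(x, x[0]) and np.allclose(y, y[0]):
            return (0.0, 1.0) if np.isclose(x[0], y[0]) else (np.inf, 0.0)
        t, p = stats.ttest_ind(x, y, equal_var=False)
        return float(t), float(p)

    rows = []
    for compound in profile.rates.index:
        t, p = welch(profile.rates.loc[compound, cols_a], profile.rates.loc[compound, cols_b])
        rows.append(
            {"compound": compound, "t": t, "p": p, "significant": p < alpha}
        )
    scent = profile.rates.loc[profile.scent_compounds]
    t, p = welch(scent[cols_a].sum(axis=0), scent[cols_b].sum(axis=0))
    total = {"t": t, "p": p, "significant": p < alpha}
    return pd.DataFrame(rows), total
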