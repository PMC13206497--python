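"""Abundance/prevalence screening of taxa.

A taxon passes the dominance criterion when its mean relative abundance
across all samples exceeds the abundance threshold (default 1%) AND it is
detected in at least the prevalence threshold fraction of samples
(default 80%). Independently of the flag, taxa are classified as
dominant (mean RA >= 10%), sub-dominant (1% <= mean RA < 10%) or minor,
the conventional abundance tiers for fermentation communities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel_io import AbundanceTable, AnalysisConfig

DOMINANT_MEAN_RA = 0.10
SUB_DOMINANT_MEAN_RA = 0.01


@dataclass
class DominanceReport:
    """Per-taxon mean RA, prevalence, criterion flag and abundance class."""

    table: pd.DataFrame  # columns: taxon, mean_ra, prevalence, flag, class

    @property
    def flagged_taxa(self) -> set[str]:
        return set(self.table.loc[self.table["flag"], "taxon"])

    def taxa_in_class(self, cls: str) -> set[str]:
        return set(self.table.loc[self.table["class"] == cls, "taxon"])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _classify(mean_ra: float) -> str:
    if mean_ra >= DOMINANT_MEAN_RA:
        return "dominant"
    if mean_ra >= SUB_DOMINANT_MEAN_RA:
        return "sub_dominant"
    return "minor"


def dominance_screen(
    table: AbundanceTable, config: AnalysisConfig | None = None
) -> DominanceReport:
    """Screen every taxon of a normalized table; report sorted by mean RA.

    Prevalence is the fraction of samples with relative abundance
    strictly greater than ``presence_epsilon`` (default 0, i.e. any
    detection counts).
    """
    config = config or AnalysisConfig()
    if not table.normalized:
        raise ValueError("dominance screening requires a normalized abundance table")
    mean_ra = table.values.mean(axis=1)
    prevalence = (table.values > config.presence_epsilon).mean(axis=1)
    flag = (mean_ra > config.dominance_abundance_threshold) & (
        prevalence >= config.dominance_prevalence_threshold
    )
    df = pd.DataFrame(
        {
            "taxon": table.taxa,
            "mean_ra": mean_ra,
            "prevalence": prevalence,
            "flag": flag,
            "class": [_classify(m) for m in mean_ra],
        }
    ).sort_values("mean_ra", ascending=False, kind="stable").reset_index(drop=True)
    return DominanceReport(table=df)
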