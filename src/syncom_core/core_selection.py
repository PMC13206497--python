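"""Core-microbe selection: triple-criterion intersection plus omission pruning.

Candidate core = taxa that are simultaneously dominant (abundance +
prevalence), hubs of the q-controlled co-occurrence network, and
significantly associated with at least five volatile compounds. The
candidate set is then pruned with leave-one-strain-out (omission)
fermentation outcomes: a candidate is retained when omitting it
significantly changes at least one of the two quality indicators (umami
amino acids, 4-ethylguaiacol). Candidates without an omission group —
the koji mold Aspergillus oryzae, without which koji cannot be made —
pass pruning by default with a logged note.

The module also ships, as named constants, the three published candidate
lists and omission outcomes for soy sauce moromi that this pipeline
operationalizes; replaying them through ``candidate_core`` and
``prune_core`` reproduces the published seven-species core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.libqsturng import psturng

from .correlation_networks import (
    CorrelationNetwork,
    build_cooccurrence,
    flavor_associated_taxa,
    hub_taxa,
)
from .datamodel_io import (
    AbundanceTable,
    AnalysisConfig,
    VolatileTable,
    write_json,
)
from .dominance import DominanceReport, dominance_screen

logger = logging.getLogger("syncom_core")

OMISSION_INDICATORS = ("umami_AA", "4EG")


# ---------------------------------------------------------------------------
# Published candidate lists for soy sauce moromi (species level)
# ---------------------------------------------------------------------------

#: High-abundance fermentative species (12 bacteria + 5 fungi).
DOMINANT_SPECIES = frozenset({
    "Weissella paramesenteroides",
    "Lactiplantibacillus plantarum",
    "Lactococcus lactis",
    "Tetragenococcus halophilus",
    "Pediococcus pentosaceus",
    "Pediococcus acidilactici",
    "Staphylococcus epidermidis",
    "Staphylococcus gallinarum",
    "Bacillus velezensis",
    "Weissella cibaria",
    "Enterobacter hormaechei",
    "Enterobacter kobei",
    "Zygosaccharomyces rouxii",
    "Candida orthopsilosis",
    "Millerozyma farinosa",
    "Aspergillus oryzae",
    "Pichia membranifaciens",
})

#: Hub species of the co-occurrence network (9 bacteria + 7 fungi).
HUB_SPECIES = frozenset({
    "Weissella paramesenteroides",
    "Lactiplantibacillus plantarum",
    "Lactobacillus fermentum",
    "Lactococcus lactis",
    "Tetragenococcus halophilus",
    "Pediococcus pentosaceus",
    "Pediococcus acidilactici",
    "Staphylococcus epidermidis",
    "Weissella cibaria",
    "Zygosaccharomyces rouxii",
    "Pichia membranifaciens",
    "Candida orthopsilosis",
    "Meyerozyma guilliermondii",
    "Aspergillus oryzae",
    "Millerozyma farinosa",
    "Candida psychrophila",
})

#: Species significantly correlated with volatiles (9 bacteria + 6 fungi).
FLAVOR_SPECIES = frozenset({
    "Weissella paramesenteroides",
    "Lactiplantibacillus plantarum",
    "Lactobacillus fermentum",
    "Saccharopolyspora thermophila",
    "Tetragenococcus halophilus",
    "Pediococcus pentosaceus",
    "Pediococcus acidilactici",
    "Staphylococcus epidermidis",
    "Bacillus velezensis",
    "Zygosaccharomyces rouxii",
    "Pichia fermentans",
    "Candida orthopsilosis",
    "Meyerozyma guilliermondii",
    "Aspergillus oryzae",
    "Candida guilliermondii",
})

#: Published omission outcomes: taxon -> (percent decrease, significant)
#: per indicator. None = not reported; A. oryzae had no omission group.
OMISSION_OUTCOMES: Mapping[str, Mapping[str, tuple[float | None, bool]]] = {
    "Weissella paramesenteroides": {"umami_AA": (27.2, True), "4EG": (None, True)},
    "Lactiplantibacillus plantarum": {"umami_AA": (15.5, True), "4EG": (42.8, True)},
    "Tetragenococcus halophilus": {"umami_AA": (25.9, True), "4EG": (None, True)},
    "Pediococcus pentosaceus": {"umami_AA": (15.8, True), "4EG": (None, True)},
    "Pediococcus acidilactici": {"umami_AA": (None, False), "4EG": (None, False)},
    "Staphylococcus epidermidis": {"umami_AA": (None, False), "4EG": (None, False)},
    "Zygosaccharomyces rouxii": {"umami_AA": (None, False), "4EG": (45.6, True)},
    "Candida orthopsilosis": {"umami_AA": (None, False), "4EG": (56.5, True)},
}


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OmissionResult:
    """Effect of omitting one taxon on one fermentation indicator."""

    taxon: str
    indicator: str
    control_mean: float | None
    omitted_mean: float | None
    percent_change: float | None
    p_value: float | None
    significant: bool


@dataclass
class CoreReport:
    """Per-taxon criterion flags, candidate core, omission results, final core."""

    dominant: set[str]
    hubs: set[str]
    flavor_associated: set[str]
    candidate_core: set[str]
    omission_results: list[OmissionResult] = field(default_factory=list)
    final_core: set[str] = field(default_factory=set)

    def flags_dataframe(self) -> pd.DataFrame:
        taxa = sorted(self.dominant | self.hubs | self.flavor_associated)
        return pd.DataFrame(
            {
                "taxon": taxa,
                "dominant": [t in self.dominant for t in taxa],
                "hub": [t in self.hubs for t in taxa],
                "flavor_associated": [t in self.flavor_associated for t in taxa],
                "candidate_core": [t in self.candidate_core for t in taxa],
                "final_core": [t in self.final_core for t in taxa],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.flags_dataframe().to_csv(path, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        write_json(
            {
                "dominant": sorted(self.dominant),
                "hubs": sorted(self.hubs),
                "flavor_associated": sorted(self.flavor_associated),
                "candidate_core": sorted(self.candidate_core),
                "final_core": sorted(self.final_core),
                "omission_results": [vars(r) for r in self.omission_results],
            },
            path,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def tukey_pvalues(arrays: Sequence[np.ndarray]) -> np.ndarray:
    """Tukey-Kramer HSD p-value matrix for a list of group samples.

    Pooled within-group variance; p-values from the studentized-range
    distribution (fast tabulated approximation, clipped to
    [0.001, 0.9]). Degenerate all-equal-variance-zero comparisons get
    p = 1 for equal means and p = 0 otherwise.
    """
    k = len(arrays)
    n = np.array([len(a) for a in arrays])
    means = np.array([np.mean(a) for a in arrays])
    df = int(n.sum() - k)
    if df <= 0:
        raise ValueError("need at least one residual degree of freedom")
    sse = sum(float(np.sum((a - m) ** 2)) for a, m in zip(arrays, means))
    mse = sse / df
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(means[i] - means[j])
            if mse == 0:
                pv = 1.0 if diff == 0 else 0.0
            else:
                q = diff / np.sqrt(mse / 2 * (1 / n[i] + 1 / n[j]))
                pv = float(np.atleast_1d(psturng(q, k, df))[0])
            p[i, j] = p[j, i] = pv
    return p


def candidate_core(
    dominance: DominanceReport | Iterable[str],
    hubs: Iterable[str],
    flavor: Iterable[str],
) -> set[str]:
    """Strict intersection of the three criterion sets."""
    if isinstance(dominance, DominanceReport):
        dominant = dominance.flagged_taxa
    else:
        dominant = set(dominance)
    return dominant & set(hubs) & set(flavor)


def omission_analysis(
    measurements: pd.DataFrame,
    config: AnalysisConfig | None = None,
    control_group: str = "control",
) -> list[OmissionResult]:
    """Per (taxon, indicator): percent change vs control and significance.

    Long-format input columns: group, indicator, replicate, value, with
    omission groups named ``omit_<taxon>``. Significance per indicator is
    one-way ANOVA across all groups followed by Tukey HSD of each
    omission group against the control at ``omission_alpha``.
    """
    config = config or AnalysisConfig()
    required = {"group", "indicator", "replicate", "value"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"omission table must have columns {sorted(required)}")
    groups = measurements["group"].unique().tolist()
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} missing from omission table")

    results: list[OmissionResult] = []
    for indicator, sub in measurements.groupby("indicator", sort=False):
        counts = sub.groupby("group")["value"].count()
        small = counts[counts < 2]
        if not small.empty:
            raise ValueError(
                f"indicator {indicator!r}: groups with fewer than 2 replicates: "
                f"{sorted(small.index)}"
            )
        group_names = list(counts.index)
        arrays = [sub.loc[sub["group"] == g, "value"].to_numpy() for g in group_names]
        with np.errstate(invalid="ignore", divide="ignore"):
            _, anova_p = stats.f_oneway(*arrays)
        anova_ok = bool(np.isfinite(anova_p) and anova_p < config.omission_alpha)
        if not anova_ok and all(a.std() == 0 for a in arrays):
            # degenerate zero-variance data: treat unequal means as real
            anova_ok = len({float(a.mean()) for a in arrays}) > 1
        tukey_p = tukey_pvalues(arrays)
        i_control = group_names.index(control_group)

        control_mean = float(sub.loc[sub["group"] == control_group, "value"].mean())
        for gi, g in enumerate(group_names):
            if g == control_group or not str(g).startswith("omit_"):
                continue
            taxon = str(g)[len("omit_"):]
            omitted_mean = float(sub.loc[sub["group"] == g, "value"].mean())
            pct = (
                (control_mean - omitted_mean) / control_mean * 100.0
                if control_mean > 0
                else None
            )
            p_adj = float(tukey_p[i_control, gi])
            reject = bool(np.isfinite(p_adj) and p_adj < config.omission_alpha)
            results.append(
                OmissionResult(
                    taxon=taxon,
                    indicator=str(indicator),
                    control_mean=control_mean,
                    omitted_mean=omitted_mean,
                    percent_change=pct,
                    p_value=p_adj,
                    significant=bool(anova_ok and reject),
                )
            )
    return results


def prune_core(candidate: set[str], omission: Sequence[OmissionResult]) -> set[str]:
    """Drop candidates significant for neither indicator.

    Candidates with no omission data at all are retained with a logged
    note (they could not be tested, e.g. the koji mold).
    """
    tested: dict[str, bool] = {}
    for r in omission:
        tested[r.taxon] = tested.get(r.taxon, False) or r.significant
    final = set()
    for taxon in candidate:
        if taxon not in tested:
            logger.info("no omission data for %r; retained in final core", taxon)
            final.add(taxon)
        elif tested[taxon]:
            final.add(taxon)
    return final


def identify_core(
    abundance: AbundanceTable,
    volatiles: VolatileTable,
    config: AnalysisConfig | None = None,
    omission: pd.DataFrame | None = None,
) -> tuple[CoreReport, CorrelationNetwork, CorrelationNetwork]:
    """Run the full selection pipeline on one dataset.

    Returns the core report plus the analysis co-occurrence network and
    the taxon-volatile network. When ``omission`` measurements are
    given, the final core is the omission-pruned candidate set;
    otherwise final core equals the candidate core.
    """
    config = config or AnalysisConfig()
    dom = dominance_screen(abundance, config)
    net = build_cooccurrence(abundance, config, kind="analysis")
    hubs = hub_taxa(net, config)
    tv_net, flavor = flavor_associated_taxa(abundance, volatiles, config)
    candidate = candidate_core(dom, hubs, flavor)
    report = CoreReport(
        dominant=dom.flagged_taxa,
        hubs=hubs,
        flavor_associated=flavor,
        candidate_core=candidate,
    )
    if omission is not None:
        report.omission_results = omission_analysis(omission, config)
        report.final_core = prune_core(candidate, report.omission_results)
    else:
        report.final_core = set(candidate)
    return report, net, tv_net


def reference_core_selection() -> CoreReport:
    """Replay the published candidate lists and omission outcomes.

    Intersecting the three published species lists yields the nine-member
    candidate core; pruning with the published omission outcomes yields
    the seven-species final core.
    """
    candidate = candidate_core(DOMINANT_SPECIES, HUB_SPECIES, FLAVOR_SPECIES)
    omission = [
        OmissionResult(
            taxon=taxon,
            indicator=indicator,
            control_mean=None,
            omitted_mean=None,
            percent_change=pct,
            p_value=None,
            significant=sig,
        )
        for taxon, per_ind in OMISSION_OUTCOMES.items()
        for indicator, (pct, sig) in per_ind.items()
    ]
    return CoreReport(
        dominant=set(DOMINANT_SPECIES),
        hubs=set(HUB_SPECIES),
        flavor_associated=set(FLAVOR_SPECIES),
        candidate_core=candidate,
        omission_results=omission,
        final_core=prune_core(candidate, omission),
    )
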