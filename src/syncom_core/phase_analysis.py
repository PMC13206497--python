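"""Fermentation phase segmentation and indicator/taxon phase assignment.

The source procedure reads four fermentation phases off PCA plots by
eye; this module makes that reproducible: timepoints are segmented into
k contiguous phases by dynamic programming that exactly minimizes the
total within-segment sum of squared deviations in the space of the first
two principal-component scores of the community (or any multivariate)
trajectory.

Indicators are split into early- vs late-phase markers from the PC1
loadings of their *rate* profiles (first differences of the z-scored
trajectory): early-changing indicators (glutamate, lactic acid, amino
nitrogen) anti-correlate with late changers (4-ethylguaiacol) in rate
space, so PC1 separates them; on raw monotone trajectories it cannot,
because two monotone-increasing indicators load with the same sign
regardless of when they change. PC1's reflection ambiguity is pinned by
orienting the earliest observation's score non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation_networks import bh_fdr, spearman
from .datamodel_io import (
    AbundanceTable,
    AnalysisConfig,
    IndicatorSeries,
    VolatileTable,
)

logger = logging.getLogger("syncom_core")

PHASE_LABELS_4 = ("immediate_early", "early", "middle", "late")

#: Indicator names pooled into the two non-volatile metabolite classes.
AMINO_ACID_INDICATORS = ("glutamic_acid", "umami_AA", "amino_N")
ORGANIC_ACID_INDICATORS = ("lactic_acid",)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Scores, loadings and variance fractions of a correlation-matrix PCA.

    Every component is sign-oriented so that the earliest (first)
    observation has a non-negative score, fixing the reflection
    ambiguity. ``kept`` holds the indices of non-constant variables that
    entered the decomposition.
    """

    scores: np.ndarray  # (n_obs, n_comp)
    loadings: np.ndarray  # (n_vars_kept, n_comp)
    variance_fractions: np.ndarray
    kept: list[int]

    def reconstruct(self) -> np.ndarray:
        """Standardized data matrix from all components."""
        return self.scores @ self.loadings.T


def pca_scores(matrix: np.ndarray | pd.DataFrame) -> PCAResult:
    """PCA of an observation-by-variable matrix on the correlation scale.

    Variables are z-standardized internally (ddof=1); constant variables
    are dropped with a warning. Requires >= 3 observations and >= 2
    usable variables.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        names = [str(i) for i in range(x.shape[1])]
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 observations")
    sd = x.std(axis=0, ddof=1)
    kept = [i for i in range(x.shape[1]) if sd[i] > 0]
    dropped = [names[i] for i in range(x.shape[1]) if sd[i] == 0]
    if dropped:
        logger.warning("dropping constant variable(s) from PCA: %s", ", ".join(dropped))
    if len(kept) < 2:
        raise ValueError("need at least 2 non-constant variables")
    z = (x[:, kept] - x[:, kept].mean(axis=0)) / sd[kept]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u * s
    loadings = vt.T
    var = s**2
    frac = var / var.sum()
    # orient each component: earliest observation scores non-negative
    for c in range(scores.shape[1]):
        col = scores[:, c]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            scores[:, c] = -col
            loadings[:, c] = -loadings[:, c]
    return PCAResult(scores=scores, loadings=loadings, variance_fractions=frac, kept=kept)


# ---------------------------------------------------------------------------
# Contiguous segmentation
# ---------------------------------------------------------------------------


@dataclass
class PhaseSegmentation:
    """Contiguous partition of ordered timepoints into named phases.

    ``boundaries`` are interior boundary days, reported as the midpoint
    between the last timepoint of one phase and the first of the next;
    ``break_indices`` give the same breaks as timepoint indices (a break
    after index i sits at position i + 0.5).
    """

    days: list[float]
    break_indices: list[int]  # segment ends after these timepoint indices
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.break_indices) != len(self.labels) - 1:
            raise ValueError("k labels require k-1 breaks")
        if any(b >= len(self.days) - 1 or b < 0 for b in self.break_indices):
            raise ValueError("break index out of range")

    @property
    def boundaries(self) -> list[float]:
        return [
            (self.days[i] + self.days[i + 1]) / 2.0 for i in self.break_indices
        ]

    @property
    def assignment(self) -> dict[float, str]:
        out = {}
        seg = 0
        bounds = list(self.break_indices) + [len(self.days) - 1]
        for i, d in enumerate(self.days):
            out[d] = self.labels[seg]
            if i == bounds[seg] and seg < len(self.labels) - 1:
                seg += 1
        return out

    def phase_of_day(self, day: float) -> str:
        """Phase containing an arbitrary day (by boundary comparison)."""
        for b, lab in zip(self.boundaries, self.labels):
            if day < b:
                return lab
        return self.labels[-1]

    def to_dict(self) -> dict:
        return {
            "days": self.days,
            "boundaries": self.boundaries,
            "labels": self.labels,
            "assignment": {str(d): p for d, p in self.assignment.items()},
        }


def _segment_costs(x: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-segment SSE of rows i..j inclusive."""
    t = x.shape[0]
    csum = np.vstack([np.zeros(x.shape[1]), np.cumsum(x, axis=0)])
    csq = np.vstack([np.zeros(x.shape[1]), np.cumsum(x * x, axis=0)])
    cost = np.full((t, t), np.inf)
    for i in range(t):
        for j in range(i, t):
            n = j - i + 1
            s = csum[j + 1] - csum[i]
            ss = csq[j + 1] - csq[i]
            cost[i, j] = float(np.sum(ss - s * s / n))
    return cost


def segment_phases(
    matrix: np.ndarray | pd.DataFrame,
    k: int = 4,
    days: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
    n_components: int = 2,
) -> PhaseSegmentation:
    """Optimal contiguous k-segmentation of a timepoint-by-variable matrix.

    The matrix rows must be in increasing day order. Segmentation
    minimizes total within-segment SSE in the space of the first
    ``n_components`` PC scores, solved exactly by dynamic programming;
    cost ties break toward the earliest boundary.
    """
    if isinstance(matrix, pd.DataFrame):
        if days is None:
            days = [float(d) for d in matrix.index]
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
    t = x.shape[0]
    if k > t:
        raise ValueError(f"cannot split {t} timepoints into {k} phases")
    if days is None:
        days = list(range(t))
    days = [float(d) for d in days]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")

    pca = pca_scores(x)
    scores = pca.scores[:, : min(n_components, pca.scores.shape[1])]
    cost = _segment_costs(scores)

    # dp[m][j]: min cost of splitting rows 0..j into m+1 segments
    dp = np.full((k, t), np.inf)
    prev = np.full((k, t), -1, dtype=int)
    dp[0] = cost[0]
    for m in range(1, k):
        for j in range(m, t):
            best, arg = np.inf, -1
            for i in range(m, j + 1):  # segment m is rows i..j
                c = dp[m - 1][i - 1] + cost[i, j]
                if c < best:  # strict: earliest start wins ties
                    best, arg = c, i
            dp[m][j], prev[m][j] = best, arg

    breaks = []
    j = t - 1
    for m in range(k - 1, 0, -1):
        i = prev[m][j]
        breaks.append(i - 1)
        j = i - 1
    breaks.reverse()

    if labels is None:
        labels = list(PHASE_LABELS_4) if k == 4 else [f"phase_{i + 1}" for i in range(k)]
    return PhaseSegmentation(days=days, break_indices=breaks, labels=list(labels))


def segmentation_cost(matrix: np.ndarray | pd.DataFrame, seg: PhaseSegmentation,
                      n_components: int = 2) -> float:
    """Total within-segment SSE of a segmentation (same space as the DP)."""
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    scores = pca_scores(x).scores[:, :n_components]
    cost = _segment_costs(scores)
    total = 0.0
    start = 0
    for b in list(seg.break_indices) + [x.shape[0] - 1]:
        total += cost[start, b]
        start = b + 1
    return total


# ---------------------------------------------------------------------------
# Indicator assignment
# ---------------------------------------------------------------------------


@dataclass
class IndicatorAssignment:
    """Early/late split of indicators with the loadings that produced it."""

    assignment: dict[str, str]  # indicator -> "early" | "late"
    pc1_loading: dict[str, float]
    variance_explained: tuple[float, float]
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "assignment": self.assignment,
            "pc1_loading": self.pc1_loading,
            "variance_explained": list(self.variance_explained),
            "excluded": self.excluded,
        }


def assign_indicators(
    indicators: Sequence[IndicatorSeries],
    segmentation: PhaseSegmentation,
) -> IndicatorAssignment:
    """Assign each indicator to the early or the late fermentation side.

    Each indicator's replicate-mean trajectory at the segmentation
    timepoints is z-scored and first-differenced (rate per day); PCA over
    the interval-by-indicator rate matrix then splits indicators by the
    sign of their PC1 loading — positive (the early-oriented sign after
    orientation) means the indicator does its changing early.
    Indicators with fewer than 3 observations at the segmentation
    timepoints, or constant over time, are excluded with a warning.
    """
    days = np.array(segmentation.days)
    cols: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for ind in indicators:
        means = ind.timepoint_means()
        if not all(d in means.index for d in days) or len(means) < 3:
            logger.warning("indicator %r lacks observations at segmentation days; excluded",
                           ind.name)
            excluded.append(ind.name)
            continue
        traj = means.loc[days].to_numpy()
        if np.ptp(traj) == 0:
            logger.warning("indicator %r is constant over time; excluded", ind.name)
            excluded.append(ind.name)
            continue
        z = (traj - traj.mean()) / traj.std(ddof=1)
        cols[ind.name] = np.diff(z) / np.diff(days)
    if len(cols) < 2:
        raise ValueError("need at least 2 assignable indicators")

    rate = pd.DataFrame(cols)
    pca = pca_scores(rate)
    names = [rate.columns[i] for i in pca.kept]
    loadings = {n: float(pca.loadings[i, 0]) for i, n in enumerate(names)}
    v1 = float(pca.variance_fractions[0])
    v2 = float(pca.variance_fractions[1]) if pca.variance_fractions.size > 1 else 0.0
    assignment = {n: ("early" if l > 0 else "late") for n, l in loadings.items()}
    excluded += [n for n in rate.columns if n not in names]
    return IndicatorAssignment(
        assignment=assignment,
        pc1_loading=loadings,
        variance_explained=(v1, v2),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Taxa-phase correspondence
# ---------------------------------------------------------------------------


def _class_trajectories(
    volatiles: VolatileTable,
    indicators: Sequence[IndicatorSeries],
    days: np.ndarray,
) -> pd.DataFrame:
    """Per-class mean z-scored trajectory at the given days.

    Classes are the seven volatile classes plus ``amino_acids`` (pooled
    amino-acid indicators) and ``organic_acids`` (lactic acid).
    """
    vdf = volatiles.to_dataframe()
    vdays = np.array([s.day for s in volatiles.samples])
    tp_means = pd.DataFrame(
        {float(d): vdf.loc[:, vdays == d].mean(axis=1) for d in days}
    )
    out: dict[str, np.ndarray] = {}
    classes = np.array(volatiles.classes)
    for cls in sorted(set(classes)):
        sub = tp_means.loc[classes == cls]
        z = sub.sub(sub.mean(axis=1), axis=0)
        sd = sub.std(axis=1, ddof=1).replace(0, np.nan)
        z = z.div(sd, axis=0).dropna()
        if len(z):
            out[cls] = z.mean(axis=0).to_numpy()

    def pooled(names: Sequence[str], label: str) -> None:
        rows = []
        for ind in indicators:
            if ind.name in names:
                means = ind.timepoint_means()
                if all(d in means.index for d in days):
                    traj = means.loc[days].to_numpy()
                    if np.ptp(traj) > 0:
                        rows.append((traj - traj.mean()) / traj.std(ddof=1))
        if rows:
            out[label] = np.mean(rows, axis=0)

    pooled(AMINO_ACID_INDICATORS, "amino_acids")
    pooled(ORGANIC_ACID_INDICATORS, "organic_acids")
    return pd.DataFrame(out, index=days)


def taxa_phase_correspondence(
    abundance: AbundanceTable,
    volatiles: VolatileTable,
    indicators: Sequence[IndicatorSeries],
    core: set[str],
    segmentation: PhaseSegmentation,
    config: AnalysisConfig | None = None,
) -> dict[str, list[str]]:
    """Map each core taxon to the phases its associated metabolism peaks in.

    For every core taxon x metabolite class, the Spearman correlation
    between the taxon's replicate-mean trajectory and the class-mean
    z-scored trajectory is computed and BH-corrected within this family.
    A taxon maps to each phase in which a significantly associated class
    has its maximum mean rate of change (first differences over days;
    each interval counts toward the phase containing its midpoint).
    Phases are returned in phase order.
    """
    config = config or AnalysisConfig()
    if not core:
        return {}
    missing = core - set(abundance.taxa)
    if missing:
        raise ValueError(f"core taxa absent from abundance table: {sorted(missing)}")
    days = np.array(segmentation.days)
    classes = _class_trajectories(volatiles, indicators, days)

    taxa_means = abundance.timepoint_means()  # taxon x day
    pairs = []
    pvals = []
    for taxon in sorted(core):
        traj = taxa_means.loc[taxon, [float(d) for d in days]].to_numpy()
        for cls in classes.columns:
            rho, p = spearman(traj, classes[cls].to_numpy())
            if np.isnan(rho):
                continue
            pairs.append((taxon, cls, rho))
            pvals.append(p)
    if not pairs:
        return {t: [] for t in sorted(core)}
    qvals = bh_fdr(pvals)

    # phase of maximum mean rate of change, per class
    mid = (days[:-1] + days[1:]) / 2.0
    interval_phase = [segmentation.phase_of_day(m) for m in mid]
    peak_phase: dict[str, str] = {}
    for cls in classes.columns:
        rates = np.diff(classes[cls].to_numpy()) / np.diff(days)
        means = {
            lab: np.mean([r for r, ph in zip(rates, interval_phase) if ph == lab])
            for lab in segmentation.labels
            if any(ph == lab for ph in interval_phase)
        }
        peak_phase[cls] = max(means, key=lambda lab: means[lab])

    order = {lab: i for i, lab in enumerate(segmentation.labels)}
    result: dict[str, set[str]] = {t: set() for t in sorted(core)}
    for (taxon, cls, rho), q in zip(pairs, qvals):
        if rho > 0 and q < config.flavor_q_threshold:
            result[taxon].add(peak_phase[cls])
    return {t: sorted(ps, key=lambda lab: order[lab]) for t, ps in result.items()}


def analyze_phases(
    abundance: AbundanceTable,
    volatiles: VolatileTable,
    indicators: Sequence[IndicatorSeries],
    core: set[str],
    config: AnalysisConfig | None = None,
    segment_min_mean_ra: float = 0.005,
) -> tuple[PhaseSegmentation, IndicatorAssignment, dict[str, list[str]]]:
    """Full phase stage: segment the community trajectory, assign
    indicators, and map core taxa to phases."""
    config = config or AnalysisConfig()
    taxa_means = abundance.timepoint_means()  # taxon x day
    # segment on log abundances of the non-rare community: the log makes
    # succession steps at low abundance as informative as at high
    # abundance, and the rare-taxon floor keeps noise dimensions from
    # rivalling the succession signal when taxa far outnumber timepoints
    keep = taxa_means.mean(axis=1) > segment_min_mean_ra
    matrix = np.log10(taxa_means.loc[keep].T + 1e-6)  # timepoint x taxon
    seg = segment_phases(matrix, k=config.n_phases)
    assignment = assign_indicators(indicators, seg)
    correspondence = taxa_phase_correspondence(
        abundance, volatiles, indicators, core, seg, config
    )
    return seg, assignment, correspondence
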