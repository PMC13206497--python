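"""Temporal SynCom inoculation schedules: grammar, enumeration, comparison.

Schedules are written in an arrow shorthand, e.g. ``"W→L→P+T→Z+C"``:
``→`` separates inoculation events at successive slot days, ``+`` joins
strains added together in one event. Strain codes cover the core
species of the soy sauce SynCom (W = Weissella paramesenteroides,
L = Lactiplantibacillus plantarum, P = Pediococcus pentosaceus,
T = Tetragenococcus halophilus, Z = Zygosaccharomyces rouxii,
C = Candida orthopsilosis, plus Pa/S/A for the acidilactici
pediococcus, the staphylococcus and the koji mold). Bacteria default to
1e8 CFU/g, yeasts to 1e7 CFU/g; default slot days are (0, 5, 10, 25) —
three LAB slots plus the fixed day-25 yeast addition.

Two shorthands that order strains differently within a ``+`` group
(``P+T`` vs ``T+P``) denote the same schedule: formatting preserves the
written order so round-trips are exact, while equality and enumeration
deduplication compare (day, strain-set) pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .core_selection import tukey_pvalues
from .datamodel_io import IndicatorSeries

ARROW = "→"
PLUS = "+"

#: Strain code registry: code -> (species, kind).
STRAIN_CODES: Mapping[str, tuple[str, str]] = {
    "W": ("Weissella paramesenteroides", "bacterium"),
    "L": ("Lactiplantibacillus plantarum", "bacterium"),
    "P": ("Pediococcus pentosaceus", "bacterium"),
    "T": ("Tetragenococcus halophilus", "bacterium"),
    "Pa": ("Pediococcus acidilactici", "bacterium"),
    "S": ("Staphylococcus epidermidis", "bacterium"),
    "Z": ("Zygosaccharomyces rouxii", "yeast"),
    "C": ("Candida orthopsilosis", "yeast"),
    "A": ("Aspergillus oryzae", "mold"),
}

DEFAULT_DOSES = {"bacterium": 1e8, "yeast": 1e7, "mold": 1e7}
DEFAULT_SLOT_DAYS = (0.0, 5.0, 10.0, 25.0)

#: The seven published temporal SynCom designs (LAB order over slots
#: 0/5/10 d plus the fixed day-25 yeast addition).
REFERENCE_SCHEDULES = (
    "W→L→P+T→Z+C",
    "W→P→L+T→Z+C",
    "W→T→L+P→Z+C",
    "W→T+P→L→Z+C",
    "L→W→P+T→Z+C",
    "L→W→T+P→Z+C",
    "L→P→T+W→Z+C",
)


@dataclass(frozen=True)
class InoculationEvent:
    """One inoculation: day, strain codes (written order kept), dose CFU/g."""

    day: float
    strains: tuple[str, ...]
    doses: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValueError("inoculation event with no strains")
        if self.day < 0:
            raise ValueError("inoculation day must be >= 0")
        if not self.doses:
            object.__setattr__(
                self,
                "doses",
                tuple(DEFAULT_DOSES[STRAIN_CODES[s][1]] for s in self.strains),
            )
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be > 0")

    @property
    def strain_set(self) -> frozenset[str]:
        return frozenset(self.strains)


@dataclass(frozen=True)
class Schedule:
    """Ordered inoculation events; equality ignores within-event order."""

    events: tuple[InoculationEvent, ...]

    def __post_init__(self) -> None:
        days = [e.day for e in self.events]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("event days must be strictly increasing")
        seen: set[str] = set()
        for e in self.events:
            for s in e.strains:
                if s in seen:
                    raise ValueError(f"strain {s!r} inoculated twice")
                seen.add(s)

    @property
    def shorthand(self) -> str:
        return ARROW.join(PLUS.join(e.strains) for e in self.events)

    @property
    def key(self) -> tuple[tuple[float, frozenset[str]], ...]:
        return tuple((e.day, e.strain_set) for e in self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, Schedule) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def to_dict(self) -> dict:
        return {
            "shorthand": self.shorthand,
            "events": [
                {
                    "day": e.day,
                    "strains": list(e.strains),
                    "species": [STRAIN_CODES[s][0] for s in e.strains],
                    "doses_cfu_per_g": list(e.doses),
                }
                for e in self.events
            ],
        }


def parse_schedule(
    shorthand: str, slot_days: Sequence[float] = DEFAULT_SLOT_DAYS
) -> Schedule:
    """Parse an arrow shorthand onto slot days.

    The k-th arrow group is inoculated on the k-th slot day;
    ``+``-joined codes share one event. Unknown codes, duplicate
    strains, and arrow-group/slot count mismatches are errors naming the
    offending token.
    """
    groups = [g.strip() for g in shorthand.replace("->", ARROW).split(ARROW)]
    if len(groups) != len(slot_days):
        raise ValueError(
            f"shorthand {shorthand!r} has {len(groups)} arrow groups but "
            f"{len(slot_days)} slot days"
        )
    events = []
    for day, group in zip(slot_days, groups):
        codes = tuple(c.strip() for c in group.split(PLUS))
        for c in codes:
            if c not in STRAIN_CODES:
                raise ValueError(f"unknown strain code {c!r} in {shorthand!r}")
        events.append(InoculationEvent(day=float(day), strains=codes))
    return Schedule(events=tuple(events))


def format_schedule(schedule: Schedule) -> str:
    """Inverse of :func:`parse_schedule` (written strain order preserved)."""
    return schedule.shorthand


@dataclass(frozen=True)
class ScheduleConstraints:
    """Design rules for the enumeration.

    The LAB set is distributed over the first ``n_lab_slots`` slot days
    with slot 0 holding a single starter from ``starters``; the yeasts
    are added together at the final slot day.
    """

    starters: tuple[str, ...] = ("W", "L")
    lab: tuple[str, ...] = ("W", "L", "P", "T")
    yeasts: tuple[str, ...] = ("Z", "C")
    slot_days: tuple[float, ...] = DEFAULT_SLOT_DAYS
    n_lab_slots: int = 3


def enumerate_schedules(
    constraints: ScheduleConstraints | None = None,
) -> list[Schedule]:
    """All distinct schedules satisfying the design constraints.

    Deduplicated by (day, strain-set) pairs; deterministic order by
    shorthand. Unsatisfiable constraints yield an empty list.
    """
    c = constraints or ScheduleConstraints()
    out: dict = {}
    n_follow = c.n_lab_slots - 1
    for starter in c.starters:
        if starter not in c.lab:
            continue
        rest = [s for s in c.lab if s != starter]
        for assignment in itertools.product(range(n_follow), repeat=len(rest)):
            slots: list[list[str]] = [[] for _ in range(n_follow)]
            for strain, slot in zip(rest, assignment):
                slots[slot].append(strain)
            if any(not s for s in slots):
                continue  # every LAB slot must be used
            groups = [[starter]] + slots + [list(c.yeasts)]
            if len(groups) != len(c.slot_days):
                continue
            try:
                sched = Schedule(
                    events=tuple(
                        InoculationEvent(day=float(d), strains=tuple(sorted(g)))
                        for d, g in zip(c.slot_days, groups)
                    )
                )
            except ValueError:
                continue
            out.setdefault(sched.key, sched)
    return sorted(out.values(), key=lambda s: s.shorthand)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Per-indicator comparison of schedule groups against a control."""

    table: pd.DataFrame  # indicator, day, group, mean, ratio_to_control,
    #                      tukey_p, significant
    anova: pd.DataFrame  # indicator, effect, F, p
    final_day_ranking: dict[str, list[str]]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "anova": self.anova.to_dict(orient="records"),
            "final_day_ranking": self.final_day_ranking,
        }


def compare_groups(
    series_per_group: Mapping[str, Sequence[IndicatorSeries] | IndicatorSeries],
    control_group: str,
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare fermentation outcomes across schedule groups.

    For every indicator: per-timepoint group means and ratios to the
    control, a two-way ANOVA (group x time), and per-time Tukey HSD
    contrasts against the control. Groups need >= 2 replicates at each
    compared timepoint. The final-day ranking orders groups by their
    mean at the last shared day, descending.
    """
    if control_group not in series_per_group:
        raise ValueError(f"control group {control_group!r} missing")
    rows = []
    for group, series in series_per_group.items():
        if isinstance(series, IndicatorSeries):
            series = [series]
        for s in series:
            for day, rep, value in s.observations:
                rows.append((group, s.name, day, rep, value))
    long = pd.DataFrame(rows, columns=["group", "indicator", "day", "replicate", "value"])

    out_rows = []
    anova_rows = []
    ranking: dict[str, list[str]] = {}
    for indicator, sub in long.groupby("indicator", sort=False):
        counts = sub.groupby(["group", "day"])["value"].count()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(
                f"indicator {indicator!r}: fewer than 2 replicates for {bad}"
            )
        # two-way ANOVA, group x time
        if sub["group"].nunique() > 1 and sub["day"].nunique() > 1:
            model = ols("value ~ C(group) * C(day)", data=sub).fit()
            av = anova_lm(model, typ=2)
            for effect in ("C(group)", "C(day)", "C(group):C(day)"):
                if effect in av.index:
                    anova_rows.append(
                        (indicator, effect, float(av.loc[effect, "F"]),
                         float(av.loc[effect, "PR(>F)"]))
                    )
        control_means = sub[sub["group"] == control_group].groupby("day")["value"].mean()
        for day, day_sub in sub.groupby("day"):
            if day not in control_means.index:
                continue
            cmean = control_means[day]
            day_groups = sorted(day_sub["group"].unique())
            tukey_p = None
            if len(day_groups) > 1 and day_sub.groupby("group")["value"].std().max() > 0:
                arrays = [
                    day_sub.loc[day_sub["group"] == g, "value"].to_numpy()
                    for g in day_groups
                ]
                tukey_p = tukey_pvalues(arrays)
            i_control = day_groups.index(control_group) if control_group in day_groups else None
            for group, g_sub in day_sub.groupby("group"):
                gmean = float(g_sub["value"].mean())
                p_adj, reject = None, False
                if tukey_p is not None and i_control is not None and group != control_group:
                    p_adj = float(tukey_p[i_control, day_groups.index(group)])
                    reject = bool(np.isfinite(p_adj) and p_adj < alpha)
                out_rows.append(
                    (
                        indicator,
                        float(day),
                        group,
                        gmean,
                        gmean / cmean if cmean != 0 else np.nan,
                        p_adj,
                        reject and group != control_group,
                    )
                )
        final_day = sub["day"].max()
        finals = sub[sub["day"] == final_day].groupby("group")["value"].mean()
        ranking[str(indicator)] = list(finals.sort_values(ascending=False).index)

    table = pd.DataFrame(
        out_rows,
        columns=["indicator", "day", "group", "mean", "ratio_to_control",
                 "tukey_p", "significant"],
    )
    anova = pd.DataFrame(anova_rows, columns=["indicator", "effect", "F", "p"])
    return GroupComparison(table=table, anova=anova, final_day_ranking=ranking)
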