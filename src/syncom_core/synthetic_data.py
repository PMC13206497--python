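"""Synthetic fermentation datasets with planted, recorded ground truth.

Emulates a ~40-day brine (moromi) fermentation sampled at ~9 timepoints
x 3 replicates: 55 bacterial + 28 fungal taxa with succession (early
lactic acid bacteria and koji mold giving way to late halophilic LAB and
yeasts), ~128 volatile compounds in seven classes, and the standard
physicochemical indicator trajectories (glutamate and lactic acid rising
early, 4-ethylguaiacol rising only late, a reducing-sugar hump, monotone
pH decline).

The planted structure gives every pipeline stage an oracle:

* latent log-abundance trajectories are piecewise-logistic with steps at
  the planted phase changepoints; replicates share the latent and differ
  only by multiplicative log-normal noise (``noise_sd``, log scale);
* two cliques (an early-falling and a late-rising group) share a common
  latent each, so within-clique rank correlations exceed the network edge
  threshold and clique members become hubs;
* core taxa are additionally abundant (passing the dominance screen) and
  carry at least ``flavor_links`` volatile producer links, so they pass
  all three selection criteria in expectation;
* decoy taxa pass exactly one or two criteria: low-abundance clique
  members (hub + flavor, not dominant), flat abundant taxa (dominant
  only), an abundant producer outside the cliques (dominant + flavor,
  not hub), low-abundance producers (flavor only), and sparse taxa that
  are abundant when present but fail the prevalence screen;
* volatile concentrations respond linearly to their producers' relative
  abundance, so association signs are planted unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import expit

from .datamodel_io import (
    AbundanceTable,
    IndicatorSeries,
    SampleMeta,
    VolatileTable,
    write_json,
)

#: Published class composition (counts) used as class proportions.
VOLATILE_CLASS_COUNTS = {
    "alcohol": 16,
    "phenol": 6,
    "pyrazine": 10,
    "aldehyde": 21,
    "ketone": 26,
    "ester": 47,
    "acid": 9,
}

#: The canonical nine-species planted core, split by succession timing.
EARLY_CORE = (
    "Weissella paramesenteroides",
    "Lactiplantibacillus plantarum",
    "Staphylococcus epidermidis",
    "Aspergillus oryzae",
)
LATE_CORE = (
    "Tetragenococcus halophilus",
    "Pediococcus pentosaceus",
    "Pediococcus acidilactici",
    "Zygosaccharomyces rouxii",
    "Candida orthopsilosis",
)

#: Emulated omission effect sizes (% decrease) per core taxon:
#: (umami amino acids, 4-ethylguaiacol). Non-zero entries mirror the
#: outcomes of the leave-one-out fermentations this module emulates;
#: two members (P. acidilactici, S. epidermidis) are planted null and are
#: expected to be pruned from the final core.
EMULATED_OMISSION_EFFECTS: Mapping[str, tuple[float, float]] = {
    "Weissella paramesenteroides": (27.2, 30.0),
    "Lactiplantibacillus plantarum": (15.5, 42.8),
    "Tetragenococcus halophilus": (25.9, 25.0),
    "Pediococcus pentosaceus": (15.8, 20.0),
    "Pediococcus acidilactici": (0.0, 0.0),
    "Staphylococcus epidermidis": (0.0, 0.0),
    "Zygosaccharomyces rouxii": (0.0, 45.6),
    "Candida orthopsilosis": (0.0, 56.5),
    "Aspergillus oryzae": (20.0, 20.0),
}

DEFAULT_CONTROL_MEANS = {"umami_AA": 10.0, "4EG": 70.0}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic fermentation.

    Defaults mirror the emulated fermentation: 55 bacterial + 28 fungal
    taxa, 9 timepoints over 40 days, 3 replicates, 128 volatiles, a
    9-member planted core. ``noise_sd`` is the log-scale standard
    deviation of replicate-level multiplicative noise on abundances;
    ``producer_effect`` scales the linear volatile response to producer
    relative abundance; ``clique_size`` must exceed the hub degree
    threshold + 1 for planted hubs to be recoverable.
    """

    n_bacterial_taxa: int = 55
    n_fungal_taxa: int = 28
    n_timepoints: int = 9
    total_days: float = 40.0
    n_replicates: int = 3
    n_volatiles: int = 128
    n_core: int = 9
    clique_size: int = 12
    noise_sd: float = 0.3
    producer_effect: float = 1.5
    flavor_links: int = 6
    volatile_noise_cv: float = 0.08
    measurement_cv: float = 0.04
    seed: int = 0

    # decoy counts (dominant-only, dominant+flavor, flavor-only, sparse)
    n_dominant_decoys: int = 2
    n_domflavor_decoys: int = 1
    n_flavor_decoys: int = 2
    n_sparse_decoys: int = 3

    def __post_init__(self) -> None:
        n_taxa = self.n_bacterial_taxa + self.n_fungal_taxa
        if self.n_core > n_taxa:
            raise ValueError(f"n_core={self.n_core} exceeds roster of {n_taxa} taxa")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_timepoints < 4:
            raise ValueError("need at least 4 timepoints")
        if self.clique_size > n_taxa:
            raise ValueError("clique larger than taxon roster")
        n_early = max(1, round(self.n_core * 4 / 9))
        n_late = self.n_core - n_early
        if self.clique_size < max(n_early, n_late):
            raise ValueError("clique_size smaller than a core succession group")
        n_decoys = (
            2 * self.clique_size
            - self.n_core
            + self.n_dominant_decoys
            + self.n_domflavor_decoys
            + self.n_flavor_decoys
            + self.n_sparse_decoys
        )
        if self.n_core + n_decoys > n_taxa:
            raise ValueError(
                f"roster of {n_taxa} taxa too small for {self.n_core} core + "
                f"{n_decoys} decoy taxa"
            )
        n_producers = self.n_core + self.n_domflavor_decoys + self.n_flavor_decoys
        if n_producers * self.flavor_links > self.n_volatiles:
            raise ValueError(
                f"{n_producers} producers x {self.flavor_links} links exceed "
                f"{self.n_volatiles} volatiles"
            )


@dataclass
class SyntheticTruth:
    """Everything planted by :func:`generate_dataset`.

    ``changepoints`` are the last sampled day of each phase (exclusive
    upper boundaries fall between that day and the next sample).
    """

    core_taxa: set[str]
    clique_memberships: list[set[str]]
    producer_links: dict[tuple[str, str], float]
    changepoints: list[float]
    total_days: float
    early_indicators: set[str] = field(default_factory=set)
    late_indicators: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        cps = list(self.changepoints)
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("changepoints must be strictly increasing")
        if cps and (cps[0] <= 0 or cps[-1] >= self.total_days):
            raise ValueError("changepoints must be interior to [0, total_days]")

    def to_json(self, path) -> None:
        write_json(
            {
                "core_taxa": sorted(self.core_taxa),
                "clique_memberships": [sorted(c) for c in self.clique_memberships],
                "producer_links": [
                    {"taxon": t, "compound": c, "effect": e}
                    for (t, c), e in sorted(self.producer_links.items())
                ],
                "changepoints": self.changepoints,
                "total_days": self.total_days,
                "early_indicators": sorted(self.early_indicators),
                "late_indicators": sorted(self.late_indicators),
            },
            path,
        )


def _volatile_roster(n_volatiles: int) -> list[tuple[str, str]]:
    """n compounds allocated to the seven classes by largest remainder."""
    total = sum(VOLATILE_CLASS_COUNTS.values())
    quotas = {c: n_volatiles * k / total for c, k in VOLATILE_CLASS_COUNTS.items()}
    counts = {c: int(q) for c, q in quotas.items()}
    short = n_volatiles - sum(counts.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    out = []
    for cls in VOLATILE_CLASS_COUNTS:
        for i in range(counts[cls]):
            out.append((f"{cls}_{i + 1:02d}", cls))
    return out


def _smooth_step(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return expit((t - center) / width)


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[AbundanceTable, VolatileTable, list[IndicatorSeries], SyntheticTruth]:
    """Simulate one fermentation run with planted ground truth.

    Returns the closed (relative-abundance) taxon table, the volatile
    table, the indicator series, and the truth record.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    n_taxa = cfg.n_bacterial_taxa + cfg.n_fungal_taxa
    days = np.linspace(0.0, cfg.total_days, cfg.n_timepoints)
    step = cfg.total_days / (cfg.n_timepoints - 1)
    changepoints = [cfg.total_days * f for f in (0.125, 0.375, 0.625)]
    centers = [cp + step / 2 for cp in changepoints]
    width = step / 4
    s1, s2, s3 = (_smooth_step(days, c, width) for c in centers)
    early_latent = -(1.2 * s1 + 1.8 * s2 + 0.8 * s3)
    late_latent = 0.8 * s1 + 1.8 * s2 + 1.2 * s3

    # --- roster and roles -------------------------------------------------
    n_early = max(1, round(cfg.n_core * 4 / 9))
    n_late = cfg.n_core - n_early
    if cfg.n_core == 9:
        early_core, late_core = list(EARLY_CORE), list(LATE_CORE)
    else:
        early_core = [f"Bacterium_core_early_{i + 1}" for i in range(n_early)]
        late_core = [f"Bacterium_core_late_{i + 1}" for i in range(n_late)]
    core = early_core + late_core

    n_named = len(core)
    n_bact_extra = cfg.n_bacterial_taxa - sum(
        1 for t in core if not t.split()[0] in
        ("Aspergillus", "Zygosaccharomyces", "Candida")
    ) if cfg.n_core == 9 else cfg.n_bacterial_taxa - n_named
    n_fung_extra = n_taxa - n_named - n_bact_extra
    pool = [f"Bacterium_sp_{i + 1:03d}" for i in range(n_bact_extra)] + [
        f"Fungus_sp_{i + 1:03d}" for i in range(n_fung_extra)
    ]
    rng.shuffle(pool)
    pool_iter = iter(pool)

    def take(k: int) -> list[str]:
        return [next(pool_iter) for _ in range(k)]

    early_decoys = take(cfg.clique_size - n_early)
    late_decoys = take(cfg.clique_size - n_late)
    dominant_decoys = take(cfg.n_dominant_decoys)
    domflavor_decoys = take(cfg.n_domflavor_decoys)
    flavor_decoys = take(cfg.n_flavor_decoys)
    sparse_decoys = take(cfg.n_sparse_decoys)
    background = list(pool_iter)

    taxa = (
        core
        + early_decoys
        + late_decoys
        + dominant_decoys
        + domflavor_decoys
        + flavor_decoys
        + sparse_decoys
        + background
    )
    early_clique = set(early_core) | set(early_decoys)
    late_clique = set(late_core) | set(late_decoys)

    # --- latent log-abundances (taxon x timepoint) ------------------------
    log_base = np.empty(len(taxa))
    latent = np.zeros((len(taxa), cfg.n_timepoints))
    wiggle_sd = np.full(len(taxa), 0.12)
    for i, t in enumerate(taxa):
        if t in set(early_core):
            log_base[i] = np.log(rng.uniform(150, 280))
            latent[i] = early_latent
            wiggle_sd[i] = 0.08
        elif t in set(late_core):
            log_base[i] = np.log(rng.uniform(5, 10))
            latent[i] = late_latent
            wiggle_sd[i] = 0.08
        elif t in early_clique:
            log_base[i] = np.log(rng.uniform(15, 30))
            latent[i] = early_latent
            wiggle_sd[i] = 0.08
        elif t in late_clique:
            log_base[i] = np.log(rng.uniform(0.4, 0.8))
            latent[i] = late_latent
            wiggle_sd[i] = 0.08
        elif t in set(dominant_decoys) or t in set(domflavor_decoys):
            log_base[i] = np.log(rng.uniform(60, 120))
        elif t in set(flavor_decoys):
            log_base[i] = np.log(rng.uniform(8, 14))
        elif t in set(sparse_decoys):
            log_base[i] = np.log(rng.uniform(20, 45))
        else:
            log_base[i] = np.log(rng.uniform(3, 14))

    wiggle = rng.normal(0.0, 1.0, size=latent.shape) * wiggle_sd[:, None]
    log_latent = log_base[:, None] + latent + wiggle

    # sparse decoys exist only in a mid-fermentation window
    window = (days >= 0.25 * cfg.total_days) & (days <= 0.625 * cfg.total_days)
    sparse_idx = [taxa.index(t) for t in sparse_decoys]

    # stabilize the combined load of the time-varying taxa: closure is
    # scale-invariant per sample, so if the succession groups' total
    # varied over time it would imprint its inverse on every flat taxon
    # as a shared trajectory, creating spurious correlations
    det = np.exp(log_latent)
    for si in sparse_idx:
        det[si, ~window] = 0.0
    varying = np.zeros(len(taxa), dtype=bool)
    for i, t in enumerate(taxa):
        if t in early_clique or t in late_clique or t in set(sparse_decoys):
            varying[i] = True
    v_load = det[varying].sum(axis=0)
    log_latent[varying] -= np.log(v_load / v_load.mean())[None, :]

    # --- replicates, noise, closure ---------------------------------------
    samples: list[SampleMeta] = []
    columns = []
    for ti, day in enumerate(days):
        for rep in range(1, cfg.n_replicates + 1):
            noise = rng.normal(0.0, cfg.noise_sd, size=len(taxa)) if cfg.noise_sd > 0 else 0.0
            abund = np.exp(log_latent[:, ti] + noise)
            for si in sparse_idx:
                if not window[ti]:
                    abund[si] = 0.0
            columns.append(abund / abund.sum())
            samples.append(
                SampleMeta(sample_id=f"d{day:04.1f}_r{rep}", day=float(day), replicate=rep)
            )
    values = np.column_stack(columns)
    abundance = AbundanceTable(
        taxa=taxa, samples=samples, values=values, level="species", normalized=True
    )

    # --- volatiles ---------------------------------------------------------
    compounds = _volatile_roster(cfg.n_volatiles)
    producers = core + domflavor_decoys + flavor_decoys
    link_slots = rng.permutation(cfg.n_volatiles)
    producer_links: dict[tuple[str, str], float] = {}
    baselines = rng.uniform(20, 200, size=cfg.n_volatiles)
    vvalues = np.tile(baselines[:, None], (1, len(samples)))
    slot = 0
    for taxon in producers:
        ra = abundance.row(taxon)
        ra_norm = ra / ra.mean()
        for _ in range(cfg.flavor_links):
            vi = link_slots[slot]
            slot += 1
            effect = cfg.producer_effect * rng.uniform(0.8, 1.2)
            vvalues[vi] = baselines[vi] * (1.0 + effect * ra_norm)
            producer_links[(taxon, compounds[vi][0])] = float(effect)
    if cfg.volatile_noise_cv > 0:
        vvalues = vvalues + rng.normal(
            0.0, 1.0, size=vvalues.shape
        ) * (cfg.volatile_noise_cv * baselines[:, None])
    vvalues = np.clip(vvalues, 0.0, None)
    volatiles = VolatileTable(compounds=compounds, samples=list(samples), values=vvalues)

    # --- indicators ---------------------------------------------------------
    indicators = _indicator_series(days, cfg, rng)

    truth = SyntheticTruth(
        core_taxa=set(core),
        clique_memberships=[early_clique, late_clique],
        producer_links=producer_links,
        changepoints=changepoints,
        total_days=cfg.total_days,
        early_indicators={
            "glutamic_acid", "umami_AA", "lactic_acid",
            "reducing_sugar", "amino_N", "pH",
        },
        late_indicators={"4EG"},
    )
    return abundance, volatiles, indicators, truth


def _indicator_series(
    days: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator
) -> list[IndicatorSeries]:
    """Indicator trajectories on a reference 40-day clock, time-rescaled."""
    t = days * (40.0 / cfg.total_days)
    sugar_shape = PchipInterpolator(
        np.array([0, 5, 10, 15, 20, 25, 30, 35, 40], dtype=float),
        np.array([5.0, 14.0, 21.1, 19.2, 18.4, 15.0, 12.0, 10.0, 8.5]),
    )
    means = {
        "glutamic_acid": 8.5 * expit((t - 10) / 3.5),
        "umami_AA": 12.0 * expit((t - 10) / 4.0),
        "amino_N": 0.15 + 0.85 * expit((t - 12) / 5.0),
        "total_N": 1.55 + 0.1 * t / 40.0,
        # three-wave rise: distinct synthesis phases at ~0-5, 5-10, 10-20 d
        "lactic_acid": (
            4.0 * expit((t - 2.5) / 0.8)
            + 4.0 * expit((t - 7.5) / 0.8)
            + 4.0 * expit((t - 15.0) / 1.5)
        ),
        "reducing_sugar": sugar_shape(t),
        "4EG": (71.32 / expit((40 - 32) / 2.5)) * expit((t - 32) / 2.5),
        "pH": 6.8 - 2.1 * expit((t - 8) / 3.0),
    }
    out = []
    for name, mean in means.items():
        obs = []
        for ti, day in enumerate(days):
            for rep in range(1, cfg.n_replicates + 1):
                if name == "pH":
                    v = mean[ti] + (rng.normal(0.0, 0.05) if cfg.measurement_cv > 0 else 0.0)
                else:
                    noise = rng.normal(0.0, cfg.measurement_cv) if cfg.measurement_cv > 0 else 0.0
                    v = max(mean[ti] * (1.0 + noise), 0.0)
                obs.append((float(day), rep, float(v)))
        out.append(IndicatorSeries(name=name, observations=obs))
    return out


def generate_omission_data(
    truth: SyntheticTruth,
    effects: Mapping[str, tuple[float, float]] | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    control_means: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Leave-one-strain-out measurement table (long format).

    ``effects`` maps each core taxon to its planted percent decrease on
    (umami amino acids, 4-ethylguaiacol); by default every core member
    gets a clearly detectable (25%, 40%) effect, so the pruned final
    core equals the planted core. Pass
    :data:`EMULATED_OMISSION_EFFECTS` to reproduce the emulated
    leave-one-out outcomes, where two members are planted null. Control
    replicates are drawn around fixed means; each omission group's mean
    is reduced by its stated percent. ``noise_sd`` is the relative (CV)
    measurement noise.
    """
    if effects is None:
        effects = {t: (25.0, 40.0) for t in truth.core_taxa}
    missing = truth.core_taxa - set(effects)
    if missing:
        raise ValueError(f"no omission effects defined for core taxa: {sorted(missing)}")
    control_means = dict(control_means or DEFAULT_CONTROL_MEANS)
    indicators = list(control_means)

    rng = np.random.default_rng(seed)
    rows = []

    def draw(mean: float) -> float:
        if noise_sd == 0:
            return mean
        return mean * (1.0 + rng.normal(0.0, noise_sd))

    for indicator in indicators:
        for rep in range(1, n_replicates + 1):
            rows.append(("control", indicator, rep, draw(control_means[indicator])))
    for taxon in sorted(effects):
        umami_pct, eg_pct = effects[taxon]
        for indicator, pct in zip(("umami_AA", "4EG"), (umami_pct, eg_pct)):
            if indicator not in control_means:
                continue
            mean = control_means[indicator] * (1.0 - pct / 100.0)
            if mean < 0:
                raise ValueError(
                    f"effect {pct}% for {taxon!r} on {indicator!r} yields a "
                    "negative mean"
                )
            for rep in range(1, n_replicates + 1):
                rows.append((f"omit_{taxon}", indicator, rep, draw(mean)))
    return pd.DataFrame(rows, columns=["group", "indicator", "replicate", "value"])
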