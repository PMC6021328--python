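"""Synthetic paired tumor/normal cohorts with planted amplification truth.

Generates probe-level copy-number tracks (arbitrary units, diploid = 2),
germline CNVs shared by both tracks, class-specific somatic amplicons,
broad polyploid gains, and survival times whose distribution depends on the
planted GAP class — everything downstream of the wet lab, desk-scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calling import ProbeTrack
from .classify import GapClass, risk_group
from .genome import CytobandMap, GeneCatalog, GenomicInterval

#: saturation exponent of the copies->value transform, solved so that
#: 7 copies map to 4.8 arbitrary units: 2 + (7-2)**alpha = 4.8.
DEFAULT_ALPHA = math.log(2.8) / math.log(5.0)


def copies_to_value(copies: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Map a true DNA copy number to the arbitrary measurement scale.

    Diploid anchors at exactly 2; above 2 the response saturates as
    ``2 + (c - 2) ** alpha`` so that 7 copies give 4.8 units while broad
    3-4-copy polyploid gains stay well below the amplification cutoff;
    below 2 the map is linear (1 copy -> 1 unit).
    """
    if copies < 0:
        raise ValueError(f"copy number must be >= 0, got {copies}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if copies >= 2:
        return 2.0 + (copies - 2.0) ** alpha
    return float(copies)


@dataclass(frozen=True)
class PlannedEvent:
    """A somatic amplification to plant: band, true copies, length in bp.

    ``anchor_gene`` centres the event on that gene's locus (it must lie in
    ``band``); otherwise the event is centred within the band.
    """

    band: str
    copies: float
    length: int
    anchor_gene: str | None = None


def _default_event_menu() -> dict[GapClass, tuple[PlannedEvent, ...]]:
    return {
        GapClass.NO_AMP: (),
        GapClass.EGFR_ONLY: (
            PlannedEvent("7p11.2", 12, 1_500_000, "EGFR"),
        ),
        GapClass.NON_EGFR_SINGLE: (
            PlannedEvent("4q12", 10, 1_200_000, "PDGFRA"),
        ),
        GapClass.MULTI_WITH_EGFR: (
            PlannedEvent("7p11.2", 12, 1_500_000, "EGFR"),
            PlannedEvent("12q14.1", 9, 1_200_000, "CDK4"),
        ),
        GapClass.MULTI_WITHOUT_EGFR: (
            PlannedEvent("4q12", 10, 1_200_000, "PDGFRA"),
            PlannedEvent("12q15", 9, 1_200_000, "MDM2"),
        ),
    }


def _default_medians() -> dict[GapClass, float]:
    # class-specific median OS in months
    return {
        GapClass.NO_AMP: 13.0,
        GapClass.EGFR_ONLY: 17.0,
        GapClass.NON_EGFR_SINGLE: 6.0,
        GapClass.MULTI_WITH_EGFR: 13.0,
        GapClass.MULTI_WITHOUT_EGFR: 8.0,
    }


def _default_proportions() -> dict[GapClass, float]:
    return {
        GapClass.NO_AMP: 0.44,
        GapClass.EGFR_ONLY: 0.21,
        GapClass.NON_EGFR_SINGLE: 0.13,
        GapClass.MULTI_WITH_EGFR: 0.16,
        GapClass.MULTI_WITHOUT_EGFR: 0.06,
    }


@dataclass(frozen=True)
class SimConfig:
    probe_spacing: int = 50_000
    noise_sd: float = 0.4          # additive Gaussian noise on the value scale
    alpha: float = DEFAULT_ALPHA
    germline_rate: float = 3.0     # expected germline CNVs per genome
    germline_length: tuple[int, int] = (100_000, 600_000)
    germline_copy_choices: tuple[float, ...] = (1.0, 3.0)
    event_menu: dict[GapClass, tuple[PlannedEvent, ...]] = field(
        default_factory=_default_event_menu)
    survival_medians: dict[GapClass, float] = field(default_factory=_default_medians)
    class_proportions: dict[GapClass, float] = field(
        default_factory=_default_proportions)
    followup_range: tuple[float, float] | None = (18.0, 84.0)
    polyploid_prob: float = 0.5    # NO_AMP chance of a whole-chromosome gain
    polyploid_copies: tuple[float, float] = (3.0, 4.0)
    polyploid_chrom: str = "7"
    chromosomes: tuple[str, ...] | None = None   # restrict genome for speed

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if any(m <= 0 for m in self.survival_medians.values()):
            raise ValueError("survival medians must be > 0")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")


@dataclass
class SimulatedPatient:
    patient_id: str
    gap_class: GapClass
    events: list[tuple[str, float, GenomicInterval]]     # somatic truth
    germline_cnvs: list[tuple[float, GenomicInterval]]   # shared truth
    tumor: ProbeTrack
    normal: ProbeTrack
    clinical: dict


def _probe_grid(cytobands: CytobandMap, config: SimConfig):
    chroms = (
        list(config.chromosomes) if config.chromosomes is not None
        else cytobands.chromosomes
    )
    grid = []
    for c in chroms:
        length = cytobands.chrom_length(c)
        pos = np.arange(config.probe_spacing // 2, length, config.probe_spacing,
                        dtype=np.int64)
        grid.append((c, pos))
    return grid


def _event_interval(
    ev: PlannedEvent, cytobands: CytobandMap, catalog: GeneCatalog | None
) -> GenomicInterval:
    if not cytobands.has_band(ev.band):
        raise ValueError(f"event band {ev.band!r} absent from annotation")
    band_iv = cytobands.band_interval(ev.band)
    if ev.anchor_gene and catalog is not None and ev.anchor_gene in catalog:
        center = catalog[ev.anchor_gene].interval.midpoint
    else:
        center = band_iv.midpoint
    start = max(0, center - ev.length // 2)
    return GenomicInterval(band_iv.chrom, start, start + ev.length)


def _apply(values: dict[str, np.ndarray], grid, iv: GenomicInterval, value: float):
    for chrom, pos in grid:
        if chrom == iv.chrom:
            mask = (pos >= iv.start) & (pos < iv.end)
            values[chrom][mask] = value


def simulate_pair(
    config: SimConfig,
    gap_class: GapClass,
    seed,
    cytobands: CytobandMap,
    catalog: GeneCatalog | None = None,
    patient_id: str = "SIM",
) -> SimulatedPatient:
    """Simulate one tumor/normal probe-track pair with planted truth.

    The normal track is diploid plus germline CNVs plus noise; the tumor
    track shares the germline baseline and additionally carries the somatic
    events of the class menu (plus, for NO_AMP, a possible whole-chromosome
    polyploid gain). Identical seed and config give a bit-identical patient.
    """
    rng = np.random.default_rng(seed)
    grid = _probe_grid(cytobands, config)
    if gap_class not in config.event_menu:
        raise ValueError(f"no event menu for class {gap_class}")
    somatic = [
        (ev.band, ev.copies, _event_interval(ev, cytobands, catalog))
        for ev in config.event_menu[gap_class]
    ]

    # germline CNVs, rejected if they collide with a planted somatic event
    chrom_lengths = {c: int(pos[-1]) + config.probe_spacing for c, pos in grid}
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    germline: list[tuple[float, GenomicInterval]] = []
    n_germ = rng.poisson(config.germline_rate)
    attempts = 0
    while len(germline) < n_germ and attempts < 100 * (n_germ + 1):
        attempts += 1
        c = chroms[rng.choice(len(chroms), p=weights)]
        length = int(rng.integers(*config.germline_length))
        start = int(rng.integers(0, max(1, chrom_lengths[c] - length)))
        iv = GenomicInterval(c, start, start + length)
        if any(iv.overlaps(siv) for _, _, siv in somatic):
            continue
        if any(iv.overlaps(giv) for _, giv in germline):
            continue
        copies = float(rng.choice(config.germline_copy_choices))
        germline.append((copies, iv))

    base = {c: np.full(len(pos), 2.0) for c, pos in grid}
    for copies, iv in germline:
        _apply(base, grid, iv, copies_to_value(copies, config.alpha))

    tumor_vals = {c: v.copy() for c, v in base.items()}
    if gap_class is GapClass.NO_AMP and rng.random() < config.polyploid_prob:
        c = config.polyploid_chrom
        if c in tumor_vals:
            copies = float(rng.uniform(*config.polyploid_copies))
            tumor_vals[c][:] = copies_to_value(copies, config.alpha)
            # germline CNVs keep their own level in both tracks
            for gcopies, giv in germline:
                if giv.chrom == c:
                    _apply(tumor_vals, grid, giv,
                           copies_to_value(gcopies, config.alpha))
    for _, copies, iv in somatic:
        _apply(tumor_vals, grid, iv, copies_to_value(copies, config.alpha))

    def track(sample: str, values: dict[str, np.ndarray]) -> ProbeTrack:
        chrom_col, pos_col, val_col = [], [], []
        for c, pos in grid:
            v = values[c]
            if config.noise_sd > 0:
                v = v + rng.normal(0.0, config.noise_sd, size=len(v))
            v = np.clip(v, 0.0, None)
            chrom_col.append(np.full(len(pos), c, dtype=object))
            pos_col.append(pos)
            val_col.append(v)
        return ProbeTrack(sample, np.concatenate(chrom_col),
                          np.concatenate(pos_col), np.concatenate(val_col))

    normal = track(f"{patient_id}:normal", base)
    tumor = track(f"{patient_id}:tumor", tumor_vals)

    os_months, event = simulate_survival(gap_class, config, rng)
    clinical = {
        "id": patient_id,
        "age": int(np.clip(round(rng.normal(62, 13)), 24, 84)),
        "sex": str(rng.choice(["M", "F"])),
        "karnofsky": int(rng.choice([40, 50, 60, 70, 80, 90, 100])),
        "surgery": str(rng.choice(["total", "partial", "biopsy"])),
        "chemotherapy": str(rng.choice(["Stupp", "Sequential", "None"])),
        "os_months": os_months,
        "event": event,
    }
    return SimulatedPatient(patient_id, gap_class, somatic, germline,
                            tumor, normal, clinical)


def simulate_survival(gap_class: GapClass, config: SimConfig, rng) -> tuple[int, int]:
    """Draw (os_months, event flag) for one patient.

    OS is exponential with the class-specific median (rate ln2 / median),
    rounded to whole months with a floor of 1; administrative censoring at a
    follow-up horizon drawn uniformly from ``followup_range`` (no censoring
    when the range is None).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    median = config.survival_medians[gap_class]
    os_raw = rng.exponential(median / math.log(2.0))
    os_months = max(1, int(round(os_raw)))
    if config.followup_range is None:
        return os_months, 1
    horizon = max(1, int(round(rng.uniform(*config.followup_range))))
    if os_months > horizon:
        return horizon, 0
    return os_months, 1


@dataclass
class Cohort:
    patients: list[SimulatedPatient]
    config: SimConfig
    seed: int

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append({
                "id": p.patient_id,
                "gap_class": p.gap_class.value,
                "risk_group": risk_group(p.gap_class).value,
                "events": ";".join(
                    f"{band}:{copies:g}:{iv.chrom}:{iv.start}-{iv.end}"
                    for band, copies, iv in p.events
                ),
                "germline_cnvs": ";".join(
                    f"{copies:g}:{iv.chrom}:{iv.start}-{iv.end}"
                    for copies, iv in p.germline_cnvs
                ),
            })
        return pd.DataFrame(rows, columns=["id", "gap_class", "risk_group",
                                           "events", "germline_cnvs"])

    def clinical_table(self) -> pd.DataFrame:
        cols = ["id", "age", "sex", "karnofsky", "surgery", "chemotherapy",
                "os_months", "event"]
        return pd.DataFrame([p.clinical for p in self.patients], columns=cols)


def simulate_cohort(
    config: SimConfig,
    n: int,
    seed: int,
    cytobands: CytobandMap,
    catalog: GeneCatalog | None = None,
) -> Cohort:
    """Simulate ``n`` patients with classes drawn from the class proportions."""
    classes = sorted(config.class_proportions, key=lambda c: c.value)
    probs = np.array([config.class_proportions[c] for c in classes])
    root = np.random.SeedSequence(seed)
    class_rng = np.random.default_rng(root.spawn(1)[0])
    drawn = class_rng.choice(len(classes), size=n, p=probs)
    patients = []
    for i, child in enumerate(root.spawn(n + 1)[1:]):
        patients.append(simulate_pair(
            config, classes[drawn[i]], child, cytobands, catalog,
            patient_id=f"P{i + 1:04d}",
        ))
    return Cohort(patients, config, seed)
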