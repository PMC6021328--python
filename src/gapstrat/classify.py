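"""Per-tumor amplification profiles, five-class GAP labels and risk groups.

A "chromosomal region" is a chromosome arm: multiple amplified bands on one
arm count as a single region, while amplification on both arms of a
chromosome counts as two.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .calling import Amplicon
from .genome import GeneCatalog

logger = logging.getLogger(__name__)

EGFR_GENE = "EGFR"
EGFR_BAND = "7p11.2"

_BAND_RE = re.compile(r"^(\d+|X|Y)([pq])")


class GapClass(str, Enum):
    """Five-level gene-amplification-profile class."""

    NO_AMP = "NO_AMP"
    EGFR_ONLY = "EGFR_ONLY"
    NON_EGFR_SINGLE = "NON_EGFR_SINGLE"
    MULTI_WITH_EGFR = "MULTI_WITH_EGFR"
    MULTI_WITHOUT_EGFR = "MULTI_WITHOUT_EGFR"


class RiskGroup(str, Enum):
    """Two-level regrouping of :class:`GapClass`."""

    FAVORABLE = "FAVORABLE"
    UNFAVORABLE = "UNFAVORABLE"


GAP_CLASS_ORDER = [
    GapClass.NO_AMP,
    GapClass.EGFR_ONLY,
    GapClass.NON_EGFR_SINGLE,
    GapClass.MULTI_WITH_EGFR,
    GapClass.MULTI_WITHOUT_EGFR,
]

_RISK_MAP = {
    GapClass.NO_AMP: RiskGroup.FAVORABLE,
    GapClass.EGFR_ONLY: RiskGroup.FAVORABLE,
    GapClass.MULTI_WITH_EGFR: RiskGroup.FAVORABLE,
    GapClass.NON_EGFR_SINGLE: RiskGroup.UNFAVORABLE,
    GapClass.MULTI_WITHOUT_EGFR: RiskGroup.UNFAVORABLE,
}


def arm_of_band(band_label: str) -> str:
    """``"7p11.2" -> "7p"``."""
    m = _BAND_RE.match(band_label)
    if not m:
        raise ValueError(f"malformed band label {band_label!r}")
    return m.group(1) + m.group(2)


@dataclass(frozen=True)
class AmplificationProfile:
    """Set of amplified arms/bands/genes for one tumor."""

    tumor_id: str
    arms: frozenset[str] = field(default_factory=frozenset)
    bands: frozenset[str] = field(default_factory=frozenset)
    genes: frozenset[str] = field(default_factory=frozenset)
    egfr_involved: bool = False

    @property
    def n_regions(self) -> int:
        return len(self.arms)


def build_profile(
    tumor_id: str,
    amplicons: Sequence[Amplicon],
    catalog: GeneCatalog | None = None,
) -> AmplificationProfile:
    """Aggregate one tumor's amplicons into an :class:`AmplificationProfile`.

    EGFR involvement is decided by gene membership when a gene catalog was
    available to the caller; without gene resolution (e.g. external SEG
    input) it falls back to overlap with band ``7p11.2``.
    """
    arms: set[str] = set()
    bands: set[str] = set()
    genes: set[str] = set()
    for amp in amplicons:
        arms.update(amp.arms)
        bands.update(amp.bands)
        genes.update(amp.genes)
    if catalog is not None and EGFR_GENE in catalog:
        egfr = EGFR_GENE in genes
    else:
        if amplicons and catalog is None:
            logger.warning(
                "%s: no gene catalog; EGFR involvement falls back to band %s overlap",
                tumor_id, EGFR_BAND,
            )
        egfr = EGFR_BAND in bands
    return AmplificationProfile(
        tumor_id, frozenset(arms), frozenset(bands), frozenset(genes), egfr
    )


def profile_from_bands(tumor_id: str, band_labels: Iterable[str]) -> AmplificationProfile:
    """Profile from amplified band labels alone (fixture / band-level input).

    EGFR involvement uses the band fallback (``7p11.2`` present).
    """
    bands = frozenset(band_labels)
    arms = frozenset(arm_of_band(b) for b in bands)
    return AmplificationProfile(tumor_id, arms, bands, frozenset(), EGFR_BAND in bands)


def classify_gap(profile: AmplificationProfile) -> GapClass:
    """Total, mutually exclusive assignment of the five GAP classes."""
    if profile.n_regions == 0:
        return GapClass.NO_AMP
    if profile.n_regions == 1:
        return GapClass.EGFR_ONLY if profile.egfr_involved else GapClass.NON_EGFR_SINGLE
    return (
        GapClass.MULTI_WITH_EGFR if profile.egfr_involved
        else GapClass.MULTI_WITHOUT_EGFR
    )


def risk_group(gap: GapClass) -> RiskGroup:
    return _RISK_MAP[gap]


def cohort_frequency_table(profiles: Sequence[AmplificationProfile]) -> pd.DataFrame:
    """Count and percentage of each GAP class over a cohort (one row per class)."""
    ids = [p.tumor_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate tumor ids: {dupes}")
    n = len(profiles)
    counts = {c: 0 for c in GAP_CLASS_ORDER}
    for p in profiles:
        counts[classify_gap(p)] += 1
    return pd.DataFrame({
        "gap_class": [c.value for c in GAP_CLASS_ORDER],
        "count": [counts[c] for c in GAP_CLASS_ORDER],
        "pct_of_cohort": [100.0 * counts[c] / n if n else 0.0 for c in GAP_CLASS_ORDER],
    })


def gene_frequency_table(profiles: Sequence[AmplificationProfile]) -> pd.DataFrame:
    """Per-gene amplification counts, as a percentage of amplified tumors."""
    amplified = [p for p in profiles if p.n_regions > 0]
    n_amp = len(amplified)
    counts: dict[str, int] = {}
    for p in amplified:
        for g in p.genes:
            counts[g] = counts.get(g, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame({
        "gene": [g for g, _ in rows],
        "count": [c for _, c in rows],
        "pct_of_amplified": [100.0 * c / n_amp if n_amp else 0.0 for _, c in rows],
    })


def classification_table(profiles: Sequence[AmplificationProfile]) -> pd.DataFrame:
    """Per-tumor table: id, arms, bands, EGFR flag, class, risk group."""
    rows = []
    for p in profiles:
        cls = classify_gap(p)
        rows.append({
            "tumor_id": p.tumor_id,
            "n_regions": p.n_regions,
            "arms": ",".join(sorted(p.arms)),
            "bands": ",".join(sorted(p.bands)),
            "egfr_involved": p.egfr_involved,
            "gap_class": cls.value,
            "risk_group": risk_group(cls).value,
        })
    return pd.DataFrame(rows)
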