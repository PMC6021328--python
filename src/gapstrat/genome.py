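"""Genome coordinate model: cytobands, chromosome arms, gene catalog.

All coordinates are 0-based half-open internally. Chromosome names are
normalized to drop any ``chr`` prefix on input; bands carry labels like
``7p11.2`` and arms labels like ``7p``.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

logger = logging.getLogger(__name__)

#: canonical chromosome ordering used for sorting output
CHROM_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]
_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}


class GenomeModelError(ValueError):
    """Raised on malformed annotation input or invalid coordinates."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and return the bare chromosome name."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_CHROM_RANK.get(chrom, len(CHROM_ORDER)), chrom)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0:
            raise GenomeModelError(f"negative start in {self}")
        if not self.start < self.end:
            raise GenomeModelError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class Cytoband(NamedTuple):
    chrom: str
    start: int
    end: int
    name: str  # e.g. "p11.2"
    stain: str

    @property
    def label(self) -> str:
        """Full band label, e.g. ``7p11.2``."""
        return f"{self.chrom}{self.name}"

    @property
    def arm(self) -> str:
        return f"{self.chrom}{self.name[0]}"

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


class CytobandMap:
    """Ordered cytobands per chromosome with derived arm boundaries.

    Bands must tile each chromosome contiguously from 0 without overlap,
    p bands strictly before q bands.
    """

    def __init__(self, bands: Iterable[Cytoband]):
        per_chrom: dict[str, list[Cytoband]] = {}
        for b in bands:
            per_chrom.setdefault(b.chrom, []).append(b)
        self._bands: dict[str, list[Cytoband]] = {}
        self._starts: dict[str, list[int]] = {}
        self._arm_boundary: dict[str, int] = {}
        self._by_label: dict[str, Cytoband] = {}
        for chrom in sorted(per_chrom, key=chrom_sort_key):
            blist = sorted(per_chrom[chrom], key=lambda b: b.start)
            self._validate_chrom(chrom, blist)
            self._bands[chrom] = blist
            self._starts[chrom] = [b.start for b in blist]
            p_end = 0
            for b in blist:
                if b.name.startswith("p"):
                    p_end = b.end
                self._by_label[b.label] = b
            self._arm_boundary[chrom] = p_end

    @staticmethod
    def _validate_chrom(chrom: str, blist: list[Cytoband]) -> None:
        if not blist:
            raise GenomeModelError(f"chromosome {chrom} has no bands")
        prev_end = 0
        seen_q = False
        for b in blist:
            if b.start != prev_end:
                raise GenomeModelError(
                    f"bands do not tile chromosome {chrom}: gap/overlap at {b.start}"
                )
            if b.name[0] not in "pq":
                raise GenomeModelError(f"band {b.label}: arm must be p or q")
            if b.name.startswith("q"):
                seen_q = True
            elif seen_q:
                raise GenomeModelError(f"p band after q band on chromosome {chrom}")
            prev_end = b.end

    @property
    def chromosomes(self) -> list[str]:
        return list(self._bands)

    def bands(self, chrom: str | None = None) -> list[Cytoband]:
        if chrom is not None:
            return list(self._bands[normalize_chrom(chrom)])
        return [b for bl in self._bands.values() for b in bl]

    def chrom_length(self, chrom: str) -> int:
        return self._bands[normalize_chrom(chrom)][-1].end

    def arm_boundary(self, chrom: str) -> int:
        """End of the last p band (the p/q boundary used as the centromere)."""
        return self._arm_boundary[normalize_chrom(chrom)]

    def band_interval(self, label: str) -> GenomicInterval:
        try:
            return self._by_label[label].interval
        except KeyError:
            raise GenomeModelError(f"unknown band label {label!r}") from None

    def has_band(self, label: str) -> bool:
        return label in self._by_label

    def arm_interval(self, arm: str) -> GenomicInterval:
        chrom, letter = arm[:-1], arm[-1]
        if letter not in "pq":
            raise GenomeModelError(f"malformed arm label {arm!r}")
        boundary = self.arm_boundary(chrom)
        if letter == "p":
            if boundary == 0:
                raise GenomeModelError(f"chromosome {chrom} has no p arm")
            return GenomicInterval(chrom, 0, boundary)
        return GenomicInterval(chrom, boundary, self.chrom_length(chrom))

    def _check_chrom(self, chrom: str) -> str:
        c = normalize_chrom(chrom)
        if c not in self._bands:
            raise GenomeModelError(f"unknown chromosome {chrom!r}")
        return c

    def arm_of(self, iv: GenomicInterval) -> str | tuple[str, str]:
        """Arm containing the interval midpoint.

        An interval straddling the p/q boundary is assigned to both arms,
        returned as a ``(p, q)`` tuple; downstream region counting treats
        the two arms as separate regions.
        """
        chrom = self._check_chrom(iv.chrom)
        boundary = self._arm_boundary[chrom]
        if 0 < boundary and iv.start < boundary < iv.end:
            return (f"{chrom}p", f"{chrom}q")
        if boundary == 0:  # no p bands annotated
            return f"{chrom}q"
        return f"{chrom}p" if iv.midpoint < boundary else f"{chrom}q"

    def arms_of(self, iv: GenomicInterval) -> tuple[str, ...]:
        """Like :meth:`arm_of` but always a tuple."""
        arm = self.arm_of(iv)
        return arm if isinstance(arm, tuple) else (arm,)

    def bands_overlapping(self, iv: GenomicInterval) -> list[str]:
        """Labels of all bands overlapping the interval, in genomic order."""
        chrom = self._check_chrom(iv.chrom)
        blist = self._bands[chrom]
        starts = self._starts[chrom]
        i = bisect.bisect_right(starts, iv.start) - 1
        i = max(i, 0)
        out = []
        while i < len(blist) and blist[i].start < iv.end:
            if blist[i].end > iv.start:
                out.append(blist[i].label)
            i += 1
        return out

    def band_at(self, chrom: str, pos: int) -> str:
        chrom = self._check_chrom(chrom)
        blist = self._bands[chrom]
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        if i < 0 or pos >= blist[i].end:
            raise GenomeModelError(f"position {chrom}:{pos} outside annotated bands")
        return blist[i].label


def read_cytobands(path) -> CytobandMap:
    """Read a UCSC ``cytoBand.txt``-dialect file (tab-separated, chr-prefixed).

    Unknown chromosomes (not 1..22, X, Y) are skipped with a warning.
    Malformed lines raise :class:`GenomeModelError` naming the line number.
    """
    bands: list[Cytoband] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise GenomeModelError(
                    f"{path}: line {lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = normalize_chrom(fields[0])
            if chrom not in _CHROM_RANK:
                logger.warning("%s: line %d: skipping unknown chromosome %r",
                               path, lineno, fields[0])
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise GenomeModelError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            bands.append(Cytoband(chrom, start, end, fields[3], fields[4]))
    if not bands:
        raise GenomeModelError(f"{path}: no cytobands parsed")
    return CytobandMap(bands)


def write_cytobands(cmap: CytobandMap, path) -> None:
    """Write a CytobandMap back to the UCSC dialect (round-trips read_cytobands)."""
    with open(path, "w") as fh:
        for b in cmap.bands():
            fh.write(f"chr{b.chrom}\t{b.start}\t{b.end}\t{b.name}\t{b.stain}\n")


@dataclass(frozen=True)
class Gene:
    symbol: str
    interval: GenomicInterval
    strand: str
    band: str


class GeneCatalog:
    """Gene symbol -> locus lookup with band labels; overlap queries."""

    def __init__(self, genes: Iterable[Gene]):
        self._genes: dict[str, Gene] = {}
        per_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            if g.symbol in self._genes:
                raise GenomeModelError(f"duplicate gene symbol {g.symbol!r}")
            self._genes[g.symbol] = g
            per_chrom.setdefault(g.interval.chrom, []).append(g)
        self._per_chrom = {
            c: sorted(gl, key=lambda g: g.interval.start)
            for c, gl in per_chrom.items()
        }

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._genes

    def __getitem__(self, symbol: str) -> Gene:
        return self._genes[symbol]

    def __len__(self) -> int:
        return len(self._genes)

    def symbols(self) -> list[str]:
        return list(self._genes)

    def genes_overlapping(self, iv: GenomicInterval) -> list[str]:
        """Symbols of genes overlapping the interval, in genomic order."""
        out = []
        for g in self._per_chrom.get(iv.chrom, []):
            if g.interval.start >= iv.end:
                break
            if g.interval.overlaps(iv):
                out.append(g.symbol)
        return out


def read_gene_bed(path, cytobands: CytobandMap) -> GeneCatalog:
    """Read a BED6 gene catalog; band labels are derived from ``cytobands``.

    Strand is stored but ignored by overlap logic.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise GenomeModelError(
                    f"{path}: line {lineno}: expected BED6, got {len(fields)} fields"
                )
            chrom = normalize_chrom(fields[0])
            try:
                iv = GenomicInterval(chrom, int(fields[1]), int(fields[2]))
            except ValueError:
                raise GenomeModelError(
                    f"{path}: line {lineno}: bad coordinates"
                ) from None
            band = cytobands.band_at(chrom, iv.midpoint)
            genes.append(Gene(fields[3], iv, fields[5], band))
    return GeneCatalog(genes)
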