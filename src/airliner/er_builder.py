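"""Edited-region (ER) construction and training-set filters.

An ER is a maximal run of catalogued editing sites in which every
consecutive pair, within one (chromosome, strand) group, is separated by at
most δ nucleotides.  δ itself is estimated from the catalogue as the
weighted average distance between consecutive sites: all consecutive-site
gaps are pooled across groups and averaged, which weights each group's mean
gap by its gap count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io_genomics import AirlinerError, GenomicSite

__all__ = [
    "EditedRegion",
    "DeltaEstimate",
    "RepeatTrack",
    "UndefinedDeltaError",
    "compute_breakpoint_delta",
    "build_edited_regions",
    "classify_repetitive",
    "filter_training_ers",
    "filter_snp_sites",
    "write_regions_bed",
]


class UndefinedDeltaError(AirlinerError):
    """No (chrom, strand) group contains two or more sites."""


@dataclass(frozen=True)
class EditedRegion:
    """A maximal δ-linked run of editing sites on one (chrom, strand).

    ``start``/``end`` are the 0-based positions of the first and last member
    site; ``length = end - start + 1`` (no flank padding).
    """

    chrom: str
    strand: str
    sites: tuple[GenomicSite, ...]
    repetitive: bool = False

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("an edited region must contain at least one site")
        pos = [s.pos for s in self.sites]
        if pos != sorted(pos):
            raise ValueError("member sites must be sorted by position")

    @property
    def start(self) -> int:
        return self.sites[0].pos

    @property
    def end(self) -> int:
        return self.sites[-1].pos

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class DeltaEstimate:
    """Pooled mean consecutive-site gap (the ER breakpoint δ)."""

    delta: float
    n_gaps: int
    per_group: dict[tuple[str, str], tuple[int, int]]  # group -> (n_gaps, gap_sum)


def _grouped(
    sites: Iterable[GenomicSite], by_strand: bool = True
) -> dict[tuple[str, str], list[GenomicSite]]:
    groups: dict[tuple[str, str], list[GenomicSite]] = {}
    for s in sites:
        key = (s.chrom, s.strand if by_strand else "+")
        groups.setdefault(key, []).append(s)
    for members in groups.values():
        members.sort(key=lambda s: s.pos)
    return groups


def compute_breakpoint_delta(
    sites: Iterable[GenomicSite], by_strand: bool = True
) -> DeltaEstimate:
    """Estimate δ as the pooled mean of consecutive-site gaps.

    Gaps are position differences between consecutive sites within each
    (chrom, strand) group; groups with a single site contribute no gaps.
    Equivalent to averaging per-group mean gaps weighted by gap counts.
    """
    per_group: dict[tuple[str, str], tuple[int, int]] = {}
    total, n = 0, 0
    for key, members in _grouped(sites, by_strand).items():
        if len(members) < 2:
            continue
        gaps = [b.pos - a.pos for a, b in zip(members, members[1:])]
        per_group[key] = (len(gaps), sum(gaps))
        total += sum(gaps)
        n += len(gaps)
    if n == 0:
        raise UndefinedDeltaError(
            "delta is undefined: no (chrom, strand) group has >= 2 sites"
        )
    return DeltaEstimate(delta=total / n, n_gaps=n, per_group=per_group)


def build_edited_regions(
    sites: Iterable[GenomicSite], delta: float, by_strand: bool = True
) -> list[EditedRegion]:
    """Segment sites into ERs by the δ-breakpoint rule.

    Within each (chrom, strand) group, a greedy left-to-right pass extends
    the current ER while the next site lies within δ of the previous one and
    starts a new ER otherwise.  Every input site belongs to exactly one ER.
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    regions: list[EditedRegion] = []
    for (chrom, strand), members in sorted(_grouped(sites, by_strand).items()):
        current = [members[0]]
        for site in members[1:]:
            if site.pos - current[-1].pos <= delta:
                current.append(site)
            else:
                regions.append(EditedRegion(chrom, strand, tuple(current)))
                current = [site]
        regions.append(EditedRegion(chrom, strand, tuple(current)))
    return regions


class RepeatTrack:
    """Repeat annotations as half-open intervals per chromosome."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]]):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, ivs in intervals.items():
            tree = IntervalTree()
            for start, end in ivs:
                if end > start:
                    tree.addi(start, end)
            self._trees[chrom] = tree

    @classmethod
    def from_bed(cls, path: str | Path) -> "RepeatTrack":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                intervals.setdefault(fields[0], []).append(
                    (int(fields[1]), int(fields[2]))
                )
        return cls(intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any repeat interval on ``chrom``."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


def classify_repetitive(
    region: EditedRegion,
    repeats: RepeatTrack | Mapping[str, Iterable[tuple[int, int]]],
) -> bool:
    """True iff the ER span [start, end+1) overlaps a repeat by >= 1 base."""
    if not isinstance(repeats, RepeatTrack):
        repeats = RepeatTrack(repeats)
    return repeats.overlaps(region.chrom, region.start, region.end + 1)


def annotate_repetitive(
    regions: Iterable[EditedRegion],
    repeats: RepeatTrack | Mapping[str, Iterable[tuple[int, int]]],
) -> list[EditedRegion]:
    """Return regions with their ``repetitive`` flag set from the track."""
    if not isinstance(repeats, RepeatTrack):
        repeats = RepeatTrack(repeats)
    return [
        EditedRegion(r.chrom, r.strand, r.sites, repetitive=classify_repetitive(r, repeats))
        for r in regions
    ]


def filter_training_ers(
    regions: Iterable[EditedRegion],
    min_len: int = 2000,
    max_len: int = 6000,
    min_sites: int = 10,
) -> list[EditedRegion]:
    """Keep ERs with min_len <= length <= max_len and >= min_sites sites.

    Defaults reproduce the training-set filter used to select
    motif-discovery regions: 2,000-6,000 nt spans holding at least 10
    editing sites, applied to non-repetitive ERs.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    return [
        r
        for r in regions
        if min_len <= r.length <= max_len and r.n_sites >= min_sites
    ]


def filter_snp_sites(
    sites: Sequence[GenomicSite], snps: set[tuple[str, int]]
) -> tuple[list[GenomicSite], int]:
    """Drop sites whose (chrom, pos) is a known SNP.

    Returns the retained sites and the number removed.
    """
    kept = [s for s in sites if (s.chrom, s.pos) not in snps]
    return kept, len(sites) - len(kept)


def write_regions_bed(regions: Sequence[EditedRegion], path: str | Path) -> None:
    """Write ERs as BED6+ with id, site count, length and repetitive flag."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end + 1}\tER{i}\t{r.n_sites}\t{r.strand}"
                f"\t{r.length}\t{int(r.repetitive)}\n"
            )
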