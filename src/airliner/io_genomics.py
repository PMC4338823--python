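"""Genomic I/O: site catalogues, SNP lists, and strand-aware window extraction.

All coordinates are 0-based internally.  BED input is 0-based half-open;
VCF input is 1-based and converted on read.  Minus-strand sites are stored
on forward-strand coordinates; orientation (reverse complement) is applied
only when a sequence window is extracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import reverse_complement

__all__ = [
    "GenomicSite",
    "SequenceWindow",
    "AirlinerError",
    "BedParseError",
    "VcfFormatError",
    "WindowBoundaryError",
    "CenterBaseError",
    "AmbiguousBaseError",
    "read_sites",
    "write_sites",
    "read_snp_positions",
    "extract_window",
    "extract_windows",
    "open_genome",
    "read_fasta",
    "write_fasta",
]

VALID_STRANDS = ("+", "-")
_ACGT = frozenset("ACGT")


class AirlinerError(Exception):
    """Base class for toolkit errors."""


class BedParseError(AirlinerError):
    """A BED record could not be parsed; message names the offending line."""


class VcfFormatError(AirlinerError):
    """A VCF file could not be read."""


class WindowBoundaryError(AirlinerError):
    """Requested window crosses a contig boundary."""


class CenterBaseError(AirlinerError):
    """The central base of a window is not adenosine in window orientation."""


class AmbiguousBaseError(AirlinerError):
    """The window contains a non-ACGT character."""


@dataclass(frozen=True, order=True)
class GenomicSite:
    """One editing-site (or SNP) position.

    Parameters
    ----------
    chrom : str
        Contig name.
    pos : int
        0-based coordinate on the reference forward strand.
    strand : str
        ``'+'`` or ``'-'``.  Minus-strand sites are still addressed on
        forward-strand coordinates.
    """

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"site position must be >= 0, got {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class SequenceWindow:
    """A (2r+1)-nt window centered on an adenosine, in window orientation.

    ``seq[radius]`` is always ``'A'``: for minus-strand sites the extracted
    genomic slice has been reverse-complemented before construction.
    """

    seq: str
    radius: int
    label: str = "unknown"
    origin: GenomicSite | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.seq) != 2 * self.radius + 1:
            raise ValueError(
                f"window length {len(self.seq)} != 2*{self.radius}+1"
            )
        if not _ACGT.issuperset(self.seq):
            raise AmbiguousBaseError(
                f"window contains non-ACGT characters: {self.seq!r}"
            )
        if self.seq[self.radius] != "A":
            raise CenterBaseError(
                f"central base is {self.seq[self.radius]!r}, expected 'A'"
            )
        if self.label not in ("edited", "unedited", "unknown"):
            raise ValueError(f"invalid label {self.label!r}")

    def __len__(self) -> int:
        return len(self.seq)


def read_sites(path: str | Path) -> list[GenomicSite]:
    """Read a BED-like file of single-base site records.

    BED convention: 0-based, half-open; each record spans exactly one base
    (``end == start + 1``).  Column 6, when present, gives the strand
    (default ``'+'``).  Sites are returned sorted by ``(chrom, pos)``;
    exact duplicates are collapsed with a warning.
    """
    sites: list[GenomicSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"line {lineno}: expected >= 3 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            if end != start + 1:
                raise BedParseError(
                    f"line {lineno}: a site record must span one base "
                    f"(end == start + 1), got [{start}, {end})"
                )
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in VALID_STRANDS:
                raise BedParseError(f"line {lineno}: invalid strand {strand!r}")
            sites.append(GenomicSite(chrom, start, strand))
    unique = sorted(set(sites), key=lambda s: (s.chrom, s.pos, s.strand))
    n_dup = len(sites) - len(unique)
    if n_dup:
        warnings.warn(f"collapsed {n_dup} duplicate site record(s)", stacklevel=2)
    return unique


def write_sites(sites: Iterable[GenomicSite], path: str | Path) -> None:
    """Write sites as BED6 (name and score columns filled with '.')."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t.\t.\t{s.strand}\n")


def read_snp_positions(path: str | Path) -> set[tuple[str, int]]:
    """Read SNP positions from a VCF or BED file into a 0-based position set.

    VCF records are retained only when both REF and ALT are a single base
    (SNVs); VCF's 1-based POS is converted to the internal 0-based
    convention.  BED rows contribute their start coordinate.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf") or _looks_like_vcf(path):
        return _read_snps_vcf(path)
    positions: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"line {lineno}: expected >= 3 columns, got {len(fields)}"
                )
            try:
                positions.add((fields[0], int(fields[1])))
            except ValueError as exc:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinate {fields[1]!r}"
                ) from exc
    return positions


def _looks_like_vcf(path: Path) -> bool:
    try:
        with open(path) as fh:
            first = fh.readline()
    except OSError:
        return False
    return first.startswith("##fileformat=VCF")


def _read_snps_vcf(path: Path) -> set[tuple[str, int]]:
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot read VCF header of {path}: {exc}") from exc
    positions: set[tuple[str, int]] = set()
    with vcf:
        for rec in vcf:
            if rec.ref is None or len(rec.ref) != 1:
                continue
            alts = rec.alts or ()
            if not any(a is not None and len(a) == 1 and a != "*" for a in alts):
                continue
            positions.add((rec.chrom, rec.pos - 1))  # VCF POS is 1-based
    return positions


def open_genome(path: str | Path):
    """Open an indexed FASTA genome (the index is built on first use)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA file fully into a name -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _contig_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] from a pyfaidx Fasta or a plain mapping."""
    contig = genome[chrom]
    return str(contig[start:end])


def _contig_len(genome, chrom: str) -> int:
    return len(genome[chrom])


def extract_window(
    genome,
    site: GenomicSite,
    radius: int,
    label: str = "unknown",
) -> SequenceWindow:
    """Extract the (2r+1)-nt window centered on ``site`` in window orientation.

    For a ``'+'`` site the window is the uppercased forward slice
    ``genome[pos-r : pos+r+1]`` and the reference base at ``pos`` must be A.
    For a ``'-'`` site the reference base must be T and the window is the
    reverse complement of that same slice, so its central base is again A.

    ``genome`` may be a :class:`pyfaidx.Fasta` or any mapping of contig
    name to sequence string.

    Raises
    ------
    WindowBoundaryError
        If the window would cross a contig boundary.
    CenterBaseError
        If the central base is not A in window orientation.
    AmbiguousBaseError
        If the window contains a non-ACGT character.
    """
    if site.chrom not in _contig_names(genome):
        raise KeyError(f"contig {site.chrom!r} not in genome")
    clen = _contig_len(genome, site.chrom)
    lo, hi = site.pos - radius, site.pos + radius + 1
    if lo < 0 or hi > clen:
        raise WindowBoundaryError(
            f"window [{lo}, {hi}) crosses boundary of {site.chrom} (length {clen})"
        )
    seq = _contig_seq(genome, site.chrom, lo, hi).upper()
    if not _ACGT.issuperset(seq):
        raise AmbiguousBaseError(
            f"window at {site.chrom}:{site.pos} contains ambiguous bases"
        )
    if site.strand == "-":
        seq = reverse_complement(seq)
    if seq[radius] != "A":
        raise CenterBaseError(
            f"central base at {site.chrom}:{site.pos} ({site.strand}) is "
            f"{seq[radius]!r} in window orientation, expected 'A'"
        )
    return SequenceWindow(seq, radius, label=label, origin=site)


def extract_windows(
    genome,
    sites: Sequence[GenomicSite],
    radius: int,
    label: str = "unknown",
    skip_invalid: bool = True,
) -> list[SequenceWindow]:
    """Extract windows for many sites, optionally skipping invalid ones.

    With ``skip_invalid`` (the default), sites whose window crosses a
    boundary, is not A-centered, or contains ambiguity codes are dropped;
    otherwise the first such error propagates.
    """
    out: list[SequenceWindow] = []
    for site in sites:
        try:
            out.append(extract_window(genome, site, radius, label=label))
        except (WindowBoundaryError, CenterBaseError, AmbiguousBaseError):
            if not skip_invalid:
                raise
    return out


def _contig_names(genome) -> Iterable[str]:
    keys = getattr(genome, "keys", None)
    return keys() if callable(keys) else genome
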