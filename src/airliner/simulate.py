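"""Synthetic fixtures: biased window sets and genomes with planted sites.

Two generators cover the toolkit's inputs without any external download:

* :func:`generate_window_sets` samples A-centered windows
  position-independently from per-class positional nucleotide profiles —
  the same independence structure the scoring model assumes, which keeps
  the ground truth analytic.
* :func:`generate_genome_with_sites` builds a random genome and plants
  gap-clustered editing sites on both strands (truncated-geometric
  within-cluster gaps, wide between-cluster separations), together with
  repeat intervals and an optional SNP duplicate track, and remembers the
  planted clusters so segmentation can be checked against the truth.

Every entry point takes a mandatory seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_genomics import AirlinerError, GenomicSite, SequenceWindow

__all__ = [
    "BiasSpec",
    "GenomeSimulation",
    "GenerationError",
    "uniform_profile",
    "generate_window_sets",
    "generate_genome_with_sites",
]

_NUCS = "ACGT"


class GenerationError(AirlinerError):
    """Synthetic placement could not satisfy the requested parameters."""


def uniform_profile(radius: int) -> np.ndarray:
    """Uniform flank distribution with the central position fixed to A."""
    width = 2 * radius + 1
    probs = np.full((4, width), 0.25)
    probs[:, radius] = [1.0, 0.0, 0.0, 0.0]
    return probs


def _point_profile(radius: int, nucleotide: str) -> np.ndarray:
    width = 2 * radius + 1
    probs = np.zeros((4, width))
    probs[_NUCS.index(nucleotide), :] = 1.0
    probs[:, radius] = [1.0, 0.0, 0.0, 0.0]
    return probs


@dataclass(frozen=True)
class BiasSpec:
    """Sampling specification for two classes of A-centered windows.

    ``edited_profile`` and ``unedited_profile`` are (4, 2r+1) column-
    stochastic matrices (row order A, C, G, T); the central column must
    assign probability 1 to A in both classes.
    """

    radius: int
    edited_profile: np.ndarray
    unedited_profile: np.ndarray
    n_pos: int = 1000
    n_neg: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        width = 2 * self.radius + 1
        for name, probs in (
            ("edited_profile", self.edited_profile),
            ("unedited_profile", self.unedited_profile),
        ):
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (4, width):
                raise AirlinerError(f"{name} must have shape (4, {width})")
            if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
                raise AirlinerError(f"{name} columns must sum to 1 within 1e-9")
            if np.any(probs < 0):
                raise AirlinerError(f"{name} has negative probabilities")
            if abs(probs[0, self.radius] - 1.0) > 1e-9:
                raise AirlinerError(
                    f"{name} central position must assign probability 1 to A"
                )
        if self.n_pos < 1 or self.n_neg < 1:
            raise AirlinerError("n_pos and n_neg must be >= 1")

    @classmethod
    def null(
        cls, radius: int = 10, n_pos: int = 1000, n_neg: int = 1000, seed: int = 0
    ) -> "BiasSpec":
        """Identical (uniform) profiles in both classes: no signal."""
        return cls(radius, uniform_profile(radius), uniform_profile(radius), n_pos, n_neg, seed)

    @classmethod
    def separated(
        cls, radius: int = 10, n_pos: int = 1000, n_neg: int = 1000, seed: int = 0
    ) -> "BiasSpec":
        """Disjoint-support flanks (all-T vs all-C): perfectly separable."""
        return cls(
            radius, _point_profile(radius, "T"), _point_profile(radius, "C"), n_pos, n_neg, seed
        )

    @classmethod
    def adar_like(
        cls, radius: int = 10, n_pos: int = 1000, n_neg: int = 1000, seed: int = 0
    ) -> "BiasSpec":
        """Mild deaminase-style neighbor bias against a uniform background.

        The edited class depletes G immediately 5' of the adenosine
        (U ≈ A > G > C ordering) and enriches G immediately 3', echoing the
        documented ADAR neighbor preferences; remaining flank positions
        carry a gentle U/A lean.
        """
        edited = uniform_profile(radius)
        for i in range(2 * radius + 1):
            if i == radius:
                continue
            edited[:, i] = [0.28, 0.20, 0.22, 0.30]  # slight A/T lean
        edited[:, radius - 1] = [0.33, 0.12, 0.20, 0.35]  # 5': U ~ A > G > C
        edited[:, radius + 1] = [0.18, 0.17, 0.35, 0.30]  # 3': G/U preference
        return cls(radius, edited, uniform_profile(radius), n_pos, n_neg, seed)


def _sample_class(
    rng: np.random.Generator, probs: np.ndarray, n: int, radius: int, label: str
) -> list[SequenceWindow]:
    width = 2 * radius + 1
    letters = np.empty((n, width), dtype="U1")
    for i in range(width):
        letters[:, i] = rng.choice(list(_NUCS), size=n, p=probs[:, i])
    return [SequenceWindow("".join(row), radius, label=label) for row in letters]


def generate_window_sets(
    spec: BiasSpec,
) -> tuple[list[SequenceWindow], list[SequenceWindow]]:
    """Sample (positive, negative) window sets from a :class:`BiasSpec`.

    Each window position is drawn independently from its class profile;
    output is deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pos = _sample_class(rng, np.asarray(spec.edited_profile, float), spec.n_pos, spec.radius, "edited")
    neg = _sample_class(rng, np.asarray(spec.unedited_profile, float), spec.n_neg, spec.radius, "unedited")
    return pos, neg


@dataclass
class GenomeSimulation:
    """A planted-truth genome fixture.

    ``clusters`` records the generator's ledger: the member sites of each
    planted cluster, in placement order — segmentation output can be
    compared against it directly.
    """

    genome: dict[str, str]
    sites: list[GenomicSite]
    repeats: dict[str, list[tuple[int, int]]]
    snps: set[tuple[str, int]]
    clusters: list[list[GenomicSite]] = field(default_factory=list)
    cluster_gap_mean: float = 0.0
    cluster_separation: int = 0


def generate_genome_with_sites(
    n_contigs: int = 2,
    contig_length: int = 100_000,
    n_sites: int = 200,
    cluster_gap_mean: float = 50.0,
    repeat_fraction: float = 0.2,
    seed: int = 0,
    sites_per_cluster: int = 10,
    cluster_separation: int | None = None,
    snp_fraction: float = 0.0,
    margin: int = 50,
) -> GenomeSimulation:
    """Generate a genome with gap-clustered editing sites and annotations.

    Sites are planted in clusters of ~``sites_per_cluster`` members whose
    internal gaps are geometric with mean ``cluster_gap_mean`` (truncated
    at 3x the mean so planted truth stays exactly recoverable); clusters
    are separated by ``cluster_separation`` nt (default 50x the gap mean)
    and assigned alternately to the two strands.  The reference base under
    each site is forced to A on '+' and T on '-'.  Repeat intervals cover
    about ``repeat_fraction`` of each contig, and ``snp_fraction`` of the
    sites are duplicated into the SNP track.
    """
    if n_sites < 1 or n_contigs < 1 or contig_length < 2 * margin:
        raise GenerationError("parameters must be positive and contigs usable")
    if not 0.0 <= repeat_fraction < 1.0 or not 0.0 <= snp_fraction <= 1.0:
        raise GenerationError("fractions must lie in [0, 1)")
    if cluster_gap_mean < 1:
        raise GenerationError("cluster_gap_mean must be >= 1")
    sep = int(cluster_separation if cluster_separation is not None else 50 * cluster_gap_mean)
    if sep <= 3 * cluster_gap_mean:
        raise GenerationError("cluster_separation must exceed 3x cluster_gap_mean")
    rng = np.random.default_rng(seed)

    contig_names = [f"chr{i + 1}" for i in range(n_contigs)]
    genomes = {
        name: rng.choice(list(_NUCS), size=contig_length) for name in contig_names
    }

    n_clusters = math.ceil(n_sites / sites_per_cluster)
    base, extra = divmod(n_sites, n_clusters)
    sizes = [base + (1 if i < extra else 0) for i in range(n_clusters)]
    gap_cap = int(3 * cluster_gap_mean)

    cursors = {name: margin for name in contig_names}
    clusters: list[list[GenomicSite]] = []
    sites: list[GenomicSite] = []
    for ci, size in enumerate(sizes):
        chrom = contig_names[ci % n_contigs]
        strand = "+" if (ci // n_contigs) % 2 == 0 else "-"
        start = cursors[chrom] + sep
        positions = [start]
        for _ in range(size - 1):
            gap = int(min(rng.geometric(1.0 / cluster_gap_mean), gap_cap))
            positions.append(positions[-1] + max(gap, 1))
        if positions[-1] >= contig_length - margin:
            raise GenerationError(
                f"cluster {ci} does not fit on {chrom}; increase contig_length"
            )
        cursors[chrom] = positions[-1]
        members = [GenomicSite(chrom, p, strand) for p in positions]
        clusters.append(members)
        sites.extend(members)
        ref = "A" if strand == "+" else "T"
        for p in positions:
            genomes[chrom][p] = ref

    genome = {name: "".join(arr) for name, arr in genomes.items()}

    repeats: dict[str, list[tuple[int, int]]] = {name: [] for name in contig_names}
    if repeat_fraction > 0:
        for name in contig_names:
            covered = 0
            target = repeat_fraction * contig_length
            attempts = 0
            while covered < target and attempts < 10_000:
                attempts += 1
                length = int(rng.integers(200, 400))
                start = int(rng.integers(0, contig_length - length))
                repeats[name].append((start, start + length))
                covered += length

    snps: set[tuple[str, int]] = set()
    if snp_fraction > 0:
        n_snps = int(round(snp_fraction * len(sites)))
        chosen = rng.choice(len(sites), size=n_snps, replace=False) if n_snps else []
        snps = {(sites[i].chrom, sites[i].pos) for i in chosen}

    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    return GenomeSimulation(
        genome=genome,
        sites=sites,
        repeats=repeats,
        snps=snps,
        clusters=clusters,
        cluster_gap_mean=cluster_gap_mean,
        cluster_separation=sep,
    )
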