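"""Candidate-motif filtering and permutation significance testing.

Motif consensus strings use IUPAC nucleotide codes; matching is exact
symbol-set containment (no mismatches), on both strands by default.
Soft-masked (lowercase) and N bases in scanned sequences never match, so
repeat-masked background pools behave as intended.

The permutation statistic is the fraction of sequences containing at least
one match; the null distribution re-computes it on seeded random samples
drawn without replacement from a background pool (e.g. 3'-UTR sequences),
and the p-value uses the add-one estimator p = (1 + #{null >= observed}) /
(n_samples + 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from .io_genomics import AirlinerError

__all__ = [
    "MotifRecord",
    "PermutationResult",
    "load_motifs",
    "bundled_motifs",
    "filter_by_evalue",
    "filter_ultraconserved",
    "scan_motif",
    "permutation_test",
]

# uppercase-only character classes: soft-masked bases must not match
_IUPAC_CLASS = {code: "[" + bases + "]" for code, bases in ambiguous_dna_values.items()}
_VALID_IUPAC = frozenset(ambiguous_dna_values) - {"X"}


@dataclass(frozen=True)
class MotifRecord:
    """One candidate motif: best-match consensus, type and discovery E-value."""

    id: str
    consensus: str
    type: Literal["palindromic", "non-palindromic"]
    evalue: float

    def __post_init__(self) -> None:
        bad = [c for c in self.consensus if c not in _VALID_IUPAC]
        if bad:
            raise AirlinerError(
                f"motif {self.id!r}: invalid IUPAC symbol(s) {sorted(set(bad))}"
            )
        if self.type not in ("palindromic", "non-palindromic"):
            raise AirlinerError(f"motif {self.id!r}: invalid type {self.type!r}")

    @property
    def width(self) -> int:
        return len(self.consensus)


def _compile(consensus: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all counted
    return re.compile("(?=" + "".join(_IUPAC_CLASS[c] for c in consensus) + ")")


def load_motifs(path: str | Path) -> list[MotifRecord]:
    """Load motifs from a TSV (id, consensus, type, evalue) or MEME text."""
    path = Path(path)
    text = path.read_text()
    if "MEME" in text.splitlines()[0] or "\nMOTIF" in text or text.startswith("MOTIF"):
        return _parse_meme_text(text)
    records: list[MotifRecord] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("id\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise AirlinerError(f"motif TSV row needs 4 columns, got {len(fields)}")
        motif_id, consensus, mtype, evalue = fields[:4]
        records.append(
            MotifRecord(
                id=motif_id,
                consensus=consensus.upper(),
                type=mtype.strip().lower(),
                evalue=float(evalue.replace(",", ".")),
            )
        )
    return records


def _parse_meme_text(text: str) -> list[MotifRecord]:
    """Parse MOTIF blocks of MEME-style text (consensus + E-value only)."""
    records: list[MotifRecord] = []
    current_id: str | None = None
    consensus: str | None = None
    evalue = float("nan")
    for line in text.splitlines():
        if line.startswith("MOTIF"):
            if current_id is not None and consensus is not None:
                records.append(
                    MotifRecord(current_id, consensus, "non-palindromic", evalue)
                )
            parts = line.split()
            current_id = parts[1] if len(parts) > 1 else f"motif{len(records) + 1}"
            consensus = (
                parts[1].upper()
                if len(parts) > 1 and set(parts[1].upper()) <= _VALID_IUPAC
                else None
            )
            m = re.search(r"E-value\s*[:=]\s*(\S+)", line)
            evalue = float(m.group(1)) if m else float("nan")
        elif line.startswith("Multilevel") and current_id is not None:
            consensus = line.split()[1].upper()
        elif "E-value" in line and current_id is not None:
            m = re.search(r"E-value\s*[:=]\s*(\S+)", line)
            if m:
                evalue = float(m.group(1))
    if current_id is not None and consensus is not None:
        records.append(MotifRecord(current_id, consensus, "non-palindromic", evalue))
    return records


def bundled_motifs() -> list[MotifRecord]:
    """The packaged catalogue of significant ER motifs (13 records)."""
    with resources.as_file(
        resources.files("airliner").joinpath("data/er_motifs.tsv")
    ) as path:
        return load_motifs(path)


def filter_by_evalue(
    motifs: Iterable[MotifRecord], cutoff: float = 0.05
) -> list[MotifRecord]:
    """Keep motifs whose discovery E-value is strictly below ``cutoff``."""
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    return [m for m in motifs if m.evalue < cutoff]


def filter_ultraconserved(
    motifs: Iterable[MotifRecord], ultraconserved: Sequence[str]
) -> list[MotifRecord]:
    """Drop motifs matching anywhere (either strand) in an ultraconserved set."""
    kept = []
    for m in motifs:
        if not any(scan_motif(seq, m) > 0 for seq in ultraconserved):
            kept.append(m)
    return kept


def scan_motif(sequence: str, motif: MotifRecord, both_strands: bool = True) -> int:
    """Count all (overlapping) IUPAC-compatible occurrences of the motif.

    Lowercase (soft-masked) and N bases never match.  With
    ``both_strands``, occurrences of the reverse-complement consensus are
    added.  A motif wider than the sequence simply yields 0.
    """
    if motif.width > len(sequence):
        return 0
    n = len(_compile(motif.consensus).findall(sequence))
    if both_strands:
        rc = reverse_complement(motif.consensus)
        if rc != motif.consensus:
            n += len(_compile(rc).findall(sequence))
    return n


@dataclass(frozen=True)
class PermutationResult:
    """Permutation-test outcome for one motif."""

    motif_id: str
    observed: float
    null: np.ndarray
    p_value: float
    n_samples: int
    sample_size: int
    statistic: str

    @property
    def significant(self) -> bool:
        return self.p_value < 0.01

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())


def permutation_test(
    motif: MotifRecord,
    observed_sequences: Sequence[str],
    background_pool: Sequence[str],
    n_samples: int = 100,
    sample_size: int = 1000,
    seed: int = 0,
    statistic: Literal["presence", "count"] = "presence",
    both_strands: bool = True,
) -> PermutationResult:
    """Assess motif enrichment against random background samples.

    The observed statistic (default: fraction of sequences with >= 1 match)
    is compared with its value on ``n_samples`` seeded draws of
    ``sample_size`` sequences each, taken without replacement from
    ``background_pool``.  Per-sequence match results are computed once per
    pool, so repeated draws are cheap.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if len(background_pool) < sample_size:
        raise AirlinerError(
            f"background pool ({len(background_pool)}) smaller than "
            f"sample_size ({sample_size})"
        )
    if len(observed_sequences) == 0:
        raise AirlinerError("no observed sequences")

    def per_seq(seqs: Sequence[str]) -> np.ndarray:
        counts = np.array([scan_motif(s, motif, both_strands) for s in seqs], float)
        return (counts > 0).astype(float) if statistic == "presence" else counts

    observed = float(per_seq(observed_sequences).mean())
    pool_stats = per_seq(background_pool)
    rng = np.random.default_rng(seed)
    null = np.empty(n_samples)
    for b in range(n_samples):
        draw = rng.choice(len(background_pool), size=sample_size, replace=False)
        null[b] = pool_stats[draw].mean()
    p = (1.0 + float(np.sum(null >= observed))) / (n_samples + 1.0)
    return PermutationResult(
        motif_id=motif.id,
        observed=observed,
        null=null,
        p_value=p,
        n_samples=n_samples,
        sample_size=sample_size,
        statistic=statistic,
    )
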