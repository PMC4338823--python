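"""Positional nucleotide probability matrices and window featurization.

P(j, i) is the probability of finding nucleotide j at window position i in
the edited training set; P'(j, i) is the same quantity for the un-edited
set.  A window s of radius r maps to the 2(2r+1)-long feature vector
[P(s[i], i)]_i followed by [P'(s[i], i)]_i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_genomics import AirlinerError, SequenceWindow

__all__ = [
    "NUCLEOTIDES",
    "PositionProbabilityMatrix",
    "build_profile",
    "featurize",
    "featurize_many",
]

NUCLEOTIDES = "ACGT"
_NUC_INDEX = {nuc: k for k, nuc in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class PositionProbabilityMatrix:
    """Column-stochastic per-position nucleotide probabilities.

    ``probs`` has shape (4, 2r+1); row order is A, C, G, T.  Built with a
    Laplace pseudocount alpha: probs[j, i] = (count(j, i) + alpha) /
    (n + 4 alpha).
    """

    radius: int
    probs: np.ndarray
    n_sequences: int
    pseudocount: float

    def __post_init__(self) -> None:
        width = 2 * self.radius + 1
        if self.probs.shape != (4, width):
            raise ValueError(f"probs shape {self.probs.shape} != (4, {width})")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("columns must sum to 1 within 1e-9")

    @property
    def width(self) -> int:
        return 2 * self.radius + 1

    def prob(self, nucleotide: str, position: int) -> float:
        """P(nucleotide, position) with 0-based window position."""
        return float(self.probs[_NUC_INDEX[nucleotide], position])

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as a TSV (one row per position) with a JSON header line."""
        header = json.dumps(
            {
                "radius": self.radius,
                "pseudocount": self.pseudocount,
                "n_sequences": self.n_sequences,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"#{header}\n")
            fh.write("position\t" + "\t".join(NUCLEOTIDES) + "\n")
            for i in range(self.width):
                row = "\t".join(f"{self.probs[j, i]:.10g}" for j in range(4))
                fh.write(f"{i + 1}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionProbabilityMatrix":
        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("#"))
            fh.readline()  # column header
            rows = [list(map(float, line.split()[1:5])) for line in fh if line.strip()]
        return cls(
            radius=meta["radius"],
            probs=np.asarray(rows).T,
            n_sequences=meta["n_sequences"],
            pseudocount=meta["pseudocount"],
        )


def build_profile(
    windows: Sequence[SequenceWindow], pseudocount: float = 1.0
) -> PositionProbabilityMatrix:
    """Estimate a positional probability matrix from same-radius windows."""
    if len(windows) == 0:
        raise AirlinerError("cannot build a profile from an empty training set")
    radius = windows[0].radius
    if any(w.radius != radius for w in windows):
        raise AirlinerError("all training windows must share the same radius")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    width = 2 * radius + 1
    counts = np.zeros((4, width), dtype=float)
    for w in windows:
        for i, nuc in enumerate(w.seq):
            counts[_NUC_INDEX[nuc], i] += 1.0
    n = len(windows)
    probs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    return PositionProbabilityMatrix(
        radius=radius, probs=probs, n_sequences=n, pseudocount=pseudocount
    )


def featurize(
    window: SequenceWindow,
    ppm_edited: PositionProbabilityMatrix,
    ppm_unedited: PositionProbabilityMatrix,
) -> np.ndarray:
    """Map a window to [P(s[i], i)]_i ++ [P'(s[i], i)]_i (length 2(2r+1))."""
    if window.radius != ppm_edited.radius or window.radius != ppm_unedited.radius:
        raise AirlinerError(
            f"window radius {window.radius} does not match matrix radii "
            f"({ppm_edited.radius}, {ppm_unedited.radius})"
        )
    idx = np.fromiter((_NUC_INDEX[c] for c in window.seq), dtype=np.intp)
    cols = np.arange(len(window.seq))
    return np.concatenate([ppm_edited.probs[idx, cols], ppm_unedited.probs[idx, cols]])


def featurize_many(
    windows: Sequence[SequenceWindow],
    ppm_edited: PositionProbabilityMatrix,
    ppm_unedited: PositionProbabilityMatrix,
) -> np.ndarray:
    """Feature matrix of shape (n_windows, 2(2r+1))."""
    return np.vstack([featurize(w, ppm_edited, ppm_unedited) for w in windows])
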