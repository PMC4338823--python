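"""The AIRlINER logistic scoring model and the multiplicative baseline.

The editing log-odds of a (2r+1)-nt window s centered on an adenosine is
modeled as

    logit P(edited | s) = beta0 + sum_i beta_i P(s[i], i)
                                - sum_i beta'_i P'(s[i], i),

where P and P' are the positional nucleotide probabilities estimated from
the edited and un-edited training windows.  The minus sign is a
parameterization: the P' feature block is negated before an unconstrained
ridge-penalized maximum-likelihood fit, leaving beta'_i free in sign.

Fitting is a damped Newton iteration on the penalized binomial
log-likelihood, started at zero — deterministic, no random state.  The L2
penalty (default 1e-3) applies to the coefficients only, not the
intercept; it absorbs the collinearity of the near-constant central-A
feature instead of dropping that column.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .io_genomics import AirlinerError, SequenceWindow
from .profiles import (
    NUCLEOTIDES,
    PositionProbabilityMatrix,
    build_profile,
    featurize,
    featurize_many,
)

__all__ = [
    "AirlinerModel",
    "AirlinerResults",
    "MultiplicativeScorer",
    "fit",
    "fit_penalized_logistic",
    "penalized_logistic_objective",
    "predict_probability",
    "classify",
]


def penalized_logistic_objective(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float
) -> float:
    """Negative binomial log-likelihood + (ridge/2)·‖coefficients‖².

    ``params[0]`` is the unpenalized intercept; ``params[1:]`` are the
    coefficients on the columns of ``X``.
    """
    eta = params[0] + X @ params[1:]
    # log(1 + exp(eta)) - y*eta, computed stably
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    return nll + 0.5 * ridge * float(params[1:] @ params[1:])


def fit_penalized_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-3,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> tuple[np.ndarray, dict]:
    """Minimize the ridge-penalized logistic loss by damped Newton from zero.

    Returns ``(params, info)`` where ``params[0]`` is the intercept and
    ``info`` records iterations, the final gradient norm, convergence and
    the covariance estimate (inverse penalized Hessian at the solution).
    Deterministic: identical inputs give bit-identical output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y shape {y.shape} != ({n},)")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    Z = np.hstack([np.ones((n, 1)), X])
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0  # intercept is not penalized
    params = np.zeros(p + 1)
    obj = penalized_logistic_objective(params, X, y, ridge)
    grad_norm = np.inf
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        prob = expit(Z @ params)
        grad = Z.T @ (prob - y) + pen * params
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm <= tol:
            converged = True
            break
        w = np.maximum(prob * (1.0 - prob), 1e-12)
        hess = (Z * w[:, None]).T @ Z + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # backtracking line search keeps the iteration (numerically) monotone;
        # the small slack lets quadratic convergence finish when objective
        # differences fall below float resolution
        t = 1.0
        for _ in range(60):
            trial = params - t * step
            trial_obj = penalized_logistic_objective(trial, X, y, ridge)
            if trial_obj <= obj + 1e-10 * max(1.0, abs(obj)):
                break
            t *= 0.5
        params, obj = trial, trial_obj
    else:
        prob = expit(Z @ params)
        grad = Z.T @ (prob - y) + pen * params
        grad_norm = float(np.linalg.norm(grad))
        converged = grad_norm <= tol
    if not converged:
        warnings.warn(
            f"logistic fit stopped at iteration cap ({maxiter}) with gradient "
            f"norm {grad_norm:.3g}; data may be separable at ridge={ridge}",
            stacklevel=2,
        )
    prob = expit(Z @ params)
    w = np.maximum(prob * (1.0 - prob), 1e-12)
    hess = (Z * w[:, None]).T @ Z + np.diag(pen)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    info = {
        "iterations": it,
        "grad_norm": grad_norm,
        "converged": converged,
        "objective": penalized_logistic_objective(params, X, y, ridge),
        "cov": cov,
        "deterministic": True,
    }
    return params, info


class AirlinerModel:
    """Editing-probability model specification bound to its training windows.

    Parameters
    ----------
    windows_pos, windows_neg : sequences of SequenceWindow
        Edited (label 1) and un-edited (label 0) training windows; all must
        share one radius.
    ridge : float
        L2 penalty on the coefficients (not the intercept).
    pseudocount : float
        Laplace smoothing used when estimating P and P'.
    """

    def __init__(
        self,
        windows_pos: Sequence[SequenceWindow],
        windows_neg: Sequence[SequenceWindow],
        ridge: float = 1e-3,
        pseudocount: float = 1.0,
    ):
        if len(windows_pos) == 0 or len(windows_neg) == 0:
            raise AirlinerError("both training sets must be non-empty")
        radii = {w.radius for w in windows_pos} | {w.radius for w in windows_neg}
        if len(radii) != 1:
            raise AirlinerError(f"mixed window radii in training data: {sorted(radii)}")
        if ridge < 0:
            raise ValueError("ridge must be >= 0")
        self.windows_pos = list(windows_pos)
        self.windows_neg = list(windows_neg)
        self.radius = radii.pop()
        self.ridge = ridge
        self.pseudocount = pseudocount

    def fit(self, tol: float = 1e-8, maxiter: int = 500) -> "AirlinerResults":
        """Estimate P, P' and the logistic coefficients; return results."""
        ppm_edited = build_profile(self.windows_pos, self.pseudocount)
        ppm_unedited = build_profile(self.windows_neg, self.pseudocount)
        windows = self.windows_pos + self.windows_neg
        y = np.concatenate(
            [np.ones(len(self.windows_pos)), np.zeros(len(self.windows_neg))]
        )
        F = featurize_many(windows, ppm_edited, ppm_unedited)
        X = _signed_design(F, self.radius)
        params, info = fit_penalized_logistic(
            X, y, ridge=self.ridge, tol=tol, maxiter=maxiter
        )
        width = 2 * self.radius + 1
        return AirlinerResults(
            beta0=float(params[0]),
            beta=params[1 : width + 1].copy(),
            beta_prime=params[width + 1 :].copy(),
            radius=self.radius,
            ridge=self.ridge,
            ppm_edited=ppm_edited,
            ppm_unedited=ppm_unedited,
            fit_info={k: v for k, v in info.items() if k != "cov"},
            cov=info["cov"],
        )


def _signed_design(features: np.ndarray, radius: int) -> np.ndarray:
    """Negate the P' block so the unconstrained fit realizes the minus sign."""
    width = 2 * radius + 1
    X = features.copy()
    X[..., width:] *= -1.0
    return X


@dataclass
class AirlinerResults:
    """Fitted editing-probability model.

    ``beta`` weights the edited-profile features P(s[i], i); ``beta_prime``
    weights the un-edited-profile features, entering the linear predictor
    with a minus sign.
    """

    beta0: float
    beta: np.ndarray
    beta_prime: np.ndarray
    radius: int
    ridge: float
    ppm_edited: PositionProbabilityMatrix
    ppm_unedited: PositionProbabilityMatrix
    fit_info: dict = field(default_factory=dict)
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        width = 2 * self.radius + 1
        self.beta = np.asarray(self.beta, dtype=float)
        self.beta_prime = np.asarray(self.beta_prime, dtype=float)
        if self.beta.shape != (width,) or self.beta_prime.shape != (width,):
            raise ValueError("coefficient vectors must have length 2*radius+1")

    @property
    def params(self) -> np.ndarray:
        """(beta0, beta_1..beta_w, beta'_1..beta'_w)."""
        return np.concatenate([[self.beta0], self.beta, self.beta_prime])

    @property
    def bse(self) -> np.ndarray | None:
        """Approximate standard errors from the inverse penalized Hessian."""
        if self.cov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def linear_predictor(self, window: SequenceWindow) -> float:
        f = featurize(window, self.ppm_edited, self.ppm_unedited)
        width = 2 * self.radius + 1
        return float(
            self.beta0 + self.beta @ f[:width] - self.beta_prime @ f[width:]
        )

    def predict_probability(self, window: SequenceWindow) -> float:
        """sigma(linear predictor) in (0, 1); pure function of the window."""
        return float(expit(self.linear_predictor(window)))

    def predict_probabilities(self, windows: Iterable[SequenceWindow]) -> np.ndarray:
        return np.array([self.predict_probability(w) for w in windows])

    def classify(self, window: SequenceWindow, threshold: float = 0.5) -> str:
        """'edited' iff predicted probability is strictly above threshold."""
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        return "edited" if self.predict_probability(window) > threshold else "unedited"

    def summary(self) -> str:
        """Plain-text coefficient table in the field's customary layout."""
        width = 2 * self.radius + 1
        bse = self.bse
        lines = [
            "AIRlINER logistic editing model",
            "=" * 64,
            f"window width:   {width} nt (radius {self.radius})",
            f"ridge penalty:  {self.ridge:g}",
            f"training n:     {self.ppm_edited.n_sequences} edited / "
            f"{self.ppm_unedited.n_sequences} un-edited",
            f"converged:      {self.fit_info.get('converged')} "
            f"({self.fit_info.get('iterations')} iterations, "
            f"|grad| = {self.fit_info.get('grad_norm', float('nan')):.2e})",
            "-" * 64,
            f"{'term':>10s} {'coef':>12s} {'std err':>12s}",
            f"{'beta0':>10s} {self.beta0:>12.5f} "
            + (f"{bse[0]:>12.5f}" if bse is not None else f"{'--':>12s}"),
        ]
        for i in range(width):
            se = f"{bse[1 + i]:>12.5f}" if bse is not None else f"{'--':>12s}"
            label = f"beta[{i + 1}]"
            lines.append(f"{label:>10s} {self.beta[i]:>12.5f} {se}")
        for i in range(width):
            se = (
                f"{bse[1 + width + i]:>12.5f}" if bse is not None else f"{'--':>12s}"
            )
            label = "beta'[" + str(i + 1) + "]"
            lines.append(f"{label:>10s} {self.beta_prime[i]:>12.5f} {se}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format": "airliner-model",
            "version": 1,
            "radius": self.radius,
            "ridge": self.ridge,
            "beta0": self.beta0,
            "beta": self.beta.tolist(),
            "beta_prime": self.beta_prime.tolist(),
            "fit_info": {
                k: v for k, v in self.fit_info.items() if not isinstance(v, np.ndarray)
            },
            "ppm_edited": _ppm_to_dict(self.ppm_edited),
            "ppm_unedited": _ppm_to_dict(self.ppm_unedited),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AirlinerResults":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        if doc.get("format") != "airliner-model":
            raise AirlinerError("not an airliner model document")
        return cls(
            beta0=doc["beta0"],
            beta=np.asarray(doc["beta"]),
            beta_prime=np.asarray(doc["beta_prime"]),
            radius=doc["radius"],
            ridge=doc["ridge"],
            ppm_edited=_ppm_from_dict(doc["ppm_edited"]),
            ppm_unedited=_ppm_from_dict(doc["ppm_unedited"]),
            fit_info=doc.get("fit_info", {}),
        )


def _ppm_to_dict(ppm: PositionProbabilityMatrix) -> dict:
    return {
        "radius": ppm.radius,
        "probs": ppm.probs.tolist(),
        "n_sequences": ppm.n_sequences,
        "pseudocount": ppm.pseudocount,
    }


def _ppm_from_dict(doc: dict) -> PositionProbabilityMatrix:
    return PositionProbabilityMatrix(
        radius=doc["radius"],
        probs=np.asarray(doc["probs"]),
        n_sequences=doc["n_sequences"],
        pseudocount=doc["pseudocount"],
    )


def fit(
    windows_pos: Sequence[SequenceWindow],
    windows_neg: Sequence[SequenceWindow],
    ridge: float = 1e-3,
    pseudocount: float = 1.0,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> AirlinerResults:
    """Convenience wrapper: build the model and fit it in one call."""
    return AirlinerModel(
        windows_pos, windows_neg, ridge=ridge, pseudocount=pseudocount
    ).fit(tol=tol, maxiter=maxiter)


def predict_probability(results: AirlinerResults, window: SequenceWindow) -> float:
    return results.predict_probability(window)


def classify(
    results: AirlinerResults, window: SequenceWindow, threshold: float = 0.5
) -> str:
    return results.classify(window, threshold=threshold)


class MultiplicativeScorer:
    """Neighbor-multiplier editing scorer (InosinePredict-style baseline).

    The score of a window is ``base_rate`` (a percentage) multiplied by one
    positive coefficient per configured flank offset, chosen by the
    nucleotide observed at that offset.  Offset 0 (the edited adenosine
    itself) is excluded.  A window is called edited when its score exceeds
    ``threshold_percent`` (default 9.6).
    """

    def __init__(
        self,
        coefficients: Mapping[int, Mapping[str, float]],
        base_rate: float = 100.0,
        threshold_percent: float = 9.6,
        name: str = "multiplicative",
    ):
        self.coefficients = {int(k): dict(v) for k, v in coefficients.items()}
        if 0 in self.coefficients:
            raise AirlinerError("offset 0 (the edited base) cannot carry a multiplier")
        for off, table in self.coefficients.items():
            for nuc, mult in table.items():
                if nuc not in NUCLEOTIDES:
                    raise AirlinerError(
                        f"invalid nucleotide {nuc!r} at offset {off}"
                    )
                if not mult > 0:
                    raise AirlinerError(
                        f"multiplier for offset {off}, nucleotide {nuc} must be > 0"
                    )
        self.base_rate = float(base_rate)
        self.threshold_percent = float(threshold_percent)
        self.name = name

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        base_rate: float = 100.0,
        threshold_percent: float = 9.6,
        name: str | None = None,
    ) -> "MultiplicativeScorer":
        """Load coefficients from a TSV of (offset, nucleotide, multiplier)."""
        coeffs: dict[int, dict[str, float]] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                off_s, nuc, mult_s = line.split("\t")[:3]
                coeffs.setdefault(int(off_s), {})[nuc] = float(mult_s)
        return cls(
            coeffs,
            base_rate=base_rate,
            threshold_percent=threshold_percent,
            name=name or Path(path).stem,
        )

    def score(self, window: SequenceWindow) -> float:
        """Percent editing score: base_rate × product of offset multipliers."""
        value = self.base_rate
        for off, table in self.coefficients.items():
            i = window.radius + off
            if not 0 <= i < len(window.seq):
                raise AirlinerError(
                    f"offset {off} outside window of radius {window.radius}"
                )
            nuc = window.seq[i]
            if nuc not in table:
                raise AirlinerError(
                    f"no multiplier configured for offset {off}, nucleotide {nuc}"
                )
            value *= table[nuc]
        return value

    def classify(self, window: SequenceWindow) -> str:
        return "edited" if self.score(window) > self.threshold_percent else "unedited"
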