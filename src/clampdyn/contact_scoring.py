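"""Cross-domain contact frequencies, per-residue binding scores, and the
fraction of common contacts (FCC).

The biased contact frequency ω_ij^b is the plain fraction of frames in which
a cross-domain residue pair is in contact; the reweighted ω_ij replaces the
uniform frame weights with metadynamics unbiasing weights.  The binding
score S_i = Σ_j ω_ij summarizes how many cross-domain contacts residue i
forms and how persistent they are during detachment.  FCC tracks how much of
a reference interface survives in each frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .collective_variables import ContactSet


@dataclass(frozen=True)
class ContactFrequencyMatrix:
    """ω_ij over cross-domain residue pairs, as a sparse pair → frequency map."""

    freq: dict  # (res_i, res_j) -> ω in [0, 1]
    variant: str  # "biased" or "reweighted"
    n_frames: int

    def __post_init__(self) -> None:
        for pair, w in self.freq.items():
            if not (0.0 <= w <= 1.0 + 1e-12):
                raise ValueError(f"ω{pair} = {w} outside [0, 1]")

    def omega(self, i: int, j: int) -> float:
        return self.freq.get((i, j), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, j, w) for (i, j), w in sorted(self.freq.items())]
        return pd.DataFrame(rows, columns=["res_i", "res_j", "omega"])


@dataclass(frozen=True)
class BindingScores:
    """Per-residue S_i, optionally with replicate statistics."""

    scores: dict  # residue -> S_i (mean over runs if aggregated)
    sd: dict | None = None  # residue -> sd over runs
    n_runs: int = 1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (res, s, (self.sd or {}).get(res, 0.0), self.n_runs)
            for res, s in sorted(self.scores.items())
        ]
        return pd.DataFrame(rows, columns=["residue", "mean_S", "sd", "n_runs"])


@dataclass(frozen=True)
class FCCSeries:
    reference: ContactSet
    time: np.ndarray  # ps
    fcc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.time, "fcc": self.fcc})


def contact_frequency(
    contact_series: list[ContactSet], weights: np.ndarray | None = None,
) -> ContactFrequencyMatrix:
    """ω_ij = Σ_t w_t·[pair in contact at t]; uniform weights when absent."""
    n = len(contact_series)
    if n == 0:
        raise ValueError("empty contact series")
    if weights is None:
        w = np.full(n, 1.0 / n)
        variant = "biased"
    else:
        w = np.asarray(weights, float)
        if len(w) != n:
            raise ValueError(f"{n} frames but {len(w)} weights")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be non-negative and normalized")
        variant = "reweighted"
    freq: dict = {}
    for t, cs in enumerate(contact_series):
        for pair in cs.pairs:
            freq[pair] = freq.get(pair, 0.0) + w[t]
    freq = {p: min(v, 1.0) for p, v in freq.items()}
    return ContactFrequencyMatrix(freq=freq, variant=variant, n_frames=n)


def binding_scores(
    omega: ContactFrequencyMatrix, residues=None, side: str = "both",
) -> BindingScores:
    """S_i = Σ_j ω_ij over partners in the opposite domain.

    ``side`` selects which pair element to score: "a" (first), "b" (second)
    or "both".  Residues listed in ``residues`` but never in contact get an
    explicit S_i = 0.
    """
    scores: dict = {}
    for (i, j), w in omega.freq.items():
        if side in ("a", "both"):
            scores[i] = scores.get(i, 0.0) + w
        if side in ("b", "both"):
            scores[j] = scores.get(j, 0.0) + w
    if residues is not None:
        for res in residues:
            scores.setdefault(int(res), 0.0)
    return BindingScores(scores=scores)


def aggregate_scores(per_run: list[BindingScores]) -> BindingScores:
    """Mean and sd of S_i over replicate runs (dispersion convention: sd)."""
    residues = sorted({r for bs in per_run for r in bs.scores})
    mat = np.array([[bs.scores.get(r, 0.0) for r in residues] for bs in per_run])
    mean = dict(zip(residues, mat.mean(axis=0)))
    sd = dict(zip(residues, mat.std(axis=0, ddof=1) if len(per_run) > 1
                  else np.zeros(len(residues))))
    return BindingScores(scores=mean, sd=sd, n_runs=len(per_run))


def score_ranking(scores: BindingScores, top_k: int) -> list[int]:
    """Residues by descending S_i; ties broken by ascending residue index."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ordered = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k > len(ordered):
        warnings.warn(
            f"top_k={top_k} exceeds {len(ordered)} residues; returning all"
        )
    return [res for res, _ in ordered[:top_k]]


def pair_ranking(omega: ContactFrequencyMatrix) -> list[tuple[int, int]]:
    """Pairs by descending ω_ij, ties broken lexicographically on (i, j)."""
    ordered = sorted(omega.freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return [pair for pair, _ in ordered]


def fraction_common_contacts(frame: ContactSet, reference: ContactSet) -> float:
    """FCC = |frame ∩ reference| / |reference|."""
    if len(reference) == 0:
        raise ValueError("reference contact set is empty")
    return len(frame.pairs & reference.pairs) / len(reference.pairs)


def fcc_series(
    contact_series: list[ContactSet], reference: ContactSet, dt: float = 1.0,
) -> FCCSeries:
    fcc = np.array([fraction_common_contacts(cs, reference) for cs in contact_series])
    return FCCSeries(reference=reference,
                     time=np.arange(len(contact_series)) * dt, fcc=fcc)
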