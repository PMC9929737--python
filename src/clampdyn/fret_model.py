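"""Förster-theory conversion of smFRET efficiencies to distances and their
comparison with model inter-residue distances.

An efficiency E maps to a donor–acceptor distance d = R0·(1/E − 1)^(1/6),
with R0 the Förster radius (5.1 nm by default) and a scalar linker
correction (1 nm) subtracted to account for fluorophore tether length.
Model distances are residue-centroid distances measured over trajectory
frames, pooled across replicas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Trajectory, parse_residue_range

DEFAULT_R0 = 5.1       # Förster radius, nm
DEFAULT_LINKER = 1.0   # fluorophore linker correction, nm


@dataclass(frozen=True)
class FretComparison:
    """Per-pair experimental vs. model distances plus summary statistics."""

    table: pd.DataFrame  # pair_label, E, d_exp_nm, d_model_mean_nm, d_model_sd_nm, physical
    R0: float
    linker: float
    correlation: float | None  # Pearson r across pairs; None for < 2 rows
    mad: float | None          # mean |d_exp − d_model|, nm


def fret_to_distance(
    E: float, R0: float = DEFAULT_R0, linker: float = DEFAULT_LINKER,
) -> tuple[float, bool]:
    """Distance (nm) from FRET efficiency; returns (d, physical_flag).

    ``physical`` is False when the linker subtraction pushes the distance to
    ≤ 0 — the value is reported rather than silently clamped or dropped.
    """
    if not (0.0 < E < 1.0):
        raise ValueError(f"FRET efficiency must lie in (0, 1), got {E}")
    d = R0 * (1.0 / E - 1.0) ** (1.0 / 6.0) - linker
    return float(d), d > 0


def distance_to_fret(
    d: float, R0: float = DEFAULT_R0, linker: float = DEFAULT_LINKER,
) -> float:
    """Inverse map: E = 1/(1 + ((d + linker)/R0)^6)."""
    return 1.0 / (1.0 + ((d + linker) / R0) ** 6)


def model_pair_distance(
    trajectories, pair_spec: tuple,
) -> tuple[float, float]:
    """Mean and sample sd (nm) of the centroid distance of a residue pair.

    ``trajectories`` is a Trajectory or a list of replicas (pooled by
    concatenation); ``pair_spec`` gives two residue selections, each a
    ``"start-end"`` string or residue list.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    res_a = parse_residue_range(pair_spec[0])
    res_b = parse_residue_range(pair_spec[1])
    dists = []
    for traj in trajectories:
        ia = traj.structure.atom_indices(res_a)
        ib = traj.structure.atom_indices(res_b)
        if ia.size == 0 or ib.size == 0:
            raise ValueError(f"residue selection {pair_spec!r} not in structure")
        ca = traj.frames[:, ia].mean(axis=1)
        cb = traj.frames[:, ib].mean(axis=1)
        dists.append(np.linalg.norm(ca - cb, axis=1))
    d_nm = np.concatenate(dists) / 10.0  # Å → nm
    sd = float(d_nm.std(ddof=1)) if len(d_nm) > 1 else 0.0
    return float(d_nm.mean()), sd


def build_comparison(
    pairs_with_E, trajectories, R0: float = DEFAULT_R0,
    linker: float = DEFAULT_LINKER,
) -> FretComparison:
    """Comparison table for rows of (pair_label, selection_a, selection_b, E)."""
    rows = []
    for label, sel_a, sel_b, E in pairs_with_E:
        d_exp, physical = fret_to_distance(E, R0, linker)
        d_mean, d_sd = model_pair_distance(trajectories, (sel_a, sel_b))
        rows.append((label, E, d_exp, d_mean, d_sd, physical))
    table = pd.DataFrame(rows, columns=[
        "pair_label", "E", "d_exp_nm", "d_model_mean_nm", "d_model_sd_nm",
        "physical",
    ])
    if len(table) >= 2:
        mad = float(np.mean(np.abs(table.d_exp_nm - table.d_model_mean_nm)))
        if table.d_exp_nm.std() > 1e-12 and table.d_model_mean_nm.std() > 1e-12:
            correlation = float(
                np.corrcoef(table.d_exp_nm, table.d_model_mean_nm)[0, 1])
        else:
            warnings.warn("zero variance across pairs: correlation undefined")
            correlation = None
    else:
        warnings.warn("fewer than 2 pairs: correlation omitted")
        correlation = None
        mad = None
    return FretComparison(table=table, R0=R0, linker=linker,
                          correlation=correlation, mad=mad)
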