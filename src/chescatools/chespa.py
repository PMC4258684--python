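"""Chemical Shift Projection Analysis (CHESPA).

For three states of one residue — apo, a reference agonist and an analog —
work in the SF-scaled plane ``(delta_H, SF*delta_N)`` and define the vectors
``A = analog - apo`` and ``B = reference - apo``.  Then

* ``dd_comb = |A|``             magnitude of the analog perturbation,
* ``cos_theta = A.B / (|A||B|)``  collinearity of analog and reference
  responses (|cos_theta| well below 1 reveals a non-linear, bent 2D
  trajectory),
* ``X = A.B / |B|^2``           fractional activation: the signed projection
  of A onto B in units of B.  X ~ 1 for agonist-like responses, X < 0 for
  reverse-agonist behaviour.

Residues with |B| = 0 have undefined cos_theta and X; residues with |A| = 0
have dd_comb = 0 and undefined cos_theta and X.  Undefined values are
reported as NaN, never as zeros.

Within a putative allosteric cluster, residues share one conformational
equilibrium and hence one X; members whose X carries the opposite sign and
falls outside the majority band are CHESCA false-positive candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .ccs_core import DEFAULT_SF
from .exceptions import DegenerateInputError
from .shift_io import ShiftDataset

__all__ = [
    "ChespaResult",
    "OutlierFlags",
    "compute_chespa",
    "flag_outliers",
    "nonlinearity_check",
]


@dataclass
class ChespaResult:
    """Per-residue (dd_comb, cos_theta, X) for one analog vs apo/reference."""

    table: pd.DataFrame  # index residue_id; columns dd_comb, cos_theta, X
    apo: str
    reference: str
    analog: str
    sf: float

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(self.table.index)


def compute_chespa(
    dataset: ShiftDataset,
    apo: str,
    reference: str,
    analog: str,
    sf: float = DEFAULT_SF,
) -> ChespaResult:
    """Vector analysis of an analog's shifts against apo and a reference state.

    Only residues observed in all three states are evaluated.
    """
    names = (apo, reference, analog)
    if len(set(names)) != 3:
        raise ValueError(f"apo, reference and analog must be distinct: {names}")
    for name in names:
        dataset.state_meta(name)  # raises on unknown state

    h = dataset.wide("H")[list(names)].dropna()
    n = dataset.wide("N").loc[h.index, list(names)]
    x = h.to_numpy(dtype=float)
    y = sf * n.to_numpy(dtype=float)

    a = np.stack([x[:, 2] - x[:, 0], y[:, 2] - y[:, 0]], axis=1)  # analog - apo
    b = np.stack([x[:, 1] - x[:, 0], y[:, 1] - y[:, 0]], axis=1)  # ref - apo
    norm_a = np.linalg.norm(a, axis=1)
    norm_b = np.linalg.norm(b, axis=1)
    dot = (a * b).sum(axis=1)

    defined = (norm_a > 0) & (norm_b > 0)
    cos_theta = np.full(len(a), np.nan)
    frac = np.full(len(a), np.nan)
    cos_theta[defined] = np.clip(
        dot[defined] / (norm_a[defined] * norm_b[defined]), -1.0, 1.0
    )
    frac[defined] = dot[defined] / norm_b[defined] ** 2

    table = pd.DataFrame(
        {"dd_comb": norm_a, "cos_theta": cos_theta, "X": frac},
        index=h.index,
    )
    table.index.name = "residue_id"
    return ChespaResult(table=table, apo=apo, reference=reference, analog=analog, sf=sf)


@dataclass
class OutlierFlags:
    """Sign-outlier diagnostics for one cluster."""

    flagged: frozenset
    majority_sign: int
    band_mean: float
    band_sd: float
    n_majority: int


def flag_outliers(chespa: ChespaResult, cluster: Iterable) -> OutlierFlags:
    """Flag cluster members whose fractional activation opposes the majority.

    The cluster's majority X sign is found, the mean +/- one SD band is
    computed over the majority-sign values, and members are flagged when
    their X (i) has the opposite sign, (ii) lies outside the band and
    (iii) exceeds the band SD in magnitude — the last condition keeps
    opposite-sign values close to zero, which are within the noise of the
    analysis, unflagged.
    """
    cluster = sorted(set(cluster))
    sub = chespa.table.loc[[r for r in cluster if r in chespa.table.index], "X"]
    sub = sub.dropna()
    signs = np.sign(sub.to_numpy())
    n_neg = int((signs < 0).sum())
    n_pos = int((signs > 0).sum())
    majority = -1 if n_neg >= n_pos else 1
    maj_vals = sub[np.sign(sub) == majority]
    if len(maj_vals) < 3:
        raise DegenerateInputError(
            "outlier flagging needs >= 3 defined X values of the majority "
            f"sign, got {len(maj_vals)}"
        )
    mean = float(maj_vals.mean())
    sd = float(maj_vals.std(ddof=1))
    lo, hi = mean - sd, mean + sd
    flagged = frozenset(
        int(rid)
        for rid, val in sub.items()
        if np.sign(val) == -majority
        and not (lo <= val <= hi)
        and abs(val) > sd
    )
    return OutlierFlags(
        flagged=flagged,
        majority_sign=majority,
        band_mean=mean,
        band_sd=sd,
        n_majority=len(maj_vals),
    )


def nonlinearity_check(
    chespa: ChespaResult, threshold: float = 0.9
) -> frozenset:
    """Residues whose analog/reference trajectories are non-collinear.

    Returns residues with defined ``|cos_theta| < threshold`` — candidates
    for projection-compression artifacts, where distinct 2D peak movements
    collapse onto similar compounded shifts.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    cos = chespa.table["cos_theta"]
    mask = cos.notna() & (cos.abs() < threshold)
    return frozenset(int(r) for r in chespa.table.index[mask])
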