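"""Compounded chemical shifts, the perturbation matrix M and correlations R.

The compounded chemical shift (CCS) collapses a 2D amide cross-peak to one
scalar::

    CCS = delta_H + SF * delta_N

with SF the nitrogen scaling factor (default 0.2).  Algebraically this is a
projection of the (delta_H, delta_N) point onto an axis rotated by
``beta = arctan(SF)`` from the 1H axis, amplified by ``alpha = sqrt(1+SF^2)``:
``CCS = alpha * (delta_H*cos(beta) + delta_N*sin(beta))``.  Peaks separated
along the orthogonal (iso-CCS) direction ``d delta_H = -SF * d delta_N``
compress onto the same CCS value — the degeneracy the per-nucleus analysis
(CHESCA-I) is designed to catch.

The matrix **M** compiles CCS values with rows = residues and columns =
states (ligands); **R** is the residue-residue Pearson correlation matrix of
the rows of **M**, i.e. the correlation matrix of **M** transpose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError
from .shift_io import ShiftDataset

__all__ = [
    "DEFAULT_SF",
    "compute_ccs",
    "ProjectionParams",
    "projection_params",
    "CCSMatrix",
    "build_matrix",
    "CorrelationMatrix",
    "correlation_matrix",
]

DEFAULT_SF = 0.2

NUCLEUS_MODES = ("combined", "H_only", "N_only")


def compute_ccs(delta_H, delta_N, sf: float = DEFAULT_SF):
    """Compounded chemical shift ``delta_H + sf*delta_N`` (ppm-equivalent).

    Accepts scalars or arrays.  ``sf`` must be non-negative and all shifts
    finite.
    """
    if sf < 0:
        raise ValueError(f"scaling factor must be >= 0, got {sf}")
    dh = np.asarray(delta_H, dtype=float)
    dn = np.asarray(delta_N, dtype=float)
    if not (np.isfinite(dh).all() and np.isfinite(dn).all()):
        raise ValidationError("non-finite chemical shift input")
    out = dh + sf * dn
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProjectionParams:
    """Rotated-axis form of the CCS: amplitude alpha and angle beta (degrees)."""

    alpha: float
    beta: float
    scaling_factor: float


def projection_params(sf: float = DEFAULT_SF) -> ProjectionParams:
    """Amplitude/rotation parameters equivalent to the CCS linear combination.

    ``alpha = sqrt(1 + sf^2)`` and ``beta = arctan(sf)`` (degrees); for every
    (delta_H, delta_N) the identity
    ``compute_ccs(dH, dN, sf) == alpha*(dH*cos(beta) + dN*sin(beta))`` holds.
    For sf = 0.2 this gives beta = 11.3 deg and alpha = 1.02.
    """
    if sf < 0:
        raise ValueError(f"scaling factor must be >= 0, got {sf}")
    return ProjectionParams(
        alpha=float(np.sqrt(1.0 + sf * sf)),
        beta=float(np.degrees(np.arctan(sf))),
        scaling_factor=float(sf),
    )


@dataclass
class CCSMatrix:
    """Residues x states matrix **M** of compounded (or single-nucleus) shifts."""

    values: pd.DataFrame  # index: residue ids, columns: state names
    nucleus_mode: str
    scaling_factor: float

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(self.values.index)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def subset(self, residues) -> "CCSMatrix":
        residues = sorted(set(residues))
        missing = set(residues) - set(self.values.index)
        if missing:
            raise KeyError(f"residues not in matrix: {sorted(missing)}")
        return CCSMatrix(
            self.values.loc[residues], self.nucleus_mode, self.scaling_factor
        )


def build_matrix(
    dataset: ShiftDataset,
    nucleus_mode: str = "combined",
    sf: float = DEFAULT_SF,
) -> CCSMatrix:
    """Build **M** from a harmonized dataset.

    ``combined`` applies the CCS per cell; ``H_only``/``N_only`` copy the
    single-nucleus shift tables (the inputs of the per-nucleus intersection
    scheme).
    """
    if nucleus_mode not in NUCLEUS_MODES:
        raise ValueError(f"nucleus_mode must be one of {NUCLEUS_MODES}")
    if not dataset.is_complete:
        raise ValidationError(
            "dataset is incomplete; harmonize() before building the matrix "
            f"(incomplete residues: {list(dataset.incomplete_residues())})"
        )
    h = dataset.wide("H")
    n = dataset.wide("N")
    if nucleus_mode == "combined":
        values = h + sf * n
    elif nucleus_mode == "H_only":
        values = h
    else:
        values = n
    return CCSMatrix(values=values, nucleus_mode=nucleus_mode, scaling_factor=sf)


@dataclass
class CorrelationMatrix:
    """Symmetric residue-residue Pearson correlation matrix **R**."""

    values: pd.DataFrame  # index == columns == residue ids
    excluded: tuple[int, ...] = field(default_factory=tuple)

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(self.values.index)

    def edges(self, threshold: float, absolute: bool = True) -> pd.DataFrame:
        """Edge list (residue_i, residue_j, r) with |r| (or r) >= threshold."""
        res = list(self.values.index)
        rows = []
        vals = self.values.to_numpy()
        for i in range(len(res)):
            for j in range(i + 1, len(res)):
                r = vals[i, j]
                score = abs(r) if absolute else r
                if score >= threshold:
                    rows.append({"residue_i": res[i], "residue_j": res[j], "r": r})
        return pd.DataFrame(rows, columns=["residue_i", "residue_j", "r"])


def correlation_matrix(m: CCSMatrix) -> CorrelationMatrix:
    """Pearson correlation of every residue pair's shift profiles across states.

    Requires >= 3 states.  Residues whose profile has zero variance across
    states (correlation undefined) are excluded with a warning rather than
    failing the whole run.
    """
    values = m.values
    if values.shape[1] < 3:
        raise DegenerateInputError(
            f"correlation needs >= 3 states, got {values.shape[1]}"
        )
    arr = values.to_numpy(dtype=float)
    stds = arr.std(axis=1)
    # constant profiles: allow for the eps*|mean| roundoff of the mean
    keep = stds > 1e-10 * (1.0 + np.abs(arr.mean(axis=1)))
    excluded = tuple(int(r) for r in values.index[~keep])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} zero-variance residue(s) from R: "
            f"{list(excluded)}",
            stacklevel=2,
        )
    kept_index = values.index[keep]
    if keep.sum() == 0:
        empty = pd.DataFrame(index=kept_index, columns=kept_index, dtype=float)
        return CorrelationMatrix(values=empty, excluded=excluded)
    r = np.corrcoef(arr[keep])
    r = np.atleast_2d(r)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        values=pd.DataFrame(r, index=kept_index, columns=kept_index),
        excluded=excluded,
    )
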