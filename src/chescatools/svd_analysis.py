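"""Singular value decomposition of the perturbation response matrix.

Each residue's CCS profile is centered across states (removing the absolute
peak position but keeping the response pattern) and the centered matrix is
decomposed as ``Mc = U S V^T``.  Residue *scores* are ``U S`` and state
*loadings* are ``V``; component signs are fixed so that the apo state's
loading is non-positive, anchoring plots reproducibly.

In the fast-exchange two-state model every purely allosteric residue's
centered profile is proportional to the centered activation-fraction vector,
so those residues form a rank-1 block: their scores lie on the component
whose loadings order the states by activation, with no variation along the
orthogonal components.  This provides an independent criterion for
reassembling fragmented complete-linkage sub-clusters into one allosteric
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ccs_core import CCSMatrix
from .exceptions import DegenerateInputError, MetadataError
from .shift_io import ACTIVE_CLASSES, INACTIVE_CLASSES, ActivityClass, StateMeta

__all__ = [
    "SVDResult",
    "svd_scores",
    "pc1_aligned_residues",
    "assign_pc_function",
    "allosteric_component",
]


@dataclass
class SVDResult:
    """Scores (residues x PCs), loadings (states x PCs) and singular values."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    singular_values: np.ndarray
    centering: str = "per-residue mean across states"

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def reconstruction(self) -> pd.DataFrame:
        """Centered matrix rebuilt as scores @ loadings^T."""
        return pd.DataFrame(
            self.scores.to_numpy() @ self.loadings.to_numpy().T,
            index=self.scores.index,
            columns=self.loadings.index,
        )


def svd_scores(
    m: CCSMatrix,
    residue_subset: Iterable | None = None,
    apo_state: str | None = None,
) -> SVDResult:
    """Decompose (a residue subset of) **M** after per-residue centering.

    ``apo_state`` anchors the sign convention (its loading on every component
    is made <= 0); it defaults to the first state column.
    """
    mat = m if residue_subset is None else m.subset(residue_subset)
    values = mat.values
    if values.shape[1] < 2:
        raise DegenerateInputError(
            f"SVD needs >= 2 states, got {values.shape[1]}"
        )
    if values.shape[0] < 2:
        raise DegenerateInputError(
            f"SVD needs >= 2 residues, got {values.shape[0]}"
        )
    arr = values.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    apo = apo_state if apo_state is not None else values.columns[0]
    if apo not in values.columns:
        raise MetadataError(f"apo state {apo!r} not among matrix columns")
    apo_idx = list(values.columns).index(apo)
    flip = np.where(vt[:, apo_idx] > 0, -1.0, 1.0)
    u = u * flip
    vt = vt * flip[:, None]
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    return SVDResult(
        scores=pd.DataFrame(u * s, index=values.index, columns=pcs),
        loadings=pd.DataFrame(vt.T, index=values.columns, columns=pcs),
        singular_values=s,
    )


def pc1_aligned_residues(
    svd: SVDResult,
    tolerance: float = 0.1,
    component: int = 0,
    ortho_component: int | None = None,
    floor: float = 0.1,
) -> frozenset:
    """Residues aligned along one component with minimal orthogonal variation.

    A residue qualifies if ``|score_ortho| <= tolerance * |score_comp|`` and
    ``|score_comp|`` exceeds ``floor`` times the largest component score (the
    floor keeps unresponsive residues, whose tiny scores trivially satisfy
    the ratio, out of the set).
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    if svd.n_components < 2:
        raise DegenerateInputError("alignment test needs >= 2 components")
    if ortho_component is None:
        ortho_component = 1 if component == 0 else 0
    s_main = svd.scores.iloc[:, component].to_numpy()
    s_orth = svd.scores.iloc[:, ortho_component].to_numpy()
    top = np.abs(s_main).max()
    if top == 0:
        return frozenset()
    eps = np.finfo(float).eps * max(1.0, float(svd.singular_values[0]))
    ok = (np.abs(s_orth) <= tolerance * np.maximum(np.abs(s_main), eps)) & (
        np.abs(s_main) >= floor * top
    )
    return frozenset(svd.scores.index[ok])


def _component_label(
    loadings: pd.Series, states: Sequence[StateMeta]
) -> str:
    by_name = {s.state: s for s in states}
    missing = [n for n in loadings.index if n not in by_name]
    if missing:
        raise MetadataError(f"states without activity metadata: {missing}")
    inactive = [n for n in loadings.index if by_name[n].activity_class in INACTIVE_CLASSES]
    active = [n for n in loadings.index if by_name[n].activity_class in ACTIVE_CLASSES]
    apo = [n for n in loadings.index if by_name[n].activity_class is ActivityClass.APO]
    bound = [n for n in loadings.index if by_name[n].is_bound]
    if inactive and active:
        lo_i, hi_i = loadings[inactive].min(), loadings[inactive].max()
        lo_a, hi_a = loadings[active].min(), loadings[active].max()
        if hi_i < lo_a or hi_a < lo_i:
            return "allosteric"
    if apo and bound:
        a = loadings[apo[0]]
        if a < loadings[bound].min() or a > loadings[bound].max():
            return "binding"
    return "unassigned"


def assign_pc_function(
    svd: SVDResult, states: Sequence[StateMeta]
) -> tuple[str, ...]:
    """Label each component as allosteric / binding / unassigned.

    A component is *allosteric* when ordering states by their loading places
    every inhibited state (apo, reverse agonists, antagonists) on one side of
    every active state — the loading progression expected when the component
    tracks the activation equilibrium.  It is *binding* when apo sits outside
    the loading range of all bound states.  The allosteric template is checked
    first; interleaved orderings are *unassigned*.
    """
    return tuple(
        _component_label(svd.loadings[pc], states) for pc in svd.loadings.columns
    )


def allosteric_component(
    svd: SVDResult, states: Sequence[StateMeta]
) -> int | None:
    """Index of the first allosteric-labelled component, or None."""
    for i, label in enumerate(assign_pc_function(svd, states)):
        if label == "allosteric":
            return i
    return None
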