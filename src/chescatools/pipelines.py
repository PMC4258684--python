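"""End-to-end CHESCA schemes and the escalation workflow.

Three schemes of increasing stringency:

* **CHESCA-SL** — single-linkage clustering of the combined-shift correlation
  matrix at |r| >= 0.98; exhaustive (few false negatives) but chaining-prone.
* **CHESCA-CL** — complete-linkage clustering at the same cutoff fragments
  the network into sub-clusters in which *every* pair correlates above the
  cutoff; sub-clusters whose state dendrograms show the inhibited/active
  bipartition and whose members share one SVD component are reassembled into
  the reconstructed allosteric cluster.
* **CHESCA-I** — the complete-linkage procedure run independently on the 1H
  and 15N shift matrices at |r| >= 0.95; the allosteric set is the
  intersection of the two reconstructions, which removes projection-
  compression artifacts at the price of extra false negatives.

The workflow orchestrator runs CHESCA-CL first, cross-checks the
reconstructed cluster with CHESPA, and escalates to CHESCA-I when sign
outliers or non-collinear trajectories are flagged, or to CHESCA-SL when
same-sign residues appear to have been missed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ccs_core import (
    CCSMatrix,
    CorrelationMatrix,
    DEFAULT_SF,
    build_matrix,
    correlation_matrix,
)
from .chespa import ChespaResult, OutlierFlags, compute_chespa, flag_outliers, nonlinearity_check
from .clustering import ClusterSet, agglomerate, classify_cluster, cut_clusters, state_dendrogram
from .exceptions import DegenerateInputError, ValidationError
from .shift_io import ShiftDataset, harmonize
from .svd_analysis import SVDResult, allosteric_component, pc1_aligned_residues, svd_scores

__all__ = [
    "ChescaConfig",
    "ChescaRun",
    "ToolsetReport",
    "chesca_sl",
    "chesca_cl",
    "chesca_i",
    "run_toolset",
]


@dataclass(frozen=True)
class ChescaConfig:
    """Every tunable of the tool set, with the canonical defaults."""

    sf: float = DEFAULT_SF
    cutoff: float = 0.98  # SL/CL correlation cutoff on combined shifts
    i_cutoff: float = 0.95  # per-nucleus cutoff for the intersection scheme
    min_size: int = 4  # clusters must have more than three residues
    svd_tolerance: float = 0.1
    signed: bool = False  # distance 1 - r instead of 1 - |r|
    alignment_fraction: float = 0.5  # cluster share that must pass alignment
    require_alignment: bool = True  # False: state-dendrogram label suffices
    max_outliers: int = 0  # flagged outliers tolerated before escalating to I
    max_missed: int = 0  # missed same-sign residues tolerated before SL


@dataclass
class ChescaRun:
    """Result of one scheme: clusters, labels and the allosteric set."""

    scheme: str
    params: dict
    clusters: ClusterSet
    cluster_functions: tuple[str, ...]
    allosteric_set: frozenset
    correlation: CorrelationMatrix | None = None
    svd: SVDResult | None = None
    aligned: frozenset = frozenset()
    subruns: dict = field(default_factory=dict)
    log: tuple[str, ...] = ()


def _empty_run(scheme: str, params: dict, linkage: str, message: str) -> ChescaRun:
    warnings.warn(message, stacklevel=3)
    return ChescaRun(
        scheme=scheme,
        params=params,
        clusters=ClusterSet((), params.get("cutoff", float("nan")), linkage, params.get("min_size", 4)),
        cluster_functions=(),
        allosteric_set=frozenset(),
        log=(message,),
    )


def _prepare(dataset: ShiftDataset) -> ShiftDataset:
    if dataset.n_states < 4:
        raise DegenerateInputError(
            f"CHESCA needs >= 4 states for meaningful correlations, got "
            f"{dataset.n_states}"
        )
    return dataset if dataset.is_complete else harmonize(dataset)


def _classify_clusters(
    m: CCSMatrix, clusters: ClusterSet, dataset: ShiftDataset, log: list
) -> tuple[str, ...]:
    labels = []
    for members in clusters.clusters:
        try:
            labels.append(
                classify_cluster(state_dendrogram(m, members), dataset.states)
            )
        except DegenerateInputError as exc:
            log.append(f"cluster {sorted(members)}: unclassifiable ({exc})")
            labels.append("mixed")
    return tuple(labels)


def chesca_sl(
    dataset: ShiftDataset,
    sf: float = DEFAULT_SF,
    cutoff: float = 0.98,
    min_size: int = 4,
    signed: bool = False,
) -> ChescaRun:
    """Single-linkage scheme on combined shifts.

    Combined CCS -> R -> single-linkage dendrogram -> cut at the cutoff ->
    clusters labelled through their state dendrograms; the allosteric set is
    the union of allosteric-labelled clusters.
    """
    params = dict(sf=sf, cutoff=cutoff, min_size=min_size, signed=signed)
    dataset = _prepare(dataset)
    m = build_matrix(dataset, "combined", sf)
    r = correlation_matrix(m)
    if len(r.values) < 2:
        return _empty_run(
            "SL", params, "single",
            "CHESCA-SL: fewer than 2 residues with variance; no clusters",
        )
    log: list[str] = []
    clusters = cut_clusters(agglomerate(r, "single", signed), cutoff, min_size)
    labels = _classify_clusters(m, clusters, dataset, log)
    allosteric = frozenset().union(
        *(c for c, lab in zip(clusters.clusters, labels) if lab == "allosteric"),
        frozenset(),
    )
    return ChescaRun(
        scheme="SL",
        params=params,
        clusters=clusters,
        cluster_functions=labels,
        allosteric_set=frozenset(allosteric),
        correlation=r,
        log=tuple(log),
    )


def _complete_linkage_scheme(
    dataset: ShiftDataset,
    nucleus_mode: str,
    scheme: str,
    sf: float,
    cutoff: float,
    min_size: int,
    svd_tolerance: float,
    signed: bool,
    alignment_fraction: float,
    require_alignment: bool,
) -> ChescaRun:
    params = dict(
        sf=sf,
        cutoff=cutoff,
        min_size=min_size,
        svd_tolerance=svd_tolerance,
        signed=signed,
        nucleus_mode=nucleus_mode,
        alignment_fraction=alignment_fraction,
        require_alignment=require_alignment,
    )
    m = build_matrix(dataset, nucleus_mode, sf)
    r = correlation_matrix(m)
    if len(r.values) < 2:
        return _empty_run(
            scheme, params, "complete",
            f"CHESCA-{scheme}: fewer than 2 residues with variance; no clusters",
        )
    log: list[str] = []
    clusters = cut_clusters(agglomerate(r, "complete", signed), cutoff, min_size)
    labels = _classify_clusters(m, clusters, dataset, log)
    candidates = [
        c for c, lab in zip(clusters.clusters, labels) if lab == "allosteric"
    ]
    svd = None
    aligned: frozenset = frozenset()
    if not candidates:
        log.append("no allosteric-classified cluster; empty allosteric set")
        allosteric: frozenset = frozenset()
    else:
        subset = frozenset().union(*candidates)
        svd = svd_scores(m, subset, apo_state=dataset.apo_state)
        comp = allosteric_component(svd, dataset.states)
        if comp is None:
            log.append("no allosteric SVD component found")
            aligned = frozenset()
        elif svd.n_components >= 2:
            aligned = pc1_aligned_residues(svd, svd_tolerance, component=comp)
        else:  # pragma: no cover - needs exactly 2 states
            aligned = subset
        if require_alignment:
            if comp is None:
                allosteric = frozenset()
            else:
                qualifying = [
                    c
                    for c in candidates
                    if len(c & aligned) >= alignment_fraction * len(c)
                ]
                allosteric = frozenset().union(frozenset(), *qualifying)
        else:
            allosteric = frozenset().union(frozenset(), *candidates)
    return ChescaRun(
        scheme=scheme,
        params=params,
        clusters=clusters,
        cluster_functions=labels,
        allosteric_set=frozenset(allosteric),
        correlation=r,
        svd=svd,
        aligned=aligned,
        log=tuple(log),
    )


def chesca_cl(
    dataset: ShiftDataset,
    sf: float = DEFAULT_SF,
    cutoff: float = 0.98,
    min_size: int = 4,
    svd_tolerance: float = 0.1,
    signed: bool = False,
    alignment_fraction: float = 0.5,
    require_alignment: bool = True,
) -> ChescaRun:
    """Complete-linkage scheme with SVD/state-dendrogram cluster reconstruction.

    Complete-linkage clusters of at least ``min_size`` residues are kept;
    clusters whose state dendrogram shows the inhibited/active bipartition
    *and* whose members score on a single allosteric SVD component (at least
    ``alignment_fraction`` of them passing the ratio test at
    ``svd_tolerance``) are merged into the reconstructed allosteric cluster.
    With ``require_alignment=False`` the state-dendrogram label alone decides.
    """
    dataset = _prepare(dataset)
    return _complete_linkage_scheme(
        dataset, "combined", "CL", sf, cutoff, min_size, svd_tolerance,
        signed, alignment_fraction, require_alignment,
    )


def chesca_i(
    dataset: ShiftDataset,
    cutoff: float = 0.95,
    min_size: int = 4,
    svd_tolerance: float = 0.1,
    sf: float = DEFAULT_SF,
    signed: bool = False,
    alignment_fraction: float = 0.5,
    require_alignment: bool = True,
) -> ChescaRun:
    """Per-nucleus intersection scheme.

    Runs the complete-linkage reconstruction independently on the 1H-only and
    15N-only shift matrices (default cutoff 0.95) and intersects the two
    reconstructed allosteric sets, eliminating residues whose combined-shift
    collinearity is a projection-compression artifact.
    """
    dataset = _prepare(dataset)
    subruns = {
        nucleus: _complete_linkage_scheme(
            dataset, f"{nucleus}_only", f"I/{nucleus}", sf, cutoff, min_size,
            svd_tolerance, signed, alignment_fraction, require_alignment,
        )
        for nucleus in ("H", "N")
    }
    allosteric = subruns["H"].allosteric_set & subruns["N"].allosteric_set
    params = dict(
        sf=sf, cutoff=cutoff, min_size=min_size, svd_tolerance=svd_tolerance,
        signed=signed, alignment_fraction=alignment_fraction,
        require_alignment=require_alignment,
    )
    return ChescaRun(
        scheme="I",
        params=params,
        clusters=subruns["H"].clusters,
        cluster_functions=subruns["H"].cluster_functions,
        allosteric_set=frozenset(allosteric),
        subruns=subruns,
        log=subruns["H"].log + subruns["N"].log,
    )


@dataclass
class ToolsetReport:
    """Workflow output: every scheme run plus the CHESPA cross-check."""

    runs: dict[str, ChescaRun]
    chespa: ChespaResult | None
    outlier_flags: OutlierFlags | None
    nonlinear: frozenset
    missed_same_sign: frozenset
    comparison: pd.DataFrame
    log: tuple[str, ...]


def _comparison_table(
    runs: dict[str, ChescaRun], chespa: ChespaResult | None
) -> pd.DataFrame:
    residues = sorted(
        set().union(*(run.allosteric_set for run in runs.values()), set())
    )
    table = pd.DataFrame(index=pd.Index(residues, name="residue_id"))
    for name, run in runs.items():
        table[f"in_{name}"] = [r in run.allosteric_set for r in residues]
    if chespa is not None:
        table = table.join(chespa.table[["X", "cos_theta"]], how="left")
    return table


def run_toolset(
    dataset: ShiftDataset,
    chespa_states: tuple[str, str, str] | None = None,
    config: ChescaConfig | None = None,
) -> ToolsetReport:
    """Flow-chart orchestration of the tool set.

    Starts with CHESCA-CL; cross-checks the reconstructed cluster with CHESPA
    (``chespa_states = (apo, reference, analog)``); escalates to CHESCA-I if
    more than ``config.max_outliers`` sign outliers (or non-collinear cluster
    members) are flagged, and to CHESCA-SL if more than ``config.max_missed``
    unclustered residues look like missed same-sign members.  Without valid
    CHESPA states the workflow degrades to CHESCA-CL alone, with a warning.
    """
    cfg = config or ChescaConfig()
    dataset = _prepare(dataset)
    log: list[str] = []
    runs: dict[str, ChescaRun] = {}
    runs["CL"] = chesca_cl(
        dataset,
        sf=cfg.sf,
        cutoff=cfg.cutoff,
        min_size=cfg.min_size,
        svd_tolerance=cfg.svd_tolerance,
        signed=cfg.signed,
        alignment_fraction=cfg.alignment_fraction,
        require_alignment=cfg.require_alignment,
    )
    log.append(
        f"CHESCA-CL: {len(runs['CL'].clusters)} cluster(s), "
        f"{len(runs['CL'].allosteric_set)} allosteric residue(s)"
    )

    chespa = None
    flags = None
    nonlinear: frozenset = frozenset()
    missed: frozenset = frozenset()
    if chespa_states is None:
        msg = "no CHESPA states supplied; workflow degrades to CHESCA-CL only"
        warnings.warn(msg, stacklevel=2)
        log.append(msg)
    else:
        try:
            chespa = compute_chespa(dataset, *chespa_states, sf=cfg.sf)
        except Exception as exc:
            msg = f"CHESPA unavailable ({exc}); workflow degrades to CHESCA-CL only"
            warnings.warn(msg, stacklevel=2)
            log.append(msg)

    if chespa is not None and runs["CL"].allosteric_set:
        cluster = runs["CL"].allosteric_set
        try:
            flags = flag_outliers(chespa, cluster)
        except DegenerateInputError as exc:
            log.append(f"outlier flagging skipped: {exc}")
        nonlinear = nonlinearity_check(chespa) & cluster

        suspicious = (flags.flagged if flags else frozenset()) | nonlinear
        if len(suspicious) > cfg.max_outliers:
            log.append(
                f"CHESPA flags {sorted(suspicious)}; escalating to CHESCA-I"
            )
            runs["I"] = chesca_i(
                dataset,
                cutoff=cfg.i_cutoff,
                min_size=cfg.min_size,
                svd_tolerance=cfg.svd_tolerance,
                sf=cfg.sf,
                signed=cfg.signed,
                alignment_fraction=cfg.alignment_fraction,
                require_alignment=cfg.require_alignment,
            )

        if flags is not None:
            x = chespa.table["X"].dropna()
            lo = flags.band_mean - flags.band_sd
            hi = flags.band_mean + flags.band_sd
            missed = frozenset(
                int(rid)
                for rid, val in x.items()
                if rid not in cluster
                and np.sign(val) == flags.majority_sign
                and lo <= val <= hi
            )
            if len(missed) > cfg.max_missed:
                log.append(
                    f"{len(missed)} same-sign residue(s) outside the cluster; "
                    "running CHESCA-SL for completeness"
                )
                runs["SL"] = chesca_sl(
                    dataset,
                    sf=cfg.sf,
                    cutoff=cfg.cutoff,
                    min_size=cfg.min_size,
                    signed=cfg.signed,
                )

    return ToolsetReport(
        runs=runs,
        chespa=chespa,
        outlier_flags=flags,
        nonlinear=nonlinear,
        missed_same_sign=missed,
        comparison=_comparison_table(runs, chespa),
        log=tuple(log),
    )
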