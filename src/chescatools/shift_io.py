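"""Reading, validation and harmonization of amide chemical-shift tables.

The canonical on-disk representation is a long-format CSV/TSV with one row per
(residue, state) pair and the columns ``residue_id, state, delta_H, delta_N``
(an optional ``residue_label`` column carries decorations such as ``"K216"``).
A wide dialect (one row per residue, ``<state>_H``/``<state>_N`` column pairs)
and a minimal NMR-STAR (BMRB ``Atom_chem_shift`` loop) reader are supported as
alternative inputs.  State metadata — the functional class of each ligand in
the perturbation library — travels alongside the shifts as :class:`StateMeta`.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    FormatError,
    MetadataError,
    ParseError,
    ValidationError,
)

__all__ = [
    "ActivityClass",
    "StateMeta",
    "ShiftDataset",
    "read_shift_table",
    "read_state_table",
    "read_nmrstar_shifts",
    "harmonize",
    "write_report",
    "read_cluster_report",
    "read_chespa_report",
    "INACTIVE_CLASSES",
    "ACTIVE_CLASSES",
]


class ActivityClass(str, Enum):
    """Functional class of a state in the perturbation library."""

    APO = "apo"
    REVERSE_AGONIST = "reverse_agonist"
    ANTAGONIST = "antagonist"
    PARTIAL_AGONIST = "partial_agonist"
    AGONIST = "agonist"


#: Classes whose states sample the inhibited side of the activation equilibrium.
INACTIVE_CLASSES = frozenset(
    {ActivityClass.APO, ActivityClass.REVERSE_AGONIST, ActivityClass.ANTAGONIST}
)
#: Classes whose states sample the activated side.
ACTIVE_CLASSES = frozenset({ActivityClass.PARTIAL_AGONIST, ActivityClass.AGONIST})


@dataclass(frozen=True)
class StateMeta:
    """Metadata for one state (one column of the perturbation library)."""

    state: str
    activity_class: ActivityClass
    is_bound: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "activity_class", ActivityClass(self.activity_class)
        )
        if self.activity_class is ActivityClass.APO and self.is_bound:
            raise MetadataError(
                f"state {self.state!r}: apo states cannot be ligand-bound"
            )


_REQUIRED_COLUMNS = ("residue_id", "state", "delta_H", "delta_N")


class ShiftDataset:
    """Residues x states collection of amide (δH, δN) chemical shifts.

    Parameters
    ----------
    records:
        Long-format table with columns ``residue_id, state, delta_H, delta_N``
        (plus optional ``residue_label``).  One row per (residue, state).
    states:
        Ordered state metadata.  Exactly one state must be of class ``apo``.
    """

    def __init__(self, records: pd.DataFrame, states: Sequence[StateMeta]):
        records = records.copy()
        missing = [c for c in _REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise FormatError(f"records table is missing columns: {missing}")
        records["residue_id"] = records["residue_id"].astype(int)
        records["state"] = records["state"].astype(str)
        for col in ("delta_H", "delta_N"):
            records[col] = pd.to_numeric(records[col], errors="raise")
        if (records["residue_id"] <= 0).any():
            bad = records.loc[records["residue_id"] <= 0, "residue_id"].tolist()
            raise ValidationError(f"residue ids must be positive, got {bad}")
        if not np.isfinite(records[["delta_H", "delta_N"]].to_numpy()).all():
            bad = records.loc[
                ~np.isfinite(records["delta_H"]) | ~np.isfinite(records["delta_N"])
            ]
            raise ValidationError(
                "non-finite chemical shifts for (residue, state): "
                f"{list(zip(bad['residue_id'], bad['state']))}"
            )
        dup = records.duplicated(subset=["residue_id", "state"])
        if dup.any():
            pairs = records.loc[dup, ["residue_id", "state"]].to_records(index=False)
            raise ValidationError(f"duplicate (residue, state) pairs: {list(pairs)}")

        states = tuple(states)
        if len({s.state for s in states}) != len(states):
            raise MetadataError("duplicate state names in metadata")
        n_apo = sum(s.activity_class is ActivityClass.APO for s in states)
        if n_apo != 1:
            raise MetadataError(f"exactly one apo state required, found {n_apo}")
        known = {s.state for s in states}
        unknown = set(records["state"]) - known
        if unknown:
            raise MetadataError(
                f"states in table without metadata: {sorted(unknown)}"
            )

        self.records = records.reset_index(drop=True)
        self.states = states

    # -- basic views ------------------------------------------------------

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.state for s in self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def apo_state(self) -> str:
        return next(
            s.state for s in self.states
            if s.activity_class is ActivityClass.APO
        )

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(sorted(self.records["residue_id"].unique()))

    def state_meta(self, name: str) -> StateMeta:
        for s in self.states:
            if s.state == name:
                return s
        raise MetadataError(f"unknown state {name!r}")

    def incomplete_residues(self) -> tuple[int, ...]:
        """Residues lacking an observation in at least one state."""
        counts = self.records.groupby("residue_id")["state"].nunique()
        return tuple(sorted(counts.index[counts < self.n_states]))

    @property
    def is_complete(self) -> bool:
        return not self.incomplete_residues()

    def wide(self, nucleus: str) -> pd.DataFrame:
        """Residues x states table of one nucleus ('H' or 'N'), ppm."""
        if nucleus not in ("H", "N"):
            raise ValueError(f"nucleus must be 'H' or 'N', got {nucleus!r}")
        table = self.records.pivot(
            index="residue_id", columns="state", values=f"delta_{nucleus}"
        )
        return table.reindex(columns=list(self.state_names)).sort_index()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ShiftDataset({len(self.residues)} residues, "
            f"{self.n_states} states: {list(self.state_names)})"
        )


# ---------------------------------------------------------------------------
# readers


def _infer_states(names: Iterable[str]) -> tuple[StateMeta, ...]:
    """Fallback metadata: 'apo' (case-insensitive) is apo, the rest agonists."""
    metas = []
    for name in names:
        if name.lower() == "apo":
            metas.append(StateMeta(name, ActivityClass.APO, is_bound=False))
        else:
            metas.append(StateMeta(name, ActivityClass.AGONIST, is_bound=True))
    warnings.warn(
        "no state metadata supplied; inferred 'apo' from state names and "
        "defaulted every other state to class 'agonist'",
        stacklevel=3,
    )
    return tuple(metas)


def read_state_table(path: str | Path) -> tuple[StateMeta, ...]:
    """Read state metadata CSV with columns state, activity_class[, is_bound]."""
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"state", "activity_class"} <= set(df.columns):
        raise FormatError(
            "state table requires columns 'state' and 'activity_class', "
            f"got {list(df.columns)}"
        )
    metas = []
    for _, row in df.iterrows():
        try:
            cls = ActivityClass(str(row["activity_class"]).strip())
        except ValueError as exc:
            raise MetadataError(
                f"unknown activity class {row['activity_class']!r}"
            ) from exc
        bound = (
            bool(row["is_bound"])
            if "is_bound" in df.columns
            else cls is not ActivityClass.APO
        )
        metas.append(StateMeta(str(row["state"]), cls, bound))
    return tuple(metas)


def _parse_long(df: pd.DataFrame) -> pd.DataFrame:
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for want, aliases in {
        "residue_id": ("residue_id", "residue", "resid"),
        "state": ("state", "ligand"),
        "delta_H": ("delta_h", "dh", "h"),
        "delta_N": ("delta_n", "dn", "n"),
    }.items():
        for alias in aliases:
            if alias in cols:
                rename[cols[alias]] = want
                break
        else:
            raise FormatError(f"required column {want!r} not found")
    df = df.rename(columns=rename)
    bad_rows = []
    for col in ("delta_H", "delta_N"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad_rows.extend((int(i) + 2, col, df[col][i]) for i in df.index[parsed.isna()])
        df[col] = parsed
    if bad_rows:
        detail = "; ".join(f"line {ln}: {col}={val!r}" for ln, col, val in bad_rows)
        raise ParseError(f"non-numeric chemical shifts: {detail}")
    return df


def _parse_wide(df: pd.DataFrame) -> pd.DataFrame:
    id_cols = [c for c in df.columns if c in ("residue_id", "residue", "residue_label")]
    if not id_cols:
        raise FormatError("wide table requires a 'residue_id' (or 'residue') column")
    state_names = []
    for c in df.columns:
        if c.endswith("_H") and f"{c[:-2]}_N" in df.columns:
            state_names.append(c[:-2])
    if not state_names:
        raise FormatError("wide table has no '<state>_H'/'<state>_N' column pairs")
    res_col = "residue_id" if "residue_id" in df.columns else "residue"
    rows = []
    for _, row in df.iterrows():
        for state in state_names:
            h, n = row[f"{state}_H"], row[f"{state}_N"]
            if pd.isna(h) and pd.isna(n):
                continue  # residue not observed in this state
            rows.append(
                {
                    "residue_id": row[res_col],
                    "state": state,
                    "delta_H": h,
                    "delta_N": n,
                    **(
                        {"residue_label": row["residue_label"]}
                        if "residue_label" in df.columns
                        else {}
                    ),
                }
            )
    out = pd.DataFrame(rows)
    bad = out.index[
        pd.to_numeric(out["delta_H"], errors="coerce").isna()
        | pd.to_numeric(out["delta_N"], errors="coerce").isna()
    ]
    if len(bad):
        pairs = out.loc[bad, ["residue_id", "state"]].to_records(index=False)
        raise ParseError(f"non-numeric chemical shifts for: {list(pairs)}")
    return out


def read_nmrstar_shifts(path: str | Path) -> dict[str, pd.DataFrame]:
    """Minimal reader for BMRB ``Atom_chem_shift`` loops.

    Parses every save frame containing an ``_Atom_chem_shift`` loop, pairs the
    H and N rows of each residue, and returns ``{frame_name: table}`` with
    columns ``residue_id, delta_H, delta_N``.  This is a deliberately small
    parser covering only the assigned-chemical-shift loop.
    """
    text = Path(path).read_text()
    frames: dict[str, pd.DataFrame] = {}
    current_frame = "shifts"
    lines = iter(text.splitlines())
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("save_") and len(stripped) > 5:
            current_frame = stripped[5:]
        if stripped != "loop_":
            continue
        tags = []
        for line in lines:
            t = line.strip()
            if t.startswith("_"):
                tags.append(t)
            else:
                first_data = t
                break
        else:  # pragma: no cover - truncated file
            break
        if not any("Atom_chem_shift" in t for t in tags):
            continue

        def tag_index(suffix: str) -> int:
            for i, t in enumerate(tags):
                if t.split(".")[-1] == suffix:
                    return i
            raise FormatError(f"Atom_chem_shift loop lacks tag .{suffix}")

        i_res = tag_index("Comp_index_ID")
        i_atom = tag_index("Atom_ID")
        i_val = tag_index("Val")
        per_residue: dict[int, dict[str, float]] = {}
        data_line = first_data
        while True:
            if data_line in ("stop_", ""):
                if data_line == "stop_":
                    break
            else:
                fields = data_line.split()
                if len(fields) >= len(tags):
                    atom = fields[i_atom]
                    if atom in ("H", "N"):
                        try:
                            rid = int(fields[i_res])
                            val = float(fields[i_val])
                        except ValueError as exc:
                            raise ParseError(
                                f"unparseable Atom_chem_shift row: {data_line!r}"
                            ) from exc
                        per_residue.setdefault(rid, {})[atom] = val
            try:
                data_line = next(lines).strip()
            except StopIteration:
                break
        rows = [
            {"residue_id": rid, "delta_H": v["H"], "delta_N": v["N"]}
            for rid, v in sorted(per_residue.items())
            if "H" in v and "N" in v
        ]
        frames[current_frame] = pd.DataFrame(rows)
    if not frames:
        raise FormatError(f"no Atom_chem_shift loop found in {path}")
    return frames


def read_shift_table(
    path: str | Path,
    dialect: str = "long_csv",
    states: Sequence[StateMeta] | str | Path | None = None,
) -> ShiftDataset:
    """Read a chemical-shift table into a :class:`ShiftDataset`.

    Parameters
    ----------
    path:
        Input file.  ``long_csv``: one row per (residue, state); ``wide_csv``:
        one row per residue with ``<state>_H``/``<state>_N`` pairs;
        ``nmrstar``: BMRB file whose save frames each hold one state's
        assigned chemical shifts (frame names become state names).
    states:
        State metadata — a sequence of :class:`StateMeta` or the path of a
        state table CSV.  If omitted, metadata is inferred from state names
        (with a warning).

    Notes
    -----
    Residues missing in some state are retained here and flagged by
    :meth:`ShiftDataset.incomplete_residues`; use :func:`harmonize` before any
    covariance analysis.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if isinstance(states, (str, Path)):
        states = read_state_table(states)

    if dialect == "long_csv":
        records = _parse_long(pd.read_csv(path, sep=None, engine="python"))
    elif dialect == "wide_csv":
        records = _parse_wide(pd.read_csv(path, sep=None, engine="python"))
    elif dialect == "nmrstar":
        frames = read_nmrstar_shifts(path)
        records = pd.concat(
            [df.assign(state=name) for name, df in frames.items()],
            ignore_index=True,
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if states is None:
        states = _infer_states(pd.unique(records["state"]))
    return ShiftDataset(records, states)


# ---------------------------------------------------------------------------
# harmonization


def harmonize(dataset: ShiftDataset, policy: str = "drop_incomplete") -> ShiftDataset:
    """Enforce residues x states completeness.

    ``drop_incomplete`` removes residues missing any state (with a warning
    listing them); ``fail`` raises instead.  Covariance analysis is undefined
    on incomplete per-residue profiles, so every pipeline entry point calls
    this first.
    """
    incomplete = dataset.incomplete_residues()
    if not incomplete:
        return dataset
    if policy == "fail":
        raise ValidationError(
            f"residues incomplete across states: {list(incomplete)}"
        )
    if policy != "drop_incomplete":
        raise ValueError(f"unknown policy {policy!r}")
    warnings.warn(
        f"dropping {len(incomplete)} residue(s) with missing states: "
        f"{list(incomplete)}",
        stacklevel=2,
    )
    kept = dataset.records[~dataset.records["residue_id"].isin(incomplete)]
    if kept.empty:
        raise DegenerateInputError("no residue is complete across all states")
    return ShiftDataset(kept, dataset.states)


# ---------------------------------------------------------------------------
# report writing (round-trip stable)


def write_report(results, path: str | Path, format: str = "csv") -> None:
    """Write a result object (ClusterSet, ChespaResult, DataFrame, dict).

    CSV/JSON outputs round-trip: reading a written cluster or projection
    report reproduces the in-memory values to full float precision.
    """
    path = Path(path)
    if format not in ("csv", "json"):
        raise ValueError(f"unknown format {format!r}")
    df = _as_frame(results)
    try:
        if format == "csv":
            df.to_csv(path, index=False)
        else:
            path.write_text(df.to_json(orient="records", double_precision=15))
    except OSError as exc:
        raise ChescaIOError(str(exc)) from exc


class ChescaIOError(IOError):
    pass


def _as_frame(results) -> pd.DataFrame:
    from .chespa import ChespaResult
    from .clustering import ClusterSet

    if isinstance(results, pd.DataFrame):
        return results
    if isinstance(results, ClusterSet):
        rows = [
            {
                "residue_id": rid,
                "cluster_id": cid,
                "linkage": results.linkage,
                "cutoff": results.cutoff,
            }
            for cid, members in enumerate(results.clusters, start=1)
            for rid in sorted(members)
        ]
        return pd.DataFrame(
            rows, columns=["residue_id", "cluster_id", "linkage", "cutoff"]
        )
    if isinstance(results, ChespaResult):
        out = results.table.reset_index()
        out.insert(1, "apo", results.apo)
        out.insert(2, "reference", results.reference)
        out.insert(3, "analog", results.analog)
        return out
    if isinstance(results, dict):
        return pd.DataFrame([results])
    raise TypeError(f"cannot serialize result of type {type(results).__name__}")


def read_cluster_report(path: str | Path):
    """Inverse of write_report for ClusterSet CSVs."""
    from .clustering import ClusterSet

    df = pd.read_csv(path)
    clusters = [
        frozenset(int(r) for r in grp["residue_id"])
        for _, grp in df.groupby("cluster_id", sort=True)
    ]
    if df.empty:
        return ClusterSet(clusters=(), cutoff=float("nan"), linkage="single", min_size=0)
    return ClusterSet(
        clusters=tuple(clusters),
        cutoff=float(df["cutoff"].iloc[0]),
        linkage=str(df["linkage"].iloc[0]),
        min_size=min(len(c) for c in clusters),
    )


def read_chespa_report(path: str | Path):
    """Inverse of write_report for ChespaResult CSVs."""
    from .chespa import ChespaResult

    df = pd.read_csv(path)
    table = df.set_index("residue_id")[["dd_comb", "cos_theta", "X"]]
    return ChespaResult(
        table=table,
        apo=str(df["apo"].iloc[0]),
        reference=str(df["reference"].iloc[0]),
        analog=str(df["analog"].iloc[0]),
        sf=float("nan"),
    )
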