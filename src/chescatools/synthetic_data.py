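"""Synthetic shift datasets under the two-state fast-exchange model.

In fast exchange the observed shift of a residue sensing only the activation
equilibrium is the population-weighted average of its pure inactive and
active positions::

    delta(r, s) = (1 - p_s) * delta_inactive(r) + p_s * delta_active(r)

where ``p_s`` is the activation fraction locked in by the ligand of state
``s``.  On top of this allosteric term the generator adds a binding offset
(switched by ligand occupancy), ligand-specific nearest-neighbour effects
(NNEs — random per (residue, bound state) perturbations that model the
chemically distinct analog moieties near binding residues) and Gaussian
measurement noise.  Residue roles:

* ``allosteric``    – two-state term only,
* ``binding``       – occupancy offset + NNEs only,
* ``mixed``         – both,
* ``unresponsive``  – neither (noise only).

Besides the general generator, two targeted fixtures reproduce the failure
modes the tool set is built around: a *chaining* fixture whose residue
profiles rotate gradually between a binding-like and an allosteric pattern
(single linkage chains the weakly correlated endpoints, complete linkage
does not), and a *projection-compression* fixture in which one residue's
peak moves along the iso-CCS direction so its compounded shifts mimic an
allosteric profile while its 2D trajectory is bent.  Both fixtures assert
their own calibration targets at generation time and refuse to emit data
that violates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ccs_core import DEFAULT_SF, build_matrix, correlation_matrix
from .chespa import compute_chespa
from .exceptions import CalibrationError, ValidationError
from .shift_io import ActivityClass, ShiftDataset, StateMeta

__all__ = [
    "StateSpec",
    "GeneratorConfig",
    "SyntheticGroundTruth",
    "generate",
    "make_chaining_fixture",
    "make_compression_fixture",
    "DEFAULT_STATES",
]

ROLES = ("allosteric", "binding", "mixed", "unresponsive")


@dataclass(frozen=True)
class StateSpec:
    """One state of the perturbation library with its ground-truth physics."""

    name: str
    activity_class: ActivityClass
    activation: float  # fraction of the active conformation, in [0, 1]
    occupancy: float  # ligand occupancy, 0 (apo) or 1 (saturated)

    def meta(self) -> StateMeta:
        return StateMeta(self.name, self.activity_class, bool(self.occupancy))


#: Five-state library qualitatively mirroring an apo + reverse-agonist +
#: partial-agonist + two-agonist analog series.
DEFAULT_STATES = (
    StateSpec("apo", ActivityClass.APO, 0.2, 0.0),
    StateSpec("Rp", ActivityClass.REVERSE_AGONIST, 0.1, 1.0),
    StateSpec("OMe", ActivityClass.PARTIAL_AGONIST, 0.8, 1.0),
    StateSpec("cAMP", ActivityClass.AGONIST, 0.95, 1.0),
    StateSpec("Sp", ActivityClass.AGONIST, 1.0, 1.0),
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic two-state generator.

    Shift scales are realistic amide ranges: random-coil positions drawn from
    deltaH in [6.5, 10] ppm and deltaN in [103, 133] ppm; inactive-to-active
    displacements of 0.02-0.15 ppm (1H) and 0.2-1.5 ppm (15N) with random
    signs; binding offsets on the same scale.  Noise defaults to 0.002 ppm on
    1H and 0.01 ppm on 15N so each nucleus contributes 0.002 ppm on the
    SF-scaled (1H-equivalent) axis.
    """

    n_allosteric: int = 30
    n_binding: int = 15
    n_mixed: int = 0
    n_unresponsive: int = 15
    states: Sequence[StateSpec] = DEFAULT_STATES
    h_range: tuple[float, float] = (6.5, 10.0)
    n_range: tuple[float, float] = (103.0, 133.0)
    disp_h: tuple[float, float] = (0.02, 0.15)
    disp_n: tuple[float, float] = (0.2, 1.5)
    bind_h: tuple[float, float] = (0.02, 0.15)
    bind_n: tuple[float, float] = (0.2, 1.5)
    nne_sigma_h: float = 0.005
    nne_sigma_n: float = 0.025
    noise_sigma_h: float = 0.002
    noise_sigma_n: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for s in self.states:
            if not (0.0 <= s.activation <= 1.0):
                raise ValidationError(
                    f"state {s.name!r}: activation fraction {s.activation} "
                    "outside [0, 1]"
                )
            if s.occupancy not in (0.0, 1.0):
                raise ValidationError(
                    f"state {s.name!r}: occupancy must be 0 or 1"
                )
        if not any(
            s.activity_class is ActivityClass.APO and s.occupancy == 0.0
            for s in self.states
        ):
            raise ValidationError("config needs one apo state with occupancy 0")
        if min(
            self.n_allosteric, self.n_binding, self.n_mixed, self.n_unresponsive
        ) < 0:
            raise ValidationError("role counts must be non-negative")
        if any(
            sigma < 0
            for sigma in (
                self.nne_sigma_h,
                self.nne_sigma_n,
                self.noise_sigma_h,
                self.noise_sigma_n,
            )
        ):
            raise ValidationError("noise/NNE sigmas must be non-negative")


@dataclass
class SyntheticGroundTruth:
    """Per-residue roles and the per-state physics the dataset was built from."""

    roles: pd.Series  # index residue_id -> role string
    activation: dict[str, float]
    occupancy: dict[str, float]
    inactive_positions: pd.DataFrame  # residue -> (delta_H, delta_N)
    displacements: pd.DataFrame  # inactive->active displacement per nucleus
    binding_offsets: pd.DataFrame
    seed: int

    def residues_with_role(self, *roles: str) -> frozenset:
        return frozenset(int(r) for r in self.roles.index[self.roles.isin(roles)])

    @property
    def allosteric_residues(self) -> frozenset:
        """Residues sensing the activation equilibrium (allosteric + mixed)."""
        return self.residues_with_role("allosteric", "mixed")


def _signed_uniform(rng, lo, hi, size):
    return rng.uniform(lo, hi, size) * rng.choice([-1.0, 1.0], size)


def generate(config: GeneratorConfig) -> tuple[ShiftDataset, SyntheticGroundTruth]:
    """Emit a ShiftDataset plus its ground truth; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = {
        "allosteric": config.n_allosteric,
        "binding": config.n_binding,
        "mixed": config.n_mixed,
        "unresponsive": config.n_unresponsive,
    }
    roles = [role for role in ROLES for _ in range(counts[role])]
    n_res = len(roles)
    residues = np.arange(1, n_res + 1)
    role_s = pd.Series(roles, index=residues, name="role")

    base_h = rng.uniform(*config.h_range, n_res)
    base_n = rng.uniform(*config.n_range, n_res)
    allo_mask = role_s.isin(["allosteric", "mixed"]).to_numpy()
    bind_mask = role_s.isin(["binding", "mixed"]).to_numpy()
    disp_h = _signed_uniform(rng, *config.disp_h, n_res) * allo_mask
    disp_n = _signed_uniform(rng, *config.disp_n, n_res) * allo_mask
    bind_h = _signed_uniform(rng, *config.bind_h, n_res) * bind_mask
    bind_n = _signed_uniform(rng, *config.bind_n, n_res) * bind_mask

    rows = []
    for spec in config.states:
        p, occ = spec.activation, spec.occupancy
        nne_h = np.zeros(n_res)
        nne_n = np.zeros(n_res)
        if occ > 0:
            nne_h = rng.normal(0.0, config.nne_sigma_h, n_res) * bind_mask
            nne_n = rng.normal(0.0, config.nne_sigma_n, n_res) * bind_mask
        dh = (
            base_h
            + p * disp_h
            + occ * bind_h
            + nne_h
            + rng.normal(0.0, config.noise_sigma_h, n_res)
        )
        dn = (
            base_n
            + p * disp_n
            + occ * bind_n
            + nne_n
            + rng.normal(0.0, config.noise_sigma_n, n_res)
        )
        rows.append(
            pd.DataFrame(
                {
                    "residue_id": residues,
                    "state": spec.name,
                    "delta_H": dh,
                    "delta_N": dn,
                }
            )
        )
    dataset = ShiftDataset(
        pd.concat(rows, ignore_index=True),
        [s.meta() for s in config.states],
    )
    truth = SyntheticGroundTruth(
        roles=role_s,
        activation={s.name: s.activation for s in config.states},
        occupancy={s.name: s.occupancy for s in config.states},
        inactive_positions=pd.DataFrame(
            {"delta_H": base_h, "delta_N": base_n}, index=residues
        ),
        displacements=pd.DataFrame(
            {"delta_H": disp_h, "delta_N": disp_n}, index=residues
        ),
        binding_offsets=pd.DataFrame(
            {"delta_H": bind_h, "delta_N": bind_n}, index=residues
        ),
        seed=config.seed,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# chaining fixture


@dataclass
class ChainingFixtureInfo:
    """Construction record for the chaining fixture."""

    chain: tuple[int, ...]  # residues in interpolation order
    endpoints: tuple[int, int]
    consecutive_min_r: float
    endpoint_r: float
    cutoff: float


def _slerp(u: np.ndarray, v: np.ndarray, t: float) -> np.ndarray:
    theta = np.arccos(np.clip(u @ v, -1.0, 1.0))
    return (np.sin((1 - t) * theta) * u + np.sin(t * theta) * v) / np.sin(theta)


def make_chaining_fixture(
    seed: int,
    n_residues: int = 6,
    sf: float = DEFAULT_SF,
    cutoff: float = 0.98,
) -> tuple[ShiftDataset, ChainingFixtureInfo]:
    """Residues whose profiles interpolate binding-like -> allosteric.

    The first residue follows a binding-like pattern (the reverse-agonist
    analog sits midway between apo and the active states) and the last an
    allosteric pattern (apo sits between the analog and the actives); the
    residues in between rotate gradually along the geodesic between the two
    centered unit profiles.  Consecutive profile correlations stay >= 0.985
    while the endpoint correlation drops to ~0.84, so single linkage at the
    0.98 cutoff chains the endpoints into one cluster while complete linkage
    separates them.  Calibration (consecutive r, endpoint r, and the absence
    of shortcut edges at the cutoff) is asserted before the dataset is
    returned.
    """
    if n_residues < 6:
        raise ValueError("chaining fixture needs >= 6 residues")
    rng = np.random.default_rng(seed)
    specs = DEFAULT_STATES
    # state profile anchors: values per state before centering/normalisation
    binding_like = np.array([0.0, 0.5, 1.0, 1.0, 1.0])  # analog midway
    allosteric = np.array([s.activation for s in specs])  # apo between Rp/actives

    def unitize(w):
        w = w - w.mean()
        return w / np.linalg.norm(w)

    u, v = unitize(binding_like), unitize(allosteric)
    ts = np.linspace(0.0, 1.0, n_residues)
    profiles = np.stack([_slerp(u, v, t) for t in ts])

    residues = np.arange(1, n_residues + 1)
    base_h = rng.uniform(6.5, 10.0, n_residues)
    base_n = rng.uniform(103.0, 133.0, n_residues)
    amp_ccs = rng.uniform(0.15, 0.3, n_residues)
    gamma = rng.uniform(0.3, 0.7, n_residues)  # share of the CCS response in 1H
    amp_h = amp_ccs * gamma
    amp_n = amp_ccs * (1.0 - gamma) / sf

    rows = []
    for j, spec in enumerate(specs):
        rows.append(
            pd.DataFrame(
                {
                    "residue_id": residues,
                    "state": spec.name,
                    "delta_H": base_h + amp_h * profiles[:, j],
                    "delta_N": base_n + amp_n * profiles[:, j],
                }
            )
        )
    dataset = ShiftDataset(
        pd.concat(rows, ignore_index=True), [s.meta() for s in specs]
    )

    r = correlation_matrix(build_matrix(dataset, "combined", sf)).values.to_numpy()
    consecutive = np.array([r[i, i + 1] for i in range(n_residues - 1)])
    endpoint = float(r[0, -1])
    if consecutive.min() < 0.985:
        raise CalibrationError(
            f"consecutive correlation {consecutive.min():.4f} < 0.985"
        )
    if abs(endpoint) > 0.90:
        raise CalibrationError(f"endpoint correlation {endpoint:.4f} > 0.90")
    shortcuts = [
        (i, j)
        for i in range(n_residues)
        for j in range(i + 2, n_residues)
        if abs(r[i, j]) >= cutoff
    ]
    if shortcuts:
        raise CalibrationError(f"non-consecutive pairs above cutoff: {shortcuts}")
    info = ChainingFixtureInfo(
        chain=tuple(int(x) for x in residues),
        endpoints=(int(residues[0]), int(residues[-1])),
        consecutive_min_r=float(consecutive.min()),
        endpoint_r=endpoint,
        cutoff=cutoff,
    )
    return dataset, info


# ---------------------------------------------------------------------------
# projection-compression fixture


@dataclass
class CompressionFixtureInfo:
    """Construction record for the projection-compression fixture."""

    compressed_residue: int
    allosteric_residues: frozenset
    cos_theta: float
    min_combined_r: float
    max_per_nucleus_r: dict[str, float]
    apo: str
    reference: str
    analog: str


def make_compression_fixture(
    seed: int,
    sf: float = DEFAULT_SF,
    n_allosteric: int = 8,
    target_cos: float = 0.5,
) -> tuple[ShiftDataset, CompressionFixtureInfo]:
    """A residue whose analog peak slides along the iso-CCS direction.

    ``n_allosteric`` residues follow the noisy two-state model; one extra
    residue is built allosteric-like except that its reverse-agonist peak is
    displaced along ``d delta_H = -sf * d delta_N`` (zero net CCS change)
    until its CHESPA trajectory bends to ``cos_theta ~ target_cos`` with a
    positive fractional activation.  Its compounded profile therefore stays
    collinear with the genuine allosteric residues (combined r >= 0.98) while
    at least one single-nucleus profile decorrelates (r < 0.95) — the
    signature that the per-nucleus intersection scheme exploits.  All three
    constraints are asserted at generation time.
    """
    if sf <= 0:
        raise ValueError(f"scaling factor must be > 0, got {sf}")
    rng = np.random.default_rng(seed)
    specs = DEFAULT_STATES
    p = np.array([s.activation for s in specs])
    apo_name, analog_name, ref_name = "apo", "Rp", "Sp"
    i_apo, i_analog, i_ref = 0, 1, 4
    noise_h, noise_n = 5e-4, 2.5e-3

    n_res = n_allosteric + 1
    residues = np.arange(1, n_res + 1)
    compressed = int(residues[-1])
    base_h = rng.uniform(6.5, 10.0, n_res)
    base_n = rng.uniform(103.0, 133.0, n_res)

    disp_h = np.empty(n_res)
    disp_n = np.empty(n_res)
    for i in range(n_allosteric):
        while True:
            dh = float(_signed_uniform(rng, 0.05, 0.15, 1)[0])
            dn = float(_signed_uniform(rng, 0.5, 1.5, 1)[0])
            if abs(dh + sf * dn) >= 0.1:
                disp_h[i], disp_n[i] = dh, dn
                break

    # compressed residue: choose a scaled-plane displacement direction at a
    # moderate angle to the iso-CCS direction u = (1, -1)/sqrt(2) so the bent
    # trajectory can reach the target cos_theta with a positive projection
    u = np.array([1.0, -1.0]) / np.sqrt(2.0)
    while True:
        psi = rng.uniform(-np.pi / 2, np.pi / 18)
        b_hat = np.array([np.cos(psi), np.sin(psi)])
        if 0.7 <= u @ b_hat <= 0.9 and abs(b_hat.sum()) * 0.25 >= 0.1:
            break
    d_scaled = 0.25 * b_hat  # (d delta_H, sf * d delta_N)
    disp_h[-1] = d_scaled[0]
    disp_n[-1] = d_scaled[1] / sf

    b_vec = (p[i_ref] - p[i_apo]) * d_scaled

    def cos_at(t):
        a_vec = (p[i_analog] - p[i_apo]) * d_scaled + t * u
        return a_vec @ b_vec / (np.linalg.norm(a_vec) * np.linalg.norm(b_vec))

    t_star = brentq(lambda t: cos_at(t) - target_cos, 0.0, 10.0)

    rows = []
    for j, spec in enumerate(specs):
        dh = base_h + p[j] * disp_h + rng.normal(0.0, noise_h, n_res)
        dn = base_n + p[j] * disp_n + rng.normal(0.0, noise_n, n_res)
        if j == i_analog:
            dh[-1] += t_star * u[0]
            dn[-1] += t_star * u[1] / sf
        rows.append(
            pd.DataFrame(
                {
                    "residue_id": residues,
                    "state": spec.name,
                    "delta_H": dh,
                    "delta_N": dn,
                }
            )
        )
    dataset = ShiftDataset(
        pd.concat(rows, ignore_index=True), [s.meta() for s in specs]
    )

    allo = frozenset(int(x) for x in residues[:-1])
    r_comb = correlation_matrix(build_matrix(dataset, "combined", sf)).values
    min_comb = float(min(abs(r_comb.at[compressed, a]) for a in allo))
    if min_comb < 0.98:
        raise CalibrationError(
            f"combined correlation of compressed residue {min_comb:.4f} < 0.98"
        )
    max_nuc = {}
    for mode, label in (("H_only", "H"), ("N_only", "N")):
        r_nuc = correlation_matrix(build_matrix(dataset, mode, sf)).values
        max_nuc[label] = float(
            max(abs(r_nuc.at[compressed, a]) for a in allo)
        )
    if min(max_nuc.values()) >= 0.95:
        raise CalibrationError(
            f"no nucleus decorrelates the compressed residue: {max_nuc}"
        )
    chespa = compute_chespa(dataset, apo_name, ref_name, analog_name, sf)
    cos = float(chespa.table.at[compressed, "cos_theta"])
    if abs(cos - target_cos) > 0.1:
        raise CalibrationError(
            f"compressed residue cos_theta {cos:.3f} not within 0.1 of "
            f"{target_cos}"
        )
    info = CompressionFixtureInfo(
        compressed_residue=compressed,
        allosteric_residues=allo,
        cos_theta=cos,
        min_combined_r=min_comb,
        max_per_nucleus_r=max_nuc,
        apo=apo_name,
        reference=ref_name,
        analog=analog_name,
    )
    return dataset, info
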