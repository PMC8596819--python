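"""Docking backend contract, batch dispatch, and write-out modes.

The orchestration layer is engine-agnostic: a backend declares its name, its
score direction (engines disagree on whether lower or higher is better), a
``dock`` function from one embedded enumeration to scored poses, and a pose
cap. Batch dispatch chunks enumerations across worker processes, collates
pose records, and reduces them with one of three write-out modes:

* ``all`` — every pose of every enumeration,
* ``best_per_enumeration`` — one row per tautomer/stereoisomer state,
* ``best_per_ligand`` — one row per input compound (the default; downstream
  screening statistics conventionally keep only the best state per ligand).

A deterministic synthetic backend ships with the package so the whole
pipeline runs end to end without any external docking engine: it scores a
ligand by similarity of a fixed physicochemical descriptor vector to a
receptor-defined target vector. Adapters for external engines are registered
as placeholders and refuse to run until an executable is configured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .analysis import DIRECTIONS, HIGHER, LOWER
from .ligands import Enumeration

WRITE_OUT_MODES = ("best_per_ligand", "best_per_enumeration", "all")

#: descriptor channels used by the synthetic backend, in order
DESCRIPTOR_NAMES = (
    "heavy_atoms",
    "rings",
    "aromatic_rings",
    "hbd",
    "hba",
    "rotatable_bonds",
    "mw_100",
    "tpsa_50",
)
#: per-channel softness of the similarity decay, in descriptor units
DESCRIPTOR_SCALES = np.array([5.0, 1.0, 1.0, 1.0, 2.0, 2.0, 1.0, 1.0])


def physchem_descriptors(smiles: str) -> np.ndarray:
    """Fixed 8-channel descriptor vector of a molecule (see DESCRIPTOR_NAMES)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return np.array(
        [
            mol.GetNumHeavyAtoms(),
            rdMolDescriptors.CalcNumRings(mol),
            rdMolDescriptors.CalcNumAromaticRings(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            Descriptors.MolWt(mol) / 100.0,
            rdMolDescriptors.CalcTPSA(mol) / 50.0,
        ],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# receptor and record types
# ---------------------------------------------------------------------------


@dataclass
class ReceptorProfile:
    """What a backend needs to know about the binding site.

    The synthetic backend reads ``target`` (preferred descriptor vector) and
    ``weights`` (channel importances); external adapters read only the opaque
    ``external_payload`` path (grid archive, PDBQT, ...). ``box_center`` /
    ``box_edges`` describe the search cavity in Angstrom.
    """

    identifier: str
    box_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    box_edges: tuple[float, float, float] = (15.0, 15.0, 15.0)
    target: np.ndarray | None = None
    weights: np.ndarray | None = None
    external_payload: str | None = None

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.box_edges):
            raise ValueError("box edge lengths must be positive")
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
            if self.weights is None:
                self.weights = np.ones_like(self.target)
            self.weights = np.asarray(self.weights, dtype=float)
            if self.target.shape != self.weights.shape:
                raise ValueError("synthetic target and weight vectors must have equal length")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReceptorProfile":
        import json

        raw = json.loads(Path(path).read_text())
        return cls(
            identifier=raw["identifier"],
            box_center=tuple(raw.get("box_center", (0.0, 0.0, 0.0))),
            box_edges=tuple(raw.get("box_edges", (15.0, 15.0, 15.0))),
            target=np.array(raw["target"], dtype=float) if "target" in raw else None,
            weights=np.array(raw["weights"], dtype=float) if "weights" in raw else None,
            external_payload=raw.get("external_payload"),
        )


@dataclass
class PoseRecord:
    ligand_id: str
    enumeration_index: int
    pose_index: int
    score: float
    smiles: str | None = None
    elements: list[str] | None = None
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("pose score must be finite")


@dataclass
class DockingFailure:
    ligand_id: str
    enumeration_index: int
    reason: str


@dataclass
class DockingReport:
    backend: str
    direction: str
    receptor_id: str
    poses: list[PoseRecord] = field(default_factory=list)
    failures: list[DockingFailure] = field(default_factory=list)
    ligand_names: dict[str, str] = field(default_factory=dict)

    @property
    def n_scored_enumerations(self) -> int:
        return len({(p.ligand_id, p.enumeration_index) for p in self.poses})


# ---------------------------------------------------------------------------
# backend contract and registry
# ---------------------------------------------------------------------------


class BackendUnavailable(RuntimeError):
    """Raised when an adapter backend has no configured executable."""


@dataclass
class SyntheticBackend:
    """Deterministic stand-in docking engine.

    The score of an enumeration is ``-(w · s)`` where ``s_k =
    exp(-|d_k - t_k| / scale_k)`` compares the ligand's physicochemical
    descriptor vector ``d`` to the receptor's target vector ``t`` channel by
    channel. Lower is better; the minimum ``-(sum w)`` is attained exactly
    when the ligand matches the target on every channel, and the score worsens
    monotonically with per-channel descriptor distance. The result is a pure
    function of (canonical SMILES, receptor payload), hence bit-reproducible.
    """

    name: str = "synthetic"
    score_direction: str = LOWER
    max_poses: int = 1
    embeds_internally: bool = False
    scales: np.ndarray = field(default_factory=lambda: DESCRIPTOR_SCALES.copy())

    def dock(self, enumeration: Enumeration, receptor: ReceptorProfile, params=None):
        return synthetic_dock(enumeration, receptor, scales=self.scales)


def synthetic_dock(
    enumeration: Enumeration,
    receptor: ReceptorProfile,
    scales: np.ndarray = DESCRIPTOR_SCALES,
) -> list[PoseRecord]:
    """Score one enumeration against the synthetic receptor; one pose out."""
    if receptor.target is None:
        raise ValueError(f"receptor {receptor.identifier!r} carries no synthetic payload")
    d = physchem_descriptors(enumeration.smiles)
    if d.shape != receptor.target.shape:
        raise ValueError(
            f"descriptor length {d.shape[0]} != receptor target length "
            f"{receptor.target.shape[0]}"
        )
    sim = np.exp(-np.abs(d - receptor.target) / np.asarray(scales, dtype=float))
    score = float(-(receptor.weights @ sim))
    return [
        PoseRecord(
            ligand_id=enumeration.ligand_id,
            enumeration_index=enumeration.enumeration_index,
            pose_index=0,
            score=score,
            smiles=enumeration.smiles,
            elements=enumeration.elements,
            coordinates=enumeration.coordinates,
        )
    ]


@dataclass
class AdapterStub:
    """Placeholder for an external docking engine behind the same contract.

    Declares the engine's score direction; refuses to dock until an
    executable path is configured (none of the engines ships with this
    package).
    """

    name: str
    score_direction: str
    max_poses: int = 1
    embeds_internally: bool = False
    executable: str | None = None

    def dock(self, enumeration, receptor, params=None):
        if self.executable is None:
            raise BackendUnavailable(
                f"backend {self.name!r} is an external-engine adapter; "
                "configure its executable to use it"
            )
        raise NotImplementedError(f"adapter for {self.name!r} is a contract stub")


BACKEND_REGISTRY: dict[str, object] = {}


def register_backend(backend) -> None:
    if backend.score_direction not in DIRECTIONS:
        raise ValueError(f"backend {backend.name!r}: invalid score direction")
    BACKEND_REGISTRY[backend.name] = backend


def get_backend(name: str):
    try:
        return BACKEND_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown backend {name!r}; registered backends: {sorted(BACKEND_REGISTRY)}"
        ) from None


register_backend(SyntheticBackend())
# external engines: contract-only adapters, direction per engine convention
for _name, _direction in (
    ("vina", LOWER),
    ("glide", LOWER),
    ("hybrid", LOWER),
    ("rdock", LOWER),
    ("gold", HIGHER),  # GOLD reports a fitness where higher is better
):
    register_backend(AdapterStub(name=_name, score_direction=_direction))


# ---------------------------------------------------------------------------
# batch dispatch
# ---------------------------------------------------------------------------


def _dock_chunk(backend, receptor, chunk: list[Enumeration]):
    poses: list[PoseRecord] = []
    failures: list[DockingFailure] = []
    for enum in chunk:
        if enum.failed:
            failures.append(
                DockingFailure(enum.ligand_id, enum.enumeration_index,
                               enum.failure_reason or "upstream failure")
            )
            continue
        if not enum.has_coordinates and not getattr(backend, "embeds_internally", False):
            failures.append(
                DockingFailure(enum.ligand_id, enum.enumeration_index, "no 3D coordinates")
            )
            continue
        try:
            result = backend.dock(enum, receptor)
        except Exception as exc:  # per-enumeration failure must not abort the batch
            failures.append(DockingFailure(enum.ligand_id, enum.enumeration_index, str(exc)))
            continue
        capped = result[: getattr(backend, "max_poses", len(result))]
        for k, pose in enumerate(capped):
            pose.pose_index = k
        poses.extend(capped)
    return poses, failures


def dock_batch(
    enumerations: list[Enumeration],
    receptor: ReceptorProfile,
    backend,
    cores: int = 1,
    max_per_core: int = 8,
    ligand_names: dict[str, str] | None = None,
) -> DockingReport:
    """Dock a batch of embedded enumerations, in parallel if requested.

    Work is chunked ``max_per_core`` enumerations per task across a process
    pool of ``cores`` workers; results are re-sorted by
    ``(ligand_id, enumeration_index)`` so output is identical for any core
    count or scheduling order. Every input enumeration ends up in exactly one
    of poses or failures.
    """
    if isinstance(backend, str):
        backend = get_backend(backend)
    if cores < 1 or max_per_core < 1:
        raise ValueError("cores and max_per_core must be >= 1")
    chunks = [enumerations[i: i + max_per_core] for i in range(0, len(enumerations), max_per_core)]
    if cores == 1 or len(chunks) <= 1:
        results = [_dock_chunk(backend, receptor, c) for c in chunks]
    else:
        results = Parallel(n_jobs=cores)(
            delayed(_dock_chunk)(backend, receptor, c) for c in chunks
        )
    report = DockingReport(
        backend=backend.name,
        direction=backend.score_direction,
        receptor_id=receptor.identifier,
        ligand_names=dict(ligand_names or {}),
    )
    for poses, failures in results:
        report.poses.extend(poses)
        report.failures.extend(failures)
    report.poses.sort(key=lambda p: (p.ligand_id, p.enumeration_index, p.pose_index))
    report.failures.sort(key=lambda f: (f.ligand_id, f.enumeration_index))
    return report


# ---------------------------------------------------------------------------
# write-out
# ---------------------------------------------------------------------------


def _pose_frame(report: DockingReport) -> pd.DataFrame:
    rows = [
        {
            "ligand_id": p.ligand_id,
            "name": report.ligand_names.get(p.ligand_id, ""),
            "enumeration_index": p.enumeration_index,
            "pose_index": p.pose_index,
            "score": p.score,
            "backend": report.backend,
            "direction": report.direction,
        }
        for p in report.poses
    ]
    cols = ["ligand_id", "name", "enumeration_index", "pose_index", "score",
            "backend", "direction"]
    return pd.DataFrame(rows, columns=cols)


def collate_writeout(report: DockingReport, mode: str = "best_per_ligand") -> pd.DataFrame:
    """Reduce pose records to a score table under the given write-out mode.

    "Best" honours the backend's score direction (min for lower-better
    engines, max for higher-better fitness); ties break deterministically on
    ascending (enumeration_index, pose_index).
    """
    if mode not in WRITE_OUT_MODES:
        raise ValueError(f"unknown write_out_mode {mode!r}; expected one of {WRITE_OUT_MODES}")
    df = _pose_frame(report)
    if mode == "all" or df.empty:
        return df.reset_index(drop=True)
    ascending = report.direction == LOWER
    df = df.sort_values(
        ["score", "enumeration_index", "pose_index"],
        ascending=[ascending, True, True],
        kind="mergesort",
    )
    group_cols = ["ligand_id"] if mode == "best_per_ligand" else ["ligand_id",
                                                                  "enumeration_index"]
    best = df.groupby(group_cols, as_index=False, sort=True).head(1)
    return best.sort_values(["ligand_id", "enumeration_index"]).reset_index(drop=True)


def write_scores_csv(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def write_poses_sdf(report: DockingReport, table: pd.DataFrame, path: str | Path) -> None:
    """Write the poses selected by a write-out table as a V2000 SDF.

    Each record carries the docking score and provenance in SDF tags. Poses
    without coordinates (backends that return scores only) are skipped.
    """
    selected = {(r.ligand_id, r.enumeration_index, r.pose_index) for r in table.itertuples()}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    writer = Chem.SDWriter(str(path))
    for pose in report.poses:
        if (pose.ligand_id, pose.enumeration_index, pose.pose_index) not in selected:
            continue
        if pose.smiles is None or pose.coordinates is None:
            continue
        mol = Chem.AddHs(Chem.MolFromSmiles(pose.smiles))
        if mol.GetNumAtoms() != len(pose.coordinates):
            continue
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y, z) in enumerate(pose.coordinates):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        mol.AddConformer(conf, assignId=True)
        mol.SetProp("_Name", f"{pose.ligand_id}:{pose.enumeration_index}:{pose.pose_index}")
        mol.SetProp("score", f"{pose.score:.6f}")
        mol.SetProp("backend", report.backend)
        writer.write(mol)
    writer.close()
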