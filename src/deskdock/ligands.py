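"""Compound representation, state enumeration, 3D embedding, and file I/O.

A docking run starts from flat compound input (SMILES or SDF). Each input
compound (``Ligand``) is expanded into one or more ``Enumeration`` records —
specific tautomer / stereoisomer states — because a docking engine scores a
concrete molecular state, not the abstract compound. States then receive 3D
coordinates from an embedder before docking.

Failures (unparsable SMILES, embedding failures) are carried as flagged
records through the pipeline rather than dropped, so that per-run failure
counts can be reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # RDKit's own stderr chatter; failures are flagged instead

DEFAULT_MAX_STATES = 32


def canonical_smiles(smiles: str) -> str | None:
    """Canonical isomeric SMILES, or None if the input does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


@dataclass
class EmbedderSpec:
    """Parameters for the built-in conformer generator.

    ``max_iterations`` bounds the force-field minimization (default 600);
    ``force_field`` selects MMFF94 with a UFF fallback for atom types MMFF
    does not cover; ``seed`` fixes the distance-geometry embedding so repeated
    runs give identical coordinates.
    """

    name: str = "rdkit"
    max_iterations: int = 600
    force_field: str = "MMFF94"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class Enumeration:
    """One concrete tautomer/stereoisomer state of a parent ligand."""

    ligand_id: str
    enumeration_index: int
    smiles: str
    elements: list[str] | None = None
    coordinates: np.ndarray | None = None  # (n_atoms, 3) in Angstrom, H included
    embedder: str | None = None
    embed_seed: int | None = None
    converged: bool | None = None
    failed: bool = False
    failure_reason: str | None = None

    @property
    def has_coordinates(self) -> bool:
        return self.coordinates is not None


@dataclass
class Ligand:
    """An input compound and its enumerated states."""

    ligand_id: str
    input_smiles: str
    name: str | None = None
    enumerations: list[Enumeration] = field(default_factory=list)
    truncated: bool = False  # enumeration hit the max_states cap
    failed: bool = False
    failure_reason: str | None = None


# ---------------------------------------------------------------------------
# state enumeration
# ---------------------------------------------------------------------------


def enumerate_states(
    ligand: Ligand,
    enumerate_stereo: bool = True,
    enumerate_tautomers: bool = False,
    max_states: int = DEFAULT_MAX_STATES,
) -> Ligand:
    """Populate ``ligand.enumerations`` with its distinct molecular states.

    Stereo enumeration expands only *unassigned* stereocentres, so specified
    stereochemistry in the input is preserved; a molecule with k unassigned
    centres and no tautomeric groups yields min(2**k, max_states) states.
    Tautomers come from a rule-based enumerator. States are deduplicated on
    canonical SMILES and ordered lexicographically, which makes the expansion
    deterministic and idempotent. Hitting the cap sets ``ligand.truncated``.

    An unparsable input marks the ligand failed (with reason) and returns it;
    nothing is raised, so a bad compound cannot abort a batch.
    """
    if max_states < 1:
        raise ValueError("max_states must be >= 1")
    mol = Chem.MolFromSmiles(ligand.input_smiles)
    if mol is None:
        ligand.failed = True
        ligand.failure_reason = f"unparsable SMILES: {ligand.input_smiles!r}"
        ligand.enumerations = []
        return ligand

    states = [mol]
    if enumerate_stereo:
        opts = StereoEnumerationOptions(onlyUnassigned=True, unique=True)
        states = [iso for m in states for iso in EnumerateStereoisomers(m, options=opts)]
    if enumerate_tautomers:
        enumerator = rdMolStandardize.TautomerEnumerator()
        states = [t for m in states for t in enumerator.Enumerate(m)]

    smiles_set = sorted({Chem.MolToSmiles(m) for m in states})
    if len(smiles_set) > max_states:
        smiles_set = smiles_set[:max_states]
        ligand.truncated = True
    ligand.enumerations = [
        Enumeration(ligand_id=ligand.ligand_id, enumeration_index=i, smiles=smi)
        for i, smi in enumerate(smiles_set)
    ]
    ligand.failed = False
    ligand.failure_reason = None
    return ligand


# ---------------------------------------------------------------------------
# 3D embedding
# ---------------------------------------------------------------------------


def embed_3d(enumeration: Enumeration, spec: EmbedderSpec | None = None) -> Enumeration:
    """Generate 3D coordinates for one enumeration.

    Distance-geometry embedding (ETKDGv3) with the spec's fixed seed, followed
    by force-field minimization capped at ``spec.max_iterations``. The
    ``converged`` flag records whether the minimizer finished within the cap;
    coordinates are kept (and are finite) either way. Embedding failure flags
    the enumeration failed instead of raising.
    """
    spec = spec or EmbedderSpec()
    mol = Chem.MolFromSmiles(enumeration.smiles)
    if mol is None:
        enumeration.failed = True
        enumeration.failure_reason = f"unparsable SMILES: {enumeration.smiles!r}"
        return enumeration
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = spec.seed
    conf_id = AllChem.EmbedMolecule(mol, params)
    if conf_id < 0:
        enumeration.failed = True
        enumeration.failure_reason = "distance-geometry embedding failed"
        return enumeration

    converged = True
    try:
        if spec.force_field.upper().startswith("MMFF") and AllChem.MMFFHasAllMoleculeParams(mol):
            rc = AllChem.MMFFOptimizeMolecule(mol, maxIters=spec.max_iterations)
        else:
            rc = AllChem.UFFOptimizeMolecule(mol, maxIters=spec.max_iterations)
        converged = rc == 0  # 1 = iteration cap hit before convergence
    except Exception:
        converged = False

    conf = mol.GetConformer()
    xyz = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    if not np.all(np.isfinite(xyz)):
        enumeration.failed = True
        enumeration.failure_reason = "non-finite coordinates from minimization"
        return enumeration
    enumeration.elements = [a.GetSymbol() for a in mol.GetAtoms()]
    enumeration.coordinates = xyz
    enumeration.embedder = spec.name
    enumeration.embed_seed = spec.seed
    enumeration.converged = converged
    enumeration.failed = False
    enumeration.failure_reason = None
    return enumeration


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

SMILES_FORMAT = "SMILES"
SDF_FORMAT = "SDF"


def read_ligands(path: str | Path, fmt: str = SMILES_FORMAT) -> list[Ligand]:
    """Read ligands from a SMILES flat file or an SDF.

    SMILES files are whitespace-separated ``SMILES [name]`` lines. Records
    that fail to parse are skipped with a logged count, never fatal. Ligand
    ids are taken from the record name when present and unique, otherwise
    assigned positionally (``L0``, ``L1``, ...).
    """
    path = Path(path)
    fmt = fmt.upper()
    records: list[tuple[str, str | None]] = []  # (smiles, name)
    n_bad = 0
    if fmt == SMILES_FORMAT:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            name = parts[1].strip() if len(parts) > 1 else None
            if canonical_smiles(smi) is None:
                n_bad += 1
                continue
            records.append((smi, name))
    elif fmt == SDF_FORMAT:
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for mol in supplier:
            if mol is None:
                n_bad += 1
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
            records.append((Chem.MolToSmiles(mol), name or None))
    else:
        raise ValueError(f"unknown ligand format {fmt!r}; expected SMILES or SDF")

    if n_bad:
        logger.warning("%s: skipped %d unparsable record(s)", path, n_bad)

    names = [name for _, name in records]
    use_names = all(names) and len(set(names)) == len(names)
    ligands = []
    for i, (smi, name) in enumerate(records):
        ligand_id = name if use_names else f"L{i}"
        ligands.append(Ligand(ligand_id=ligand_id, input_smiles=smi, name=name))
    return ligands


def write_ligands(ligands: list[Ligand], path: str | Path, fmt: str = SMILES_FORMAT) -> None:
    """Write ligands to a SMILES flat file or a V2000 SDF.

    Reading the output back preserves ligand count, ids and canonical SMILES.
    SDF records carry embedded 3D coordinates when the first enumeration has
    them, 2D depiction coordinates otherwise. Failed ligands are skipped.
    """
    path = Path(path)
    fmt = fmt.upper()
    if fmt == SMILES_FORMAT:
        lines = []
        for lig in ligands:
            if lig.failed:
                continue
            smi = canonical_smiles(lig.input_smiles)
            lines.append(f"{smi} {lig.ligand_id}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == SDF_FORMAT:
        writer = Chem.SDWriter(str(path))
        writer.SetForceV3000(False)
        for lig in ligands:
            if lig.failed:
                continue
            embedded = next(
                (e for e in lig.enumerations if e.has_coordinates and not e.failed), None
            )
            if embedded is not None:
                mol = Chem.AddHs(Chem.MolFromSmiles(embedded.smiles))
                conf = Chem.Conformer(mol.GetNumAtoms())
                for i, (x, y, z) in enumerate(embedded.coordinates):
                    conf.SetAtomPosition(i, (float(x), float(y), float(z)))
                mol.AddConformer(conf, assignId=True)
            else:
                mol = Chem.MolFromSmiles(lig.input_smiles)
                AllChem.Compute2DCoords(mol)
            mol.SetProp("_Name", lig.ligand_id)
            if lig.name:
                mol.SetProp("name", lig.name)
            writer.write(mol)
        writer.close()
    else:
        raise ValueError(f"unknown ligand format {fmt!r}; expected SMILES or SDF")


def write_failure_report(ligands: list[Ligand], path: str | Path) -> None:
    """CSV of per-record failures: ligand_id, stage, reason."""
    import csv

    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ligand_id", "stage", "reason"])
        for lig in ligands:
            if lig.failed:
                writer.writerow([lig.ligand_id, "enumeration", lig.failure_reason])
            for enum in lig.enumerations:
                if enum.failed:
                    writer.writerow(
                        [f"{lig.ligand_id}:{enum.enumeration_index}", "embedding",
                         enum.failure_reason]
                    )
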