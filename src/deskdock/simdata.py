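"""Epoch-similarity analytics and synthetic test fixtures.

Two halves:

1. **Batch similarity over a generative run.** An RL agent proposes a batch
   of molecules per epoch; the average linkage similarity between two epochs,

       L(e1, e2) = (1 / (N1 N2)) Σ_i Σ_j T(x_{e1,i}, x_{e2,j}),

   is the mean pairwise Tanimoto over circular fingerprints across the two
   batches. Sampling every ``stride`` epochs gives a square similarity matrix
   whose drift toward high values traces the agent's transition from
   exploration to exploitation. No within-batch deduplication is applied, so
   the diagonal measures intra-batch self-similarity (1.0 for a batch of one
   repeated molecule).

2. **Synthetic screens and toy libraries.** Labelled active/decoy score sets
   with a planted enrichment shift (emulating a 40-active / 1200-decoy
   benchmark target composition), and a deterministic fragment-grammar SMILES
   library, so every pipeline stage is testable without any external dataset
   or docking engine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator

from .analysis import ACTIVE, DECOY, DIRECTIONS, LOWER, LabeledScores


# ---------------------------------------------------------------------------
# epoch similarity
# ---------------------------------------------------------------------------


@dataclass
class FingerprintSpec:
    """Circular (Morgan) fingerprint parameters: radius 3, 1024 bits default."""

    radius: int = 3
    bits: int = 1024

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.bits < 1 or (self.bits & (self.bits - 1)) != 0:
            raise ValueError("bits must be a power of two")

    def generator(self):
        return rdFingerprintGenerator.GetMorganGenerator(radius=self.radius, fpSize=self.bits)


@dataclass
class EpochBatch:
    """The molecules proposed in one RL epoch (1-based epoch index)."""

    epoch: int
    smiles: list[str]

    def __post_init__(self) -> None:
        if self.epoch < 1:
            raise ValueError("epoch index is 1-based")
        if not self.smiles:
            raise ValueError("an epoch batch must contain at least one molecule")


def _batch_fingerprints(batch: EpochBatch, spec: FingerprintSpec, cache: dict):
    gen = None
    fps = []
    for smi in batch.smiles:
        if smi not in cache:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"invalid SMILES in epoch {batch.epoch}: {smi!r}")
            if gen is None:
                gen = spec.generator()
            cache[smi] = gen.GetFingerprint(mol)
        fps.append(cache[smi])
    return fps


def average_linkage(
    b1: EpochBatch,
    b2: EpochBatch,
    fp: FingerprintSpec | None = None,
    _cache: dict | None = None,
) -> float:
    """Mean pairwise Tanimoto similarity between all molecule pairs of two
    batches; symmetric, bounded in [0, 1], and 1 for identical
    single-molecule batches."""
    fp = fp or FingerprintSpec()
    cache = _cache if _cache is not None else {}
    fps1 = _batch_fingerprints(b1, fp, cache)
    fps2 = _batch_fingerprints(b2, fp, cache)
    total = 0.0
    for f1 in fps1:
        total += sum(DataStructs.BulkTanimotoSimilarity(f1, fps2))
    return total / (len(fps1) * len(fps2))


@dataclass
class SimilarityMatrix:
    epochs: list[int]  # sampled epoch indices
    values: np.ndarray  # square, symmetric, in [0, 1]
    stride: int

    def to_csv(self, path: str | Path) -> None:
        labels = [f"epoch_{e}" for e in self.epochs]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)


def similarity_matrix(
    batches: list[EpochBatch], stride: int = 5, fp: FingerprintSpec | None = None
) -> SimilarityMatrix:
    """Average-linkage similarity between every pair of sampled epochs.

    Every ``stride``-th batch is sampled (cutting an E-epoch run down to
    ceil(E / stride) rows, e.g. 1000 epochs at stride 5 give a 200 x 200
    matrix). The diagonal holds the intra-batch average similarity.
    Fingerprints are computed once per distinct molecule.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not batches:
        raise ValueError("at least one epoch batch is required")
    epochs = [b.epoch for b in batches]
    if any(e2 <= e1 for e1, e2 in zip(epochs, epochs[1:])):
        raise ValueError("epoch indices must be strictly increasing")
    fp = fp or FingerprintSpec()
    sampled = batches[::stride]
    cache: dict = {}
    fps = [_batch_fingerprints(b, fp, cache) for b in sampled]
    m = len(sampled)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            total = 0.0
            for f1 in fps[i]:
                total += sum(DataStructs.BulkTanimotoSimilarity(f1, fps[j]))
            values[i, j] = values[j, i] = total / (len(fps[i]) * len(fps[j]))
    return SimilarityMatrix(epochs=[b.epoch for b in sampled], values=values, stride=stride)


# ---------------------------------------------------------------------------
# synthetic screens
# ---------------------------------------------------------------------------

BASELINES = ("gaussian", "uniform", "heavy_tailed")


@dataclass
class SyntheticScreenSpec:
    """Parameters of a planted-enrichment active/decoy score set.

    Decoy scores follow the baseline distribution; active scores are shifted
    ``delta`` noise units toward "better" per the score direction, so
    ``delta = 0`` is an uninformative screen and larger ``delta`` plants
    stronger enrichment. Default composition mirrors a standard benchmark
    target: 40 actives vs 1200 decoys. The seed is mandatory — every screen
    is reproducible.
    """

    seed: int
    n_actives: int = 40
    n_decoys: int = 1200
    delta: float = 0.0
    noise_scale: float = 1.0
    direction: str = LOWER
    baseline: str = "gaussian"
    baseline_loc: float = -7.0  # docking-score-like centre for the gaussian baseline

    def __post_init__(self) -> None:
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ValueError("counts must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.baseline not in BASELINES:
            raise ValueError(f"unknown baseline {self.baseline!r}; expected {BASELINES}")


def generate_screen(spec: SyntheticScreenSpec) -> LabeledScores:
    """Draw one labelled screen from the spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_actives + spec.n_decoys
    if spec.baseline == "gaussian":
        base = rng.normal(spec.baseline_loc, spec.noise_scale, size=n)
    elif spec.baseline == "uniform":
        base = rng.uniform(0.0, 1.0, size=n) * spec.noise_scale
    else:  # heavy_tailed: Student t with 3 dof, stresses the FPR clipping policy
        base = spec.baseline_loc + rng.standard_t(3, size=n) * spec.noise_scale
    shift = spec.delta * spec.noise_scale
    signed = -shift if spec.direction == LOWER else shift
    scores = base.copy()
    scores[: spec.n_actives] += signed
    ids = [f"A{i}" for i in range(spec.n_actives)] + [f"D{i}" for i in range(spec.n_decoys)]
    labels = [ACTIVE] * spec.n_actives + [DECOY] * spec.n_decoys
    return LabeledScores(ligand_ids=ids, scores=scores, labels=labels, direction=spec.direction)


def write_screen_csv(data: LabeledScores, path: str | Path) -> None:
    pd.DataFrame(
        {"ligand_id": data.ligand_ids, "score": data.scores, "label": data.labels}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# toy SMILES library
# ---------------------------------------------------------------------------

# fragment grammar: cores carry one or two substitution slots filled from a
# fixed decoration set; every combination is RDKit-validated before use
_CORES_ONE = (
    "{R1}c1ccccc1",
    "{R1}c1ccncc1",
    "{R1}c1cccs1",
    "{R1}c1ccco1",
    "{R1}C1CCCCC1",
    "{R1}C1CCNCC1",
    "{R1}c1ccc2ccccc2c1",
    "{R1}c1cncnc1",
)
_CORES_TWO = (
    "{R1}c1ccc({R2})cc1",
    "{R1}c1ccc(C{R2})cc1",
    "{R1}c1ccc(O{R2})cc1",
    "{R1}c1ccc(N{R2})cc1",
    "{R1}c1ccc(-c2ccc({R2})cc2)cc1",
    "{R1}c1ccc(-c2ccc({R2})s2)cc1",
    "{R1}c1ccc(C(=O)N{R2})cc1",
    "{R1}C1CCN({R2})CC1",
)
_DECORATIONS = (
    "C", "CC", "CCC", "O", "OC", "N", "NC", "F", "Cl", "Br",
    "C(F)(F)F", "C(=O)O", "C(=O)N", "C#N", "CO", "CN(C)C",
)


def _grammar_space() -> list[str]:
    combos = [t.format(R1=r1) for t in _CORES_ONE for r1 in _DECORATIONS]
    combos += [
        t.format(R1=r1, R2=r2)
        for t in _CORES_TWO
        for r1, r2 in itertools.product(_DECORATIONS, repeat=2)
    ]
    return combos


_VALID_LIBRARY: list[str] | None = None


def _valid_library() -> list[str]:
    global _VALID_LIBRARY
    if _VALID_LIBRARY is None:
        seen: set[str] = set()
        out: list[str] = []
        for smi in _grammar_space():
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            can = Chem.MolToSmiles(mol)
            if can not in seen:
                seen.add(can)
                out.append(can)
        _VALID_LIBRARY = out
    return _VALID_LIBRARY


def generate_toy_library(n: int, seed: int = 0) -> list[str]:
    """n distinct, valid, drug-like-ish SMILES from the fragment grammar.

    Deterministic per seed (a seeded shuffle of the enumerated, validated,
    canonicalized grammar space). Raises if n exceeds the grammar space.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = list(_valid_library())
    if n > len(pool):
        raise ValueError(f"toy grammar holds only {len(pool)} distinct molecules (asked {n})")
    rng = np.random.default_rng(seed)
    rng.shuffle(pool)
    return pool[:n]


def write_smiles_file(smiles: list[str], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{smi} T{i}" for i, smi in enumerate(smiles)) + "\n"
    )
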