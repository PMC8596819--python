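"""Generative-chemistry scoring: transforms, MPO aggregation, diversity filter.

A generative agent optimizing molecules against docking needs every raw
property (docking score, molecular weight, H-bond donor count, ...) mapped
onto a common [0, 1] desirability scale and aggregated into a single reward.
This module provides:

* monotone transformation functions P(raw) ∈ [0, 1] (sigmoid families for
  soft preferences, linear ramps, range steps);
* the total score S(x) = (Π P_i^{w_i})^{1 / Σ w_i}, a weighted geometric
  mean — any property at zero annihilates the reward, so every property must
  be reasonably satisfied;
* a scaffold-keyed diversity filter that penalizes an agent once a generic
  scaffold's bucket is saturated, preventing mode collapse;
* an agent-agnostic reinforcement-learning step harness (plus a hill-climbing
  toy proposer) that exercises the scoring/docking interface the way an RL
  agent does, one proposal batch per epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs, Descriptors, Lipinski, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .docking import ReceptorProfile, physchem_descriptors

TRANSFORM_KINDS = ("sigmoid", "reverse_sigmoid", "linear_clip", "step")

ACYCLIC_KEY = "<acyclic>"


# ---------------------------------------------------------------------------
# transformation functions
# ---------------------------------------------------------------------------


@dataclass
class TransformSpec:
    """A monotone (or range) map from a raw property value to [0, 1].

    ``low`` and ``high`` anchor the interesting range of the raw value.
    For the sigmoid kinds the midpoint maps to 0.5 and steepness ``k``
    controls how sharply the anchors approach 0/1 (at the default k = 5 the
    anchors map to ~0.007 / ~0.993). ``reverse_sigmoid`` decreases in the raw
    value and is the natural choice for lower-is-better docking scores;
    ``linear_clip`` ramps linearly from 0 at ``low`` to 1 at ``high``;
    ``step`` is the indicator of the closed range [low, high].
    """

    kind: str = "reverse_sigmoid"
    low: float = -12.0
    high: float = -4.0
    k: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}; expected {TRANSFORM_KINDS}")
        if not self.low < self.high:
            raise ValueError("transform anchors must satisfy low < high")
        if not self.k > 0:
            raise ValueError("steepness k must be > 0")


def apply_transform(raw: float, spec: TransformSpec) -> float:
    """Evaluate the transform; non-finite raw (failed docking) maps to 0.0."""
    if raw is None or not math.isfinite(raw):
        return 0.0
    mid = 0.5 * (spec.low + spec.high)
    half = 0.5 * (spec.high - spec.low)
    if spec.kind == "sigmoid":
        p = 1.0 / (1.0 + math.exp(-spec.k * (raw - mid) / half))
    elif spec.kind == "reverse_sigmoid":
        p = 1.0 / (1.0 + math.exp(spec.k * (raw - mid) / half))
    elif spec.kind == "linear_clip":
        p = (raw - spec.low) / (spec.high - spec.low)
    else:  # step
        p = 1.0 if spec.low <= raw <= spec.high else 0.0
    return float(min(1.0, max(0.0, p)))


# ---------------------------------------------------------------------------
# components and the weighted geometric mean
# ---------------------------------------------------------------------------


def molecular_weight_provider(mol: Chem.Mol) -> float:
    return Descriptors.MolWt(mol)


def hbd_provider(mol: Chem.Mol) -> float:
    return float(Lipinski.NumHDonors(mol))


def synthetic_docking_provider(
    receptor: ReceptorProfile,
) -> Callable[[Chem.Mol], float]:
    """Raw-score provider backed by the synthetic docking engine.

    The synthetic engine's score is a pure function of the molecule's
    descriptor vector, so the provider evaluates it directly — no conformer
    generation is needed to obtain the score an agent would be rewarded with.
    """
    if receptor.target is None:
        raise ValueError("receptor carries no synthetic payload")

    def provider(mol: Chem.Mol) -> float:
        d = physchem_descriptors(Chem.MolToSmiles(mol))
        from .docking import DESCRIPTOR_SCALES

        sim = np.exp(-np.abs(d - receptor.target) / DESCRIPTOR_SCALES)
        return float(-(receptor.weights @ sim))

    return provider


BUILTIN_PROVIDERS: dict[str, Callable[[Chem.Mol], float]] = {
    "molecular_weight": molecular_weight_provider,
    "hbd": hbd_provider,
}


@dataclass
class ComponentSpec:
    """One property in the multi-parameter objective.

    ``provider`` maps an RDKit Mol to the raw property value (a builtin name,
    a docking provider, or any external descriptor hook such as a published
    drug-likeness score); ``transform`` normalizes it; ``weight`` sets its
    relative importance (all-equal weights reduce S(x) to the plain geometric
    mean).
    """

    name: str
    transform: TransformSpec
    provider: Callable[[Chem.Mol], float] | str = "molecular_weight"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("component weight must be >= 0")
        if isinstance(self.provider, str):
            if self.provider not in BUILTIN_PROVIDERS:
                raise ValueError(
                    f"unknown builtin provider {self.provider!r}; "
                    f"expected one of {sorted(BUILTIN_PROVIDERS)}"
                )
            self.provider = BUILTIN_PROVIDERS[self.provider]


@dataclass
class MpoResult:
    total: float
    raw: dict[str, float]
    transformed: dict[str, float]
    valid: bool = True
    reason: str | None = None


def total_score(components: Sequence[ComponentSpec], molecule: str | Chem.Mol) -> MpoResult:
    """Weighted-geometric-mean aggregation of the component desirabilities.

    S(x) = (Π_i P_i(x)^{w_i})^{1/Σ_i w_i} ∈ [0, 1]. Any component at zero
    (including a failed provider, which yields a non-finite raw value) drives
    the total to zero. An unparsable molecule scores 0 with a reason.
    """
    if not components:
        raise ValueError("at least one scoring component is required")
    total_weight = sum(c.weight for c in components)
    if total_weight <= 0:
        raise ValueError("sum of component weights must be positive")
    mol = Chem.MolFromSmiles(molecule) if isinstance(molecule, str) else molecule
    if mol is None:
        return MpoResult(total=0.0, raw={}, transformed={}, valid=False,
                         reason="unparsable SMILES")
    raws: dict[str, float] = {}
    ps: dict[str, float] = {}
    log_sum = 0.0
    zero = False
    for comp in components:
        try:
            raw = float(comp.provider(mol))
        except Exception:
            raw = math.nan
        p = apply_transform(raw, comp.transform)
        raws[comp.name] = raw
        ps[comp.name] = p
        if p == 0.0 and comp.weight > 0:
            zero = True
        elif p > 0.0:
            log_sum += comp.weight * math.log(p)
    total = 0.0 if zero else math.exp(log_sum / total_weight)
    return MpoResult(total=float(min(1.0, max(0.0, total))), raw=raws, transformed=ps)


# ---------------------------------------------------------------------------
# diversity filter
# ---------------------------------------------------------------------------


def generic_scaffold(smiles: str) -> str:
    """Generic (topological) scaffold key of a molecule.

    The Bemis–Murcko framework with every atom turned into carbon and every
    bond into a single bond, canonicalized — insensitive to decorations and
    heteroatoms, so benzene, pyridine, toluene and phenol all share one key.
    Ring-free molecules have an empty framework and map to a designated
    acyclic key.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ACYCLIC_KEY
    generic = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    return Chem.MolToSmiles(generic)


@dataclass
class ScaffoldBucketStore:
    """Memory of generified scaffolds already exploited by the agent.

    Compounds whose total score passes ``min_score`` fill their scaffold's
    bucket (capacity ``bucket_size``, default 25). Once a bucket is full,
    further compounds matching that scaffold are penalized to score 0 —
    permanently — pushing the agent toward unexplored chemical space. Exact
    SMILES duplicates of stored compounds are always penalized.
    ``similarity_threshold`` = 1.0 means exact generic-scaffold key match;
    values below 1.0 additionally penalize compounds whose scaffold
    fingerprint Tanimoto to a saturated scaffold reaches the threshold.
    """

    bucket_size: int = 25
    min_score: float = 0.4
    similarity_threshold: float = 1.0
    buckets: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    _stored_smiles: set[str] = field(default_factory=set)
    _fp_gen: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.bucket_size < 1:
            raise ValueError("bucket_size must be >= 1")
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must be in (0, 1]")

    def occupancy(self, key: str) -> int:
        return len(self.buckets.get(key, []))

    def _scaffold_fp(self, key: str):
        if self._fp_gen is None:
            self._fp_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        mol = Chem.MolFromSmiles(key) if key != ACYCLIC_KEY else Chem.MolFromSmiles("C")
        return self._fp_gen.GetFingerprint(mol)

    def _matches_saturated(self, key: str) -> bool:
        if self.occupancy(key) >= self.bucket_size:
            return True
        if self.similarity_threshold >= 1.0:
            return False
        fp = self._scaffold_fp(key)
        for other, entries in self.buckets.items():
            if len(entries) >= self.bucket_size and other != key:
                if DataStructs.TanimotoSimilarity(fp, self._scaffold_fp(other)) >= \
                        self.similarity_threshold:
                    return True
        return False

    def score_and_update(self, smiles: str, total: float) -> float:
        """Apply the saturation rule to one proposed compound; returns the
        adjusted total score and updates the store in place."""
        can = Chem.MolFromSmiles(smiles)
        if can is None:
            return 0.0
        can_smiles = Chem.MolToSmiles(can)
        if can_smiles in self._stored_smiles:
            return 0.0  # repeat proposal of a stored compound
        if total < self.min_score:
            return total  # not good enough to occupy a bucket; no penalty either
        key = generic_scaffold(can_smiles)
        if self._matches_saturated(key):
            return 0.0
        self.buckets.setdefault(key, []).append((can_smiles, total))
        self._stored_smiles.add(can_smiles)
        return total


def diversity_penalty(
    smiles: str, total: MpoResult | float, store: ScaffoldBucketStore
) -> tuple[float, ScaffoldBucketStore]:
    """Functional wrapper over ``ScaffoldBucketStore.score_and_update``."""
    value = total.total if isinstance(total, MpoResult) else float(total)
    return store.score_and_update(smiles, value), store


# ---------------------------------------------------------------------------
# RL step harness
# ---------------------------------------------------------------------------


@dataclass
class EpochRecord:
    epoch: int
    n_proposed: int
    mean_total: float
    max_total: float
    mean_adjusted: float
    mean_raw_docking: float
    unique_passing: int  # cumulative unique canonical SMILES above threshold


class HillClimbProposer:
    """Toy proposer: epsilon-greedy hill climbing over a fixed library.

    Keeps the best-scoring compounds seen so far and proposes unseen library
    members closest to them in descriptor space, mixed with random
    exploration. Deterministic for a fixed seed. Stands in for a generative
    agent in tests; it never repeats a proposal, so exhaustion of the library
    ends the run cleanly.
    """

    def __init__(self, library: Sequence[str], seed: int = 0, explore_fraction: float = 0.5,
                 n_elite: int = 5):
        self.library = list(library)
        self.rng = np.random.default_rng(seed)
        self.explore_fraction = explore_fraction
        self.n_elite = n_elite
        self.descriptors = np.array([physchem_descriptors(s) for s in self.library])
        self.unseen = list(range(len(self.library)))
        self.fitness: dict[int, float] = {}

    def propose(self, batch_size: int) -> list[str]:
        if not self.unseen:
            return []
        n = min(batch_size, len(self.unseen))
        elite = sorted(self.fitness, key=self.fitness.get, reverse=True)[: self.n_elite]
        n_explore = n if not elite else max(1, int(round(n * self.explore_fraction)))
        picks: list[int] = list(
            self.rng.choice(len(self.unseen), size=n_explore, replace=False)
        )
        if elite and n_explore < n:
            elite_desc = self.descriptors[elite]
            remaining = [k for k in range(len(self.unseen)) if k not in set(picks)]
            cand_desc = self.descriptors[[self.unseen[k] for k in remaining]]
            dists = np.linalg.norm(
                cand_desc[:, None, :] - elite_desc[None, :, :], axis=2
            ).min(axis=1)
            order = np.argsort(dists, kind="stable")[: n - n_explore]
            picks.extend(remaining[k] for k in order)
        chosen = sorted({int(k) for k in picks}, reverse=True)
        indices = [self.unseen[k] for k in chosen]
        batch = [self.library[i] for i in indices]
        for k in chosen:
            del self.unseen[k]
        self._pending = indices
        return batch

    def update(self, smiles: Sequence[str], fitness: Sequence[float]) -> None:
        for idx, fit in zip(getattr(self, "_pending", []), fitness):
            self.fitness[idx] = float(fit)


def rl_step_harness(
    proposer,
    components: Sequence[ComponentSpec],
    store: ScaffoldBucketStore | None = None,
    epochs: int = 50,
    batch_size: int = 128,
    score_threshold: float = 0.4,
    docking_component: str = "docking",
) -> list[EpochRecord]:
    """Run the propose → score → filter → feedback loop for some epochs.

    Per epoch the proposer emits a batch, every compound gets its MPO total
    S(x), the diversity filter adjusts it, and the adjusted scores are fed
    back to the proposer (if it exposes ``update``). Records per epoch the
    mean/max total, mean adjusted total, the mean raw value of the component
    named ``docking_component`` (NaN if absent), and the cumulative number of
    unique compounds whose adjusted score passes ``score_threshold``. A
    proposer returning an empty batch stops the run cleanly.
    """
    store = store if store is not None else ScaffoldBucketStore()
    records: list[EpochRecord] = []
    unique_passing: set[str] = set()
    for epoch in range(1, epochs + 1):
        batch = proposer.propose(batch_size)
        if not batch:
            break
        totals, adjusted, raws = [], [], []
        for smi in batch:
            result = total_score(components, smi)
            adj = store.score_and_update(smi, result.total)
            totals.append(result.total)
            adjusted.append(adj)
            raws.append(result.raw.get(docking_component, math.nan))
            if adj >= score_threshold:
                mol = Chem.MolFromSmiles(smi)
                if mol is not None:
                    unique_passing.add(Chem.MolToSmiles(mol))
        if hasattr(proposer, "update"):
            proposer.update(batch, adjusted)
        finite_raws = [r for r in raws if math.isfinite(r)]
        records.append(
            EpochRecord(
                epoch=epoch,
                n_proposed=len(batch),
                mean_total=float(np.mean(totals)),
                max_total=float(np.max(totals)),
                mean_adjusted=float(np.mean(adjusted)),
                mean_raw_docking=float(np.mean(finite_raws)) if finite_raws else math.nan,
                unique_passing=len(unique_passing),
            )
        )
    return records


def epoch_records_to_csv(records: Sequence[EpochRecord], path) -> None:
    import pandas as pd

    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)
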