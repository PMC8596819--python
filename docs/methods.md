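# Methods

## Scope and model of a docking experiment

A docking experiment is: read compounds → enumerate molecular states →
generate 3D conformers → dock each state against a receptor → reduce pose
records to a score table. Every stage carries failures forward as flagged
records rather than dropping them, so the per-run accounting (ligands in /
embedded / docked / failed) is always conserved: every input enumeration
appears exactly once across scored records and failures.

### State enumeration

Stereo expansion touches only *unassigned* stereocentres (specified
stereochemistry is user intent and is preserved); a molecule with k
unassigned centres and no tautomeric groups yields min(2^k, `max_states`)
states. Tautomers come from RDKit's rule-based enumerator. States are
deduplicated on canonical isomeric SMILES and ordered lexicographically —
the ordering is arbitrary but total, which buys determinism and idempotence
(re-enumerating an enumerated state returns itself). `max_states` defaults
to 32 to bound combinatorial blow-up on polyols; truncation is flagged on
the ligand rather than silent.

### 3D embedding

ETKDGv3 distance geometry with a fixed seed (default 42), then force-field
minimization (MMFF94 where parameterized, UFF fallback) capped at
`max_iterations` (default 600). The convergence flag records whether the
minimizer finished within the cap; non-converged coordinates are kept — a
strained geometry is still dockable and downstream code decides what to do
with the flag.

### The synthetic docking backend

External engines are out of scope by design; the shipped backend must be
deterministic, cheap, and *orderable* so that pipeline invariances and
enrichment machinery can be tested meaningfully. The score of an
enumeration is

    score = −( w · s ),   s_k = exp(−|d_k − t_k| / σ_k),

where d is a fixed 8-channel physicochemical descriptor vector (heavy
atoms, rings, aromatic rings, H-bond donors, H-bond acceptors, rotatable
bonds, MW/100, TPSA/50), t and w are the receptor profile's target and
weight vectors, and σ are fixed per-channel softness scales (5, 1, 1, 1, 2,
2, 1, 1 — roughly one "chemically meaningful step" per channel). Properties:
lower is better; the global minimum −Σw is attained exactly at d = t; the
score worsens monotonically in each channel's distance; and it is a pure
function of (canonical SMILES, receptor payload), hence bit-reproducible and
independent of conformers. It makes no claim of physical realism — it is an
internally consistent stand-in engine, not a scoring-function surrogate.

### Parallel dispatch and write-out

Batches are chunked `max_compounds_per_core` enumerations per task over a
joblib process pool and results re-sorted by (ligand_id,
enumeration_index), so output is identical for any core count or input
order. Write-out modes: `all`, `best_per_enumeration`, `best_per_ligand`
(default — screening statistics conventionally keep only the best state per
compound). "Best" honours the backend's declared score direction; ties
break on ascending (enumeration_index, pose_index) for determinism. The
three modes form a subset chain after best-selection.

## Analysis statistics

**pROC AUC.** Entries are sorted best-first; a score tie between an active
and a decoy ranks the decoy first, making reported enrichment conservative
and deterministic. β_i is the fraction of decoys strictly ahead of the i-th
active, clipped below at 1/N_decoys because an active recovered before any
decoy gives β = 0 and a divergent log10(1/β); the clip keeps the statistic
finite while preserving early-enrichment weighting, and the clip count is
reported so saturation is visible. The statistic is the mean of log10(1/β)
over actives — the normalization consistent with the random-selection
expectation log10(e) ≈ 0.434 (for uninformative scores β is asymptotically
uniform on (0,1] and E[−ln β] = 1, so E[log10(1/β)] = 1/ln 10). Bounds:
0 ≤ pROC AUC ≤ log10(N_decoys) under this clipping.

**ROC AUC** uses the Mann–Whitney rank formula on fractional ranks, so ties
contribute one half.

**Spearman ρ** is computed from fractional (average) ranks. On tie-free
data the classical closed form 1 − 6Σd²/(n(n²−1)) is used directly — it is
algebraically identical to Pearson-on-ranks there but evaluates the
monotonic-data identities exactly (±1 without float round-off); with ties,
Pearson on the fractional ranks is used. A constant vector leaves ρ
undefined (flagged, never raised).

**Kendall τ_B** classifies all n(n−1)/2 pairs via vectorized sign outer
products: concordant C, discordant D, tied on one variable only (the two T
correction terms), tied on both (excluded from every term, per the standard
τ_B convention). An all-tied vector zeroes a denominator factor → undefined
flag. The implementation is cross-checked in the tests against a pure-Python
pair-enumeration oracle and against scipy's independent implementation.

**Thresholds mode** classifies each point into one of four quadrants under
direction-aware hard boundaries on both axes. A value exactly at a threshold
counts as "active" — one consistent rule, chosen because
limit-of-quantification censoring piles measurements exactly onto the
boundary and dropping them would be arbitrary.

All analysis modes operate on best-per-ligand tables by default and accept
any number of score files; one malformed input is reported in its own row
and never aborts the rest.

## Generative-design scoring

**Transforms.** Sigmoid kinds use P = 1/(1+exp(∓k(x−m)/h)) with m the anchor
midpoint and h the half-range, so the midpoint maps to 0.5 and at the
default steepness k = 5 the anchors map to ≈0.007/0.993. `reverse_sigmoid`
(decreasing) is the default for lower-is-better docking scores, with anchors
set from the score range of known actives — desirability should saturate
where verified binders score. `linear_clip` ramps 0→1 between the anchors;
`step` is the indicator of [low, high] (used for hard property windows such
as MW ∈ [200, 575] or H-bond donors ≤ 7). A non-finite raw value — a failed
docking — maps to 0, so the agent is penalized for undockable proposals
rather than having them silently dropped.

**Aggregation.** S(x) is evaluated in log space; the exponent normalization
1/Σw makes it invariant to rescaling all weights, and any zero component
annihilates the total. All-equal weights reduce it to the plain geometric
mean.

**Diversity filter.** The scaffold key is the generic Bemis–Murcko
framework: all atoms → carbon, all bonds → single, canonicalized — so
benzene, pyridine, toluene and phenol share one key; ring-free molecules map
to a designated acyclic key. Compounds with S(x) ≥ `min_score` (default 0.4)
fill their key's bucket (capacity 25); once full, matching compounds score 0
forever, and exact SMILES duplicates of stored compounds are always
penalized. The default match rule is exact key equality (threshold 1.0); an
optional relaxation also penalizes compounds whose scaffold-fingerprint
Tanimoto to a saturated scaffold reaches a sub-1.0 threshold.

**Harness.** `rl_step_harness` runs the propose → score → filter → feedback
loop agent-agnostically (batch size default 128), recording per epoch the
mean/max total, mean adjusted total, mean raw docking value, and the
cumulative count of unique compounds passing a total-score threshold (a
nondecreasing curve whose slope reflects exploration). The bundled
`HillClimbProposer` is an ε-greedy library walker used for tests; it is not
a generative model and no policy update is implemented — only the scoring
and diversity interface an agent would consume.

## Epoch similarity

Average linkage between two epoch batches is the full double-sum mean of
pairwise Tanimoto similarities on Morgan fingerprints (radius 3, 1024 bits —
configurable). No within-batch deduplication is applied, and the matrix
diagonal is the intra-batch value (1.0 for a batch of one repeated
molecule). The matrix samples every `stride`-th epoch (default 5), giving
ceil(E/stride) rows; fingerprints are computed once per distinct molecule,
which makes the degenerate constant-run case effectively free.

## Synthetic fixtures

`generate_screen` emulates a benchmark target's composition: 40 actives and
1200 decoys by default. Decoys follow a baseline distribution (Gaussian in
score units centred at −7 by default; uniform and Student-t(3) heavy-tailed
variants exist, the latter to stress the β-clipping policy); actives are
shifted `delta` noise units toward "better" per the score direction.
`delta = 0` is an uninformative screen whose expected pROC AUC is the
random-selection limit; expected enrichment is nondecreasing in delta. Every
screen requires an explicit seed. Because both enrichment statistics are
rank-based, the choice of baseline family does not affect their null
expectations.

`generate_toy_library` enumerates a fixed fragment grammar (8 one-slot and 8
two-slot ring cores × 16 decorations), validates and canonicalizes every
combination with RDKit, deduplicates, and returns a seeded shuffle — ~2000
distinct, parseable, embeddable molecules. The library makes no chemical
realism claims; it exists so enumeration, embedding, docking, scaffold and
fingerprint code paths run on plausible drug-like topologies without any
download.

## Problem sizes and numerical choices

The statistical checks use 1000 replicate screens for the random-selection
expectations (standard error ≈ 0.002 on the pROC mean, comfortably inside
the ±0.01 check), 100 replicates per point on the planted-enrichment ladder,
and 1000 random instances (n ≤ 50) for the correlation oracle equivalence.
Pipeline tests run on a 20-ligand embedded fixture shared across the
session. Configuration validation is strict (unknown keys are errors, with
the offending path named) and total: every JSON either yields a fully
defaulted, validated configuration or a structured error. Config-relative
paths are resolved against the config file's directory so experiments are
location-independent.

## Known limitations

* The synthetic backend's scores have no physical meaning; conclusions
  about real docking engines' enrichment or correlation behaviour cannot be
  drawn from it. It demonstrates the orchestration, reduction and analysis
  machinery only.
* External-engine adapters are contract stubs: they declare score direction
  and refuse to run without a configured executable.
* Tautomer coverage is whatever RDKit's rule set produces; protonation/pKa
  modelling is not attempted (the pH parameters are carried through the
  configuration for embedders that use them, but the built-in embedder does
  not).
* No bootstrap confidence intervals on AUCs and no enrichment-factor-at-%
  metrics; the toolkit reports point statistics.
* The RL harness contains no generative model, no policy gradient and no
  experience replay; it exercises the scoring interface only.
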