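# Methods

This note records the modeling and numerical choices behind molforge, in
enough detail to re-derive every number the test suite asserts.

## The molecular grammar

Molecules are represented as strings over a robust SELFIES-style token
alphabet (`molforge.grammar.ALPHABET`, 23 tokens): sixteen atom/bond tokens
(`[C]`, `[=C]`, `[#C]`, `[N]`, `[=N]`, `[#N]`, `[O]`, `[=O]`, `[S]`,
`[=S]`, `[P]`, `[=P]`, `[F]`, `[Cl]`, `[Br]`, `[I]`), ring-closure tokens
of orders one to three and one or two index digits (`[Ring1]`, `[=Ring1]`,
`[#Ring1]`, `[Ring2]`, `[=Ring2]`) and branch tokens (`[Branch1]`,
`[Branch2]`). The first sixteen tokens double as base-16 digits for branch
lengths and ring look-back distances.

Decoding is a derivation that **clips every requested bond order to the
free valences of both endpoints** (C:4, N:3, O:2, S:6, P:5, halogens:1) and
silently drops instructions that cannot apply (a ring token with no earlier
atom, a branch at the end of the string). Consequently *every* token
string decodes to a chemically valid molecule or, rarely, to the empty
sentinel `""` when the payload contains no atom token at all. This
robustness is load-bearing three times over: sampled sequences are always
valid (validity is structural, not statistical), mutation during molecule
evolution can never leave chemical space, and random token strings are a
legitimate molecule generator for fixtures.

Encoding is the exact inverse on a supported subset: the input is
canonicalized and kekulized, traversed depth-first from atom 0, branches
wrapped in branch tokens with length digits, and ring bonds emitted at the
later-visited endpoint. Every encode is verified by round-trip; molecules
that are charged, multi-fragment after cleaning, or contain unsupported
elements raise `EncodingError` and are excluded by preprocessing (a small
minority, counted in the preprocessing report).

## The backbone generator

A chemical language model over the token corpus: embedding → three stacked
GRU layers → linear projection to vocabulary logits, trained with
teacher-forced next-token cross-entropy (natural log, pad positions masked)
and sampled autoregressively from the start placeholder.

There is no deep-learning framework in the dependency set, so the network
is implemented directly in numpy (`molforge.nn`): gate convention
(reset, update, candidate) with separate input/hidden biases, full
backpropagation through time, and Adam with bias correction. Gradients are
validated against central finite differences in the test suite (worst
relative error below 1e-5). Everything is float64.

The parameter count follows the closed form

    P = V·E + Σ_layers 3·(d_in·H + H² + 2H) + (H·V + V)

which for the default full-scale configuration (vocabulary V=148,
embedding E=270, hidden H=540, 3 layers) gives exactly 4,941,148 ≈ 4.9 M
trainable parameters. Tests and examples use reduced dimensions
(embedding 32–64, hidden 64–128, <1 M parameters) that train in seconds to
minutes on one CPU.

Sampling masks the start and pad placeholders at every step and restricts
the **first** step to atom tokens — every encoded training sequence begins
with one (its traversal root), and without the restriction a lightly
trained model occasionally opens with a ring/branch token and decodes to
the empty sentinel. With the mask, 100% validity holds for any parameter
state. Temperature 0 is the greedy limit; sampling is chunked and
deterministic under a seeded generator.

## Synthesis scoring and reward shaping

A raw synthesis score `x` (positive = easy to synthesize, nominal range
about ±150) is projected to the strictly positive reinforcement score

    RS(x) = exp(x / 150) + e.

In positive-direction optimization the reward is additionally truncated:

| raw score        | label | reward      |
|------------------|-------|-------------|
| x > 150          | ES    | 0 (excluded)|
| 0 < x ≤ 150      | ES    | RS/2        |
| x ≤ 0            | HS    | RS          |

Negative-direction optimization uses the plain RS. Note the deliberate
consequence of the half-reward rule: a hard-to-synthesize molecule's full
RS exceeds an easy one's halved RS, so under truncation the *shaped* reward
is not monotone in the raw score. This is faithful to the rule as
specified; it is why the directional-optimization property is checked with
truncation disabled (plain RS is strictly monotone) while truncation's own
purpose — collapse mitigation — is checked separately.

The reference scorer is a Bernoulli naive-Bayes log-odds model over RDKit
Morgan circular fragments (radius ≤ 2, Laplace α = 1): a molecule's score
is the sum over its distinct fragment ids of the smoothed per-class
document-frequency log-odds. It is antisymmetric under swapping the
training classes, and fragments unseen in training score 0 when the
classes are balanced. Mock scorers (constant, atom-count, arbitrary rule)
support controlled experiments; an adapter for the external SYBA package
activates only if that optional dependency is installed.

## Policy-gradient fine-tuning

The generator is treated as a token-level policy. Each step samples
molecules de novo, scores them, and minimizes the REINFORCE surrogate

    L = -(1/N) Σ_n R(τ_n) Σ_t log p(a_t | s_t)        (positive direction)

with the exact negation for the negative direction. There is no baseline
or critic; reward truncation is the only variance/collapse control, as in
the method being modeled. Gradients are obtained by re-running the sampled
sequences under teacher forcing with per-sequence weight R/N and the *same*
logit mask the sampler used, so the differentiated likelihood is exactly
the sampling policy's. Molecules excluded by truncation carry weight 0.
The default schedule is 10 molecules/step, 20 steps/epoch, 10 epochs; the
default learning rate is 1e-4 (tests use 2e-3, a workable step size for the
reduced models, chosen from the pretraining scale before outcomes were
measured). A divergence guard aborts if the mean |log p| explodes.

A collapse monitor records per epoch the duplicate-molecule fraction, mean
reward and number of distinct tokens used — the quantities that expose the
degenerate policy that repeats a few high-reward molecules.

### The collapse study condition

The truncation-mitigates-collapse property is tested under a *saturating*
scorer whose degenerate optimum is a small set of molecules:
`raw = 300 − 40·n_heavy`, a size-penalizing caricature of synthetic
accessibility (small molecules are trivially synthesizable and overshoot
the 150 threshold). Without truncation the policy collapses onto a
handful of tiny molecules (final-epoch duplicate fraction ≈ 0.96 in
development runs); with truncation those are excluded and the duplicate
fraction stays low (0.01–0.16 across learning rates). Size-*rewarding*
scorers were tried first and rejected as study conditions: their
no-truncation optimum is long molecules, which are combinatorially diverse,
so they do not reproduce the failure mode the mechanism exists to prevent.

## Metrics

For a sample set S with valid subset V (canonicalized):

    validity   = |V| / |S|
    uniqueness = |set(V)| / |V|
    novelty    = 1 − |set(V) ∩ N| / |set(V)|    (N = training set)

Drug-likeness is RDKit QED and Crippen logP. The Lipinski rule-of-five
filter uses the canonical four thresholds (MW ≤ 500, logP ≤ 5, H-bond
donors ≤ 5, acceptors ≤ 10) with pass = all four; thresholds are
configurable. Chemical-space projection is a scikit-learn PCA of binary
Morgan fingerprints (radius 2, 2048 bits).

With the installed RDKit, the bundled Ma97 molecule scores QED 0.9297 and
Crippen logP 3.8491 (3.85 at two decimals; agreement with the nominal 3.84
is asserted within 0.01, one unit in the last printed place, since the
exact second decimal depends on the Crippen parameter tables shipped with
the toolkit version).

## Molecule evolution

`evolve(start, end)` hill-climbs in token space: each step draws up to 200
mutants of the current token string (1–2 edits, each uniformly
replace/insert/delete at a uniform position), decodes them (always valid),
and accepts the candidate with the highest Tanimoto similarity to the
endpoint, only if it strictly improves on the current similarity. The
similarity-to-end series is therefore non-decreasing, consecutive path
members differ by at most two token edits, and a fixed seed reproduces the
path exactly. The walk stops at similarity ≥ 0.9 (configurable) or after
max_steps.

Each intermediate records similarity to both endpoints and the joint
similarity (T_start + T_end)/2 − |T_start − T_end| (a `min` variant is
available), plus QED and logP; the path report flags steps whose QED
strictly exceeds the start's and whose logP is strictly closer to the
drug-like midpoint 2.5. The endpoint selector picks the maximal-QED
Lipinski-passing molecule with logP inside a configurable window, with a
deterministic lexicographic tie-break.

## Fixtures

All inputs are generated: `random_molecule_set` draws uniform token strings
over a compact organic alphabet (C/N/O/F atoms, one branch, two ring
tokens) and decodes them — unique, valid, deterministic under seed.
`labelled_es_hs_sets` builds two structurally separable families for scorer
training: one from a sulfur-free alphabet, the other filtered to contain
sulfur, so sulfur environments are the documented marker fragments and
held-out classification is exact. `bundled_drugs` ships four named
molecules (Ma97, ribavirin, aspirin, benzene); ribavirin's SMILES is the
standard reference structure and is used only in evolution demos.

## Limitations

- The grammar covers a neutral organic subset; charged species,
  stereochemistry, and exotic elements are excluded by design.
- Full-scale results (ChEMBL-sized corpora, the 4.9 M-parameter model
  trained to convergence) are out of desk scale; the test suite validates
  the mechanisms on reduced models and seeded fixture corpora.
- The numpy implementation is single-threaded beyond BLAS; it is sized for
  the reduced configurations, not for production-scale training.
- The reference synthesis scorer is a stand-in with exact, documented
  semantics, not a re-trained replica of any published classifier.
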