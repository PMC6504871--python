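# Methods

## Model

The migration network is a Boolean network: a directed graph G(V, E) over 19
proteins, each node carrying a binary activity X_i(t) and a logical
transition function f_i over its regulators. Two update semantics are used
for two different jobs. Steady states are defined synchronously — a state s
is an attractor iff f(s) = s — which makes them scheme-invariant: a fixed
point of the synchronous map is exactly a state no single-node asynchronous
update can leave. Dynamics (perturbation ensembles, random walks) are
asynchronous: at each step one node is drawn uniformly from the unclamped
nodes and updated. The uniform single-node draw is an assumption; the
underlying simulation literature says only "chosen at random". Cyclic
asynchronous attractors are not enumerated; walks that fail to land on a
fixed point simply report nothing.

Only fixed points are reported as attractors because the biological claims
rest on stable protein-activity configurations; limit cycles in this network
family are an artifact of the update order and are deliberately out of scope.

## The 19-protein rule set

The published analysis describes its network only through its attractor
table, so the packaged rule set is a reconstruction, not a transcription: it
was derived so that its fixed-point structure equals the published table
exactly, and `validate_against_table1` re-verifies this on every run of the
validation command and the test suite. Structurally: DISC1 is mutually
antagonistic with the inhibitor bloc (GSK3B, SOX10, FOXD3, RHEB — each
`!DISC1`, and DISC1 requires `!GSK3B`); eight downstream facilitators (NDEL1,
LIS1, CC141, MYH2, ACTB, AKT1, GRDN) simply follow DISC1; PCM1↔BBS4 and
A4↔DAB1 are DISC1-gated mutual-activation pairs; CDK5 and ZN365 are
self-sustaining inputs, with DIXC1 = CDK5 & DISC1; and DISC1 additionally
requires at least one of PCM1/A4/ZN365. Whether that last disjunction is the
authors' literal choice cannot be decided from the attractor table — all
consistent variants share the same fixed points — so the fixture is
replaceable data: any rule file passing validation is equivalent for every
analysis here.

The functional-module classifier is likewise reverse-engineered from the
attractor table's 18 rows: an FM is facilitated iff the core facilitators are
ON, the inhibitor bloc is OFF, and the FM-specific extras hold (FM1 needs
PCM1+BBS4, FM2 needs ZN365, FM3 needs CDK5+DIXC1, FM4 needs A4+DAB1, FM5–FM8
need nothing extra). The exhaustive 18-row test, not the derivation, is the
evidence it is right.

## Attractor search and robustness

Exhaustive enumeration tests f(s) = s for every one of the 2^n states
(vectorized over chunks of ≤ 2^20 states; refused above 24 nodes). Random-walk
search runs L asynchronous steps from random initial states and reports the
terminal state only if it verifies as a fixed point, so its yield is provably
a subset of the exhaustive set; a walk already sitting on a fixed point exits
early, which changes nothing observable.

Robustness follows the shuffle protocol of the BoolNet `perturbNetwork`
function: each perturbed network permutes the truth-table output column of
**one** uniformly chosen node's rule (wiring preserved), and an original
attractor "occurs" in that network iff at least one seeded walk terminates in
it *and* it verifies as a fixed point of the perturbed network — the stricter
of the two available readings. Shuffling every rule instead (exposed as
`shuffle_perturb(..., rules="all")`) destroys all original attractors with
probability ≈ 1 − (1/2)^n per network and cannot reproduce the published
occurrence counts; the one-rule protocol reproduces their range closely.
Defaults: 3000 perturbed networks, 100 walks of 1000 steps each per network
(walk counts are not published; these are set once and configurable). The
published per-attractor counts depend on an unpublished RNG and are treated
as qualitative — the reproducible claim is that all 18 attractors recur with
high, strictly positive frequency.

## Per-FM perturbation networks

The per-module rule templates are a design choice constrained by the
published outcomes, since the underlying rule files are not printed:

- TF = conjunction of negated loop miRNAs (a TF is expressed only when every
  miRNA repressing it in a feedback loop is OFF);
- miRNA = scenario-signed function of its regulating TFs, OR-combined;
- gene = under TF-activates scenarios `(OR TFs) | !(OR miRNAs)` — direct TF
  activation dominates miRNA repression, the minimal convention consistent
  with STAT3 overexpression saturating module 1 even while STAT3 also
  activates the miRNAs — and under TF-represses scenarios
  `!(OR TFs) & !(OR miRNAs)`; empty regulator layers are omitted rather than
  treated as vacuous truths, and a gene with no regulators holds its state;
- protein-layer repressions (DISC1 ⊣ SOX10/FOXD3 in FM7, DISC1 ⊣ RHEB in
  FM8, DISC1 ⊣ GSK3B in FM2) are conjoined as `& !repressor` and dominate
  everything, which is what makes DISC1 overexpression force migration in
  FM7/FM8 under all four scenarios;
- migration readout = AND of facilitatory genes AND of negated inhibitory
  genes.

Ensembles use the published settings: 1000 runs × 150 steps from a shared
initial condition, smoothing window 10. The initial condition itself is
unstated upstream; all-OFF (clamps applied) is used so that any activation is
attributable to the perturbation, and it is validated by the printed 0%/100%
outcomes. A window of 10 over the 151 sampled points t = 0…150 yields 142
smoothed points (the upstream description says "140 time steps"; the
off-by-one depends on whether t = 0 and t = 150 are both sampled, so the code
reports actual lengths instead of forcing a count). Node order, and hence the
update-order stream for a given seed, is scenario-independent, so
cross-scenario comparisons of one perturbation are paired.

The per-FM wiring tables are an emulation of the published comprehensive
model (which TFs and loop miRNAs directly regulate which genes in which
module), shipped as editable TSVs; their docstrings mark them as synthetic
snapshots, not database exports.

## Feedback-loop mining

TF enrichment uses the one-sided (over-representation) Fisher exact test via
`scipy.stats.fisher_exact`, checked in the tests against an exact
fixed-margin enumeration oracle in rational arithmetic (agreement < 1e-12).
The p ≤ 0.05 threshold is inclusive and uncorrected, matching the upstream
filtering description. Contingency counts are fixture inputs: the background
universe belongs to the enrichment server that produced them and cannot be
reconstituted from gene lists alone.

Loop mining intersects the normalized miRNA→TF and TF→miRNA tables; a loop is
a pair present in both directions. Identifier normalization lower-cases,
strips the `hsa-` prefix and `-5p`/`-3p` arm suffixes, and removes
separators, so `hsa-miR-155-5p` ≡ `hsa-mir-155` ≡ `miR155`; arm-level
distinctions are deliberately collapsed (no fixture carries both arms of one
miRNA). Loop→FM assignment asks whether the loop's TF or miRNA has a direct
edge onto any gene of the module; DISC1 is excluded from the assignment gene
sets because the critical TFs upregulate DISC1 in *every* module — keeping it
would trivially assign every loop to all eight FMs, while the upstream
assignments reflect module-specific direct targets. The loop tables are tuned
fixtures reproducing the published loop census (21 loops / 17 miRNAs / 11
TFs / 8 multi-FM); only six TFs and ten miRNAs of that census are named in
the main text, so the remainder are plausible literature loop partners, and
the algorithm itself is generic (verified on planted-loop synthetic tables).

## Synthetic data

`synth.random_network` draws each node ≤ `max_in_degree` random regulators
and a random truth-table column with configurable ON bias, then renders the
table to an expression, so generated networks are exactly representable in
the rule dialect and shuffle perturbation is exact on them. Defaults
(10 nodes, in-degree ≤ 3, bias 0.5) give networks small enough for the
brute-force fixed-point oracle. `synth.planted_edge_tables` embeds a known
set of mutual miRNA-TF pairs among never-reciprocated noise edges. What these
generators do *not* emulate: realistic degree distributions, correlated
regulation, database noise such as conflicting evidence lines, or
sequence-level target prediction — passing tests on them demonstrates
algorithmic correctness, not biological fidelity of any curated input.

## Numerics and determinism

States are integer bitmasks (node i ↔ bit i, declaration order). Hot loops
(walks, ensembles) run as numba kernels over a packed truth-table form;
exhaustive enumeration is vectorized numpy. All randomness flows through
caller-supplied seeds; sub-seeds are derived with `numpy.random.SeedSequence`
and kept below 2^31. Identical seeds give bit-identical curves, counts, and
TSVs. Problem sizes in the test suite are chosen to keep the brute-force
oracles exhaustive where claimed (≤ ~2^11 states) while the full-scale
computations (2^19 enumeration, 3000-network robustness, 1000×150 ensembles)
run at the study's own settings.

## Known limitations

- The rule set and per-FM wiring are reconstructions validated against
  published summaries, not the authors' files; conclusions about rules the
  attractor table cannot discriminate are undetermined.
- Only steady-state attractors are reported; complex attractors are ignored.
- The enrichment background and the loop tables are fixtures; re-curating
  live databases is out of scope, and absolute curation counts (e.g. how
  many miRNAs target the interactome) are snapshot-dependent.
- Asynchronous update-order distribution and robustness walk parameters are
  assumptions where the upstream description is silent (each flagged above).
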