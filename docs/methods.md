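# Methods

## Corpus standardization

`parse_and_standardize` maps raw SMILES to the *super parent*: largest
organic fragment, charges neutralized where chemically possible, isotopes
stripped, stereochemistry removed, canonical tautomer selected, then
canonical SMILES. The pipeline is RDKit's `rdMolStandardize.SuperParent`,
the C++ port of the classic MolVS pipeline. Two consequences worth noting:

- Standardization is applied only where the API says so (corpus readers,
  the `standardize` CLI). Featurizers (`EcfpFeaturizer`,
  `DescriptorFeaturizer`) and the generation metrics parse and canonicalize
  *without* re-standardizing, so a molecule is fingerprinted as given.
  Silent tautomer rewriting inside a featurizer would make results depend
  on an invisible step.
- Invalid strings are flagged (`is_valid=False`), never dropped silently
  and never raised as exceptions; explicit filter calls do the dropping.
  This keeps dataset construction auditable.

The pretraining filter admits only {H, C, N, O, F, S, Cl, Br} and requires
strictly fewer than 50 heavy atoms. Splitting is seeded and floor-rounded
with defaults 70% train / 10% test, 20% of the train allocation carved out
as validation; the remaining 20% of the corpus stays unassigned but
retrievable, because allocating it would invent usage the protocol does
not define. On 2,669 records the test partition is 266 molecules
(floor(0.1·2669)).

## Peptide builder

Notation grammar: `[Fmoc- | CH3(CH2)n- ] SEQUENCE [-NH2]` over the 20
canonical L-amino acids. Structures are assembled as linear SMILES with
L-alpha stereocenters (`[C@@H]`), tau(Nε)-H neutral histidine, neutral side
chains, a carbamate-linked fluorenylmethyloxycarbonyl group for `Fmoc-`,
an alkanoyl amide for `CH3(CH2)n-`, and COOH or CONH₂ at the C-terminus.

The lipid-chain prefix is ambiguous in the literature: read literally,
`CH3(CH2)14-` is a C15 alkyl substituent, but printed monoisotopic masses
of such lipid peptides typically correspond to an N-acyl chain of a
different length (e.g. 414.288 Da for the tryptophan lipopeptide matches
the C14 acyl, N-myristoyl-Trp). The builder therefore maps the prefix to
an acyl linkage with the chain length *explicit*: the default reading is
CH3(CH2)nCO- (n+2 acyl carbons) and `acyl_carbons` overrides it at parse
time, so neither the notation nor the printed mass is silently
contradicted.

Monoisotopic masses are computed twice by independent routes — a residue
mass table built from standard atomic masses (C 12.000000, H 1.0078250,
N 14.0030740, O 15.9949146, S 31.9720707) plus terminal adjustments
(+H₂O; −0.98402 Da for C-amide; +C15H10O2 for Fmoc; +CkH(2k−2)O for a
k-carbon acyl), and RDKit's exact mass of the built structure — and the
test suite requires agreement within 1e-4 Da on random specs.

A note on one published reference cell: the His-Trp dipeptide
(C17H19N5O3) has monoisotopic mass 341.1488 Da by any standard atomic-mass
table; a printed value of 341.144 for this molecule cannot be reproduced
and is treated as a misprint (all neighboring cells of that panel
reproduce exactly).

## Descriptor panel

- **LogP**: Ghose–Crippen/Wildman atom-contribution estimate (RDKit
  `Crippen.MolLogP`).
- **TPSA**: fragment-contribution topological polar surface area.
- **HBA / HBD**: RDKit's SMARTS-based Lipinski acceptor/donor counts
  (donors counted per heteroatom, not per hydrogen).
- **nBase**: no RDKit builtin exists; implemented as a SMARTS count of
  basic nitrogens — aliphatic amines not bonded to an aromatic system,
  a heteroatom, or a C=O/C=N/C=S carbon, plus amidine/guanidine =N−
  centers. The definition reproduces the expected counts for tryptophan
  (1), His-Trp (1), Fmoc-His-Trp (0) and N-acyl-Trp (0): carbamate and
  amide nitrogens and aromatic imidazole nitrogens are not basic under
  this reading.
- **Mol. wt**: monoisotopic, not average — reference panels for gelator
  characterization are mass-spec oriented.

Fingerprints are Morgan/ECFP, radius 2, 2048 bits (the "ECFP4" community
default); radius and width are parameters. Tanimoto similarity is defined
as 1.0 when both vectors are empty (identical absence of features).

## Language model

A GPT-style decoder: learned token and position embeddings, pre-norm
blocks (causal multi-head self-attention, then a GELU feed-forward
network), final layer norm, linear vocabulary head. Full-scale
configuration: 18 layers, d_model 48, 12 heads (4 dims/head), d_ff 512,
context window 128. A desk profile (4 layers, window 64) is the default
for CPU runs; both are plain parameter settings of the same class.

Because no deep-learning framework is part of the dependency set, the
model runs on a purpose-built numpy autodiff engine (`gelgen.lm.autodiff`)
covering exactly the required operations, with Adam. Training is float32;
sampling uses an incremental decoder with per-layer key/value caches that
is verified in the tests to match the training-time forward pass to 1e-4.

Choices the training protocol leaves open, and the defaults taken:

- **Tokenization** is regex-based with multi-character tokens (`Cl`, `Br`,
  bracket atoms, `%nn` ring labels) — a character model would split them
  and generate chemically meaningless strings. Sequences carry START/END
  sentinels; PAD fills windows.
- **Corpus packing**: molecules are encoded, concatenated into one token
  stream, and cut into context-window packs that may span molecule
  boundaries (the literal reading of training on a concatenated corpus).
  Targets in the final short pack are masked.
- **Optimizer**: Adam, base learning rate 3e-4 (full scale) / 1e-3–3e-3
  (desk scale), batch 64/32, cosine decay to 10% of the base rate over the
  scheduled epochs. Optional early stopping on validation NLL.
- **Sampling**: multinomial at temperature 1.0 from START until END or the
  context limit. Output strings are raw; validity is judged downstream.
- **Initialization**: weights N(0, 0.02); the vocabulary head starts at
  zero, so an untrained model predicts the uniform distribution exactly
  and its per-token NLL is ln |V| — a useful analytic baseline that the
  tests assert.

Checkpoints are single `.npz` files embedding config, vocabulary, history
and weights, with a version string; loading a mismatched version fails
loudly. All randomness (init, shuffling, sampling) flows from explicit
seeds; fixed seeds give bit-identical runs.

## Screening classifier

`GelationClassifier` chains ECFP featurization, minority-class random
oversampling to parity (duplication with replacement — bit vectors do not
interpolate meaningfully, so no synthetic-point schemes), and
`SVC(kernel='rbf', C=10, gamma=0.01, probability=True)`. The RBF kernel is
implied by the (C, γ) parameterization; γ would be meaningless for a
linear kernel. `probability=True` is Platt sigmoid calibration with
internal cross-validation, which is what a calibrated 0.5 decision
threshold requires. The active call is strict (> 0.5): a molecule scoring
exactly 0.5 is not a candidate. Screening never drops unparseable input
lines; they are returned flagged invalid with NaN probability.

AUROC is the rank-based area (midranks for ties), equal to the
Mann–Whitney concordance probability — the tests check this equivalence
against `scipy.stats.mannwhitneyu` on random score sets.

## Generation metrics

Percentages: validity over all generated strings; uniqueness = distinct /
valid; novelty = (distinct ∉ training) / distinct. The novelty denominator
(distinct valid molecules) is recorded in the report metadata since other
conventions exist. The active rate is the mean of the active fractions
among novel distinct molecules and among all valid generated molecules.

Two definitional ambiguities in the metric suite's common usage are
resolved as follows and recorded in report metadata:

- **Diversity** uses the *distance* reading — mean pairwise
  (1 − Tanimoto) — so that higher values mean more diverse sets; the
  similarity reading would invert the scale.
- **Frag/Scaff** return cosine *similarity* of BRICS-fragment /
  Bemis–Murcko-scaffold frequency vectors (higher = closer), with the
  convention 1.0 if both sets produce no fragments/scaffolds and 0.0 if
  only one does.

The Fréchet distance fits Gaussians to feature clouds and evaluates
|μ₁−μ₂|² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^½). The featurizer is pluggable; the default
is the jointly standardized 6-descriptor panel. This default is **not**
numerically comparable to published FCD values, which use a specific
pretrained neural network's activations; the machinery is identical, the
feature space is not. Degenerate covariances get an eps = 1e-6 diagonal
ridge before the matrix square root; tiny negative round-off results are
clamped to zero.

## Synthetic fixtures

`make_corpus` grows valence-correct random trees over C/N/O atoms
(occasionally seeded with a benzene ring, occasional carbonyls) and mixes
in ~10% di-/tripeptides from the peptide builder; everything is valid,
within the heavy-atom cap, and passes the pretraining filter by
construction. The generator is sized to produce ≥95% canonically distinct
molecules at n = 2000 (single residues and very small trees collide too
often and are excluded). `make_labeled_set` emulates the shape of a
hydrogelator screening set: a 13.7% minority positive class (matching a
2,669/16,761 positive/negative corpus) in which every positive contains a
planted aromatic-carbamate substructure and no negative does — a rule a
fingerprint classifier can recover exactly, giving a known-answer test.

What the fixtures deliberately do *not* emulate: real hydrogelator
chemistry (amphiphilicity, aromatic stacking propensity, pH-dependent
charge), realistic chemical-space density, or label noise. Passing the
planted-rule test shows the screening machinery learns a structural rule
from fingerprints; it says nothing about predicting real gelation.

## Test-scale choices

The suite exercises the full-scale architecture only through its
configuration; training runs use the desk profile at sizes chosen for a
single-CPU run: overfitting oracles on 1–10 molecules, the
distribution-learning property on a 600-molecule corpus with 300 samples
(validity ≥ 80%, novelty < 100%), the classifier recovery on a
1,000-molecule labeled set, and one end-to-end loop (pretrain → fine-tune
→ sample 500 → screen → report) on a 300-molecule corpus. Reported
wall-times and thresholds in the tests refer to these sizes.

## Known limitations

- The LM is CPU-bound numpy; pretraining the 18-layer configuration on a
  300k-molecule corpus is out of desk scope by design.
- Platt calibration inside `SVC(probability=True)` is deprecated upstream
  (scikit-learn ≥ 1.9 suggests `CalibratedClassifierCV`); the current
  wrapper keeps the classic behavior and will need a one-line migration.
- The peptide builder covers linear peptides of the canonical 20 L-amino
  acids with the three supported terminal modifications only — no cyclic
  peptides, D-residues, or side-chain modifications.
- `nBase` is one defensible SMARTS definition among several in use;
  alternative definitions can disagree on edge cases (e.g. anilines,
  conjugated amidines).
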