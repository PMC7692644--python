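# Methods

## The screening model

The screen formalizes a co-occurrence argument: if compound B equals a
predicted solvolysis/oxidation product of compound A, and A and B are
both reported from the same biological source, then A is a candidate
reactive natural product and B its probable extraction artifact.  The
unit of screening is the *relational record* — one source with its full
reported compound cohort, deduplicated by structure.  Assumptions worth
keeping in mind:

* **Structure identity is the full 27-character standard InChIKey.**
  Stereoisomers are therefore distinct; no tautomer or salt normalization
  is applied.  Matching on the key's first block would merge stereo- and
  protonation variants and is deliberately not done, at the cost of
  missing cases where the literature reports differ only in drawn
  stereochemistry.
* **Direction is not resolved.**  A co-occurring (acid, methyl ester)
  pair yields an esterification case from the acid *and*, when the water
  class is screened, a hydrolysis case from the ester.  Both rows are
  retained; deciding which member is the true natural product needs
  evidence outside the relational data.
* **Predicted products matching the query itself are discarded** — a
  prediction that returns the input structure carries no information here.
* **A compound's prediction status** is "successful" when at least one
  reaction class yields a valid product string and "partially successful"
  when exactly one does; compounds with no valid prediction skip the
  matching step.
* `screen_all`/`screen_source` accept a subset of the seven classes
  (default: all).  Restricting classes is how a screen of a
  methanol-planted table avoids reporting the mirror-image hydrolysis
  cases; the fixture ground truth is nevertheless computed to be complete
  for whatever class subset is requested.

## The reaction-template engine

Each of the seven classes (methanol, ethanol, acetone, dichloromethane,
chloroform, water solvolysis; oxidation) is realized by one or more
single-reactant → single-product reaction SMARTS, applied over all
matching sites with RDKit; products are sanitized, canonicalized,
deduplicated by InChIKey, and never include the reactant itself.  The
library is minimal but class-complete: carboxylic-acid esterification and
phenol O-alkylation (methanol, ethanol), quinone–methanol conjugate
addition, 1,2-/1,3-diol acetonides (acetone), catechol → methylenedioxy
bridging (dichloromethane), methyl/ethyl-ester and aryl-methyl-ether
hydrolysis (water), and benzylic-alcohol → carbonyl plus hydroquinone →
para-quinone oxidations.  The chloroform class has no well-attested
artifact chemistry at this scale; it is represented by a ketone +
chloroform → trichloromethyl-carbinol adduct template carrying an
explicit `low_confidence` flag.  No reaction conditions, kinetics or
regioselectivity ranking are modelled — every matching site reacts.

The engine serves three roles: rule-based predictor in the screen,
independent oracle against the neural translator, and generator of
training corpora (`generate_pairs`: seeded scaffold draws, decoration
with 1–2 substituents from {methyl, methoxy, hydroxy, F, Cl} at aromatic
CH sites, template application, deduplication; a bounded number of
attempts guards against template/scaffold mismatches).

## The sequence translator

One model per reaction class translates reactant SMILES to product SMILES
at the character level ("Cl" is two tokens).  The embedding is one-hot
over the corpus alphabet plus pad/start/end symbols (`' '`, `'^'`, `'$'`
— all outside legal SMILES), with 16 sinusoidal position channels
appended; `max_length` is the longest corpus string plus two, capped at
120 (the architecture suits short strings, and longer entries are
excluded with a warning).

Architecture (all convolutions width 3, float32):

* encoder: three 1-D convolutions of width 256 with ReLU, residual
  connections on the equal-width layers, and dilations 1/3/9 so the last
  layer's receptive field covers most of a short SMILES;
* decoder: the same stack at width 64, causally padded, consuming the
  target offset by one position (teacher forcing);
* attention: scaled general (Luong) dot-product attention of decoder over
  encoder states, with padding masked and a soft Gaussian diagonal prior
  (width 4 positions) on the scores — reactant and product of a
  single-site transformation are mostly copies, so the true alignment
  hugs the diagonal;
* a copy readout: the attention weights applied to the raw one-hot
  encoder characters, concatenated with the decoder states and the
  context, so reproducing an input character reduces to attending to the
  right position;
* output block: a causal width-3 convolution to 128 channels (ReLU) and a
  linear projection to the alphabet; per-position categorical
  cross-entropy with pad positions masked.

Training uses Adam (β₁ 0.9, β₂ 0.999) at batch size 64 with a 5-epoch
linear warmup to 1.5·10⁻², cosine decay, global gradient-norm clipping at
1.0, and dropout 0.15 on the convolutional branches (residual paths
intact).  Epochs default per class (methanol/acetone 100; ethanol,
dichloromethane, water, oxidation 500; chloroform 1000).  Everything is
seeded: initialization, batch order and dropout draw from one generator,
so a fixed `ModelConfig.seed` reproduces the run bit-for-bit on the same
BLAS.  Inference is greedy argmax decoding from the start symbol until
the end symbol or `max_length`; no beam search.  The network and its
forward/backward passes are implemented directly on NumPy batched
matmuls; gradients are verified against finite differences in the test
suite's development history and the training loop is exercised by
memorization and determinism tests.

The widths 256/64, batch 64 and the optimizer follow the reference
configuration for this architecture family; the remaining choices
(dilations, position channels, diagonal prior, copy readout, dropout,
learning-rate schedule) were selected on held-out validation performance
of template-generated corpora and are recorded as `ModelConfig` defaults
so any experiment is reproducible from its config.

## Metrics

* **Success** = 100 × (valid generated strings) / (total), validity being
  RDKit parseability+sanitization.
* **Concordance** = mean Ratcliff–Obershelp gestalt ratio
  2M/(|target|+|predicted|) via `difflib.SequenceMatcher`
  (`autojunk=False`), averaged over *all* predictions; invalid strings
  are still character sequences and are included (a `valid_only` variant
  is reported alongside).  The recursive longest-block decomposition
  breaks ties toward its first argument, so the ratio is not exactly
  symmetric for strings with repeated blocks; the (target, predicted)
  order is fixed and documented.
* **Accuracy** = 100 × (predictions whose full InChIKey equals the
  target's) / (total); invalid predictions count as mismatches, hence
  Accuracy ≤ Success identically.

## Synthetic data: what it does and does not show

`fixtures` emulates the *relational structure* of a compound/source
database: each synthetic source carries planted (reactant,
template-product) co-occurrences diluted with decoys drawn from a pool
verified inert under every reaction class, and the ground truth
enumerates every template-reachable (reactant, product, class) relation
present in the cohort — including reverse relations of bidirectional
chemistry — by direct template application, independently of the
screening machinery.  Scaffolds are ~45 short hand-written SMILES across
the functional families the templates recognise.

What the synthetic tables do **not** emulate: the structural complexity
of real natural products (sugars, stereocenter-rich terpenoids,
macrocycles), reporting noise, tautomer/salt variation between papers,
and — critically — non-template chemistry.  Recall = 100% on fixtures is
a correctness property of the pipeline (the planted chemistry *is*
template chemistry), not a claim about screening sensitivity in the
wild; likewise zero false positives is a property of the decoy pool.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen so a
full from-scratch run stays in the minutes range on one CPU: 20-source
relational fixtures (1 planted pair + 5 decoys each), 100 generated pairs
per class for engine/corpus consistency, and a 500-pair single-template
(methanol esterification) corpus with an 80/20 seeded split for the
learnability check, trained at 60 epochs.  Under those conditions the
translator reaches ≈ 90–100% Success and ≈ 60–70% structure Accuracy on
the held-out pairs across seeds, with Concordance ≈ 0.96 — comfortably
above a random-string baseline and sufficient to demonstrate that the
architecture recovers a known transformation from data.  Accuracy rises
further with the per-class default epoch counts; the reduced setting is
used where wall-clock time matters.

Degenerate inputs: empty SMILES are invalid by contract; unparsable rows
in relational tables are dropped and counted with a warning rather than
fatal; reactants outside a model's alphabet yield an invalid outcome
rather than an exception; duplicate structures within a source are merged
keeping the first spelling and concatenating references.

## Known limitations

* Exact-key matching misses artifacts reported as different stereoisomers
  or salt forms of the predicted product.
* The template library is a desk-scale core of the artifact chemistry,
  not an exhaustive model of solution reactivity; the chloroform class in
  particular is speculative.
* The translator is trained and validated on template-generated corpora;
  performance on literature reaction data will be lower and depends on
  corpus curation.
* Human review of screened cases — part of any real artifact-hunting
  workflow — is out of scope.
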