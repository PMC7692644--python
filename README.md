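# npscreen

Virtual screening for **reactive natural products** and their probable
**extraction artifacts**.

Natural-product chemists routinely isolate compounds that were never made
by the organism: chemically unstable metabolites react with the
extraction solvent (methanol, ethanol, acetone, dichloromethane,
chloroform, water) or oxidize on exposure to air and light, and the
reaction products — *artifacts* — end up reported as natural products.
`npscreen` flags probable cases computationally.  The key observation is
that a reactive natural product and its artifact tend to **co-occur in
the relational data of one biological source** (the set of all compounds
reported from one species).  The screen therefore:

1. takes a relational table of (biological source, compound SMILES) rows;
2. predicts each compound's solvolysis and oxidation products under seven
   reaction classes — six solvent classes plus oxidation;
3. matches the predicted products against the *other* compounds from the
   same source by InChIKey;
4. emits every hit as a candidate (natural product, probable artifact,
   reaction class) case.

Two predictors are provided and can be ensembled:

* a deterministic **reaction-template engine** (reaction SMARTS for
  esterification, O-alkylation, quinone–methanol addition, acetonide
  formation, methylenedioxy bridging, ester/aryl-ether hydrolysis,
  benzylic-alcohol and hydroquinone oxidation);
* a per-class **character-level convolutional sequence translator** that
  maps reactant SMILES to product SMILES (encoder of three 1-D
  convolutions, latent width 256; causal decoder convolutions, width 64;
  attention with a copy readout; trained with teacher forcing, batch 64,
  Adam), decoded greedily and judged by whether the generated string
  parses.

Model quality is summarized by the three standard quantities: **Success**
(% of generated strings that parse), **Concordance** (mean
Ratcliff–Obershelp sequence match ratio between target and generated
strings) and **Accuracy** (% of predictions with the target's InChIKey),
with Accuracy ≤ Success by construction.

Because the original compound/source database is not redistributable, the
package ships a synthetic-data module (`npscreen.fixtures`) that builds
relational tables with planted reactive pairs plus template-inert decoys
— with exact ground truth — and template-generated training corpora, so
the whole pipeline is testable offline.

## Worked example

```python
import npscreen as nps

spec = nps.FixtureSpec(n_sources=5, planted_per_source=1, decoys_per_source=4,
                       reaction_classes=(nps.ReactionClass.METHANOL,), seed=11)
records, truth = nps.make_relational_fixture(spec)
cases = nps.screen_all(records, nps.RulePredictor(),
                       classes=(nps.ReactionClass.METHANOL,))
for c in cases[:3]:
    print(f"{c.source_id} {c.source_name}: {c.natural_product.canonical_smiles}"
          f" -> {c.artifact.canonical_smiles} [{c.reaction_class.value}]")
print(f"recovered {len(cases)} of {len(truth.planted_cases)} planted cases")
```

prints

```
SRC0001 Syntheticum alpha: O=C(O)c1ccco1 -> COC(=O)c1ccco1 [methanol]
SRC0002 Syntheticum beta: Oc1ccccc1 -> COc1ccccc1 [methanol]
SRC0003 Syntheticum gamma: Oc1ccccc1O -> COc1ccccc1O [methanol]
recovered 5 of 5 planted cases
```

Row one reads: 2-furoic acid and its methyl ester were both "reported"
from the same source, and the methanol class explains the second as an
esterification artifact of the first.  The same loop runs over a real
relational CSV via the CLI:

```bash
npscreen screen --input relational.csv --predictor rules --output cases.csv
npscreen train --reaction-class methanol --corpus methanol.tsv --out models/methanol
npscreen evaluate --model models/methanol --corpus methanol_val.tsv
```

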