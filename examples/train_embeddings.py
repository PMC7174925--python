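"""Train bipartite skip-gram embeddings and inspect what they learned.

Trains on a synthetic corpus where drugs and reactions co-occur within
planted classes, then ranks all reactions for one drug by cosine between
the drug's input vector and each reaction's target-side embedding.  A
well-trained model puts the drug's own-class reactions at the top.
"""

from msgddi import GenParams, TrainParams, generate, train
from msgddi.enrichment import cosine

bundle = generate(
    GenParams(
        n_classes=3,
        drugs_per_class=12,
        background_drugs=15,
        reactions_per_class=10,
        background_reactions=25,
        n_reports=600,
        ddis_per_class=10,
        background_ddis=10,
        seed=42,
    )
)
model = train(bundle.corpus, TrainParams(dim=30, epochs=5, min_count=3, seed=1))
print(f"vocabulary: {len(model.vocab)} tokens "
      f"({len(model.vocab.drugs)} drugs, {len(model.vocab.reactions)} reactions)")

drug = next(d for d in model.vocab.drugs if bundle.truth.drug_class[d] == 0)
scores = sorted(
    (
        (cosine(model.vector(drug), model.output_vector(r)), r)
        for r in model.vocab.reactions
    ),
    reverse=True,
)
print(f"\ntop 5 reactions for drug {drug} (planted class 0):")
for cos, r in scores[:5]:
    cls = bundle.truth.reaction_class[r]
    print(f"  reaction {r}  cosine {cos:+.3f}  planted class {cls}")
print(
    "\nCosine is between the drug's input vector and the reaction's"
    "\ntarget-side (Huffman-path) embedding; class-0 reactions at the top"
    "\nmean the planted co-occurrence structure was recovered."
)
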