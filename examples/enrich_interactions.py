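"""Enrich drug-drug interaction descriptions with ranked reactions.

For each keyword-bearing interaction record, ranks every in-vocabulary
reaction by cosine to the additive pair embedding and checks whether any
of the top 20 falls under the class's System Organ Class — the validity
rule behind the per-class accuracy table.
"""

from msgddi import GenParams, TrainParams, accuracy_table, enrich_pair, generate, train

bundle = generate(GenParams(n_reports=1500, signal=0.9, noise_rate=0.1, seed=3))
model = train(bundle.corpus, TrainParams(dim=50, epochs=5, min_count=5, seed=4))
vectors = model.enrichment_vectors()
reactions = model.vocab.reactions

results = {}
for ec in bundle.event_classes:
    out = []
    for rec in bundle.resources.ddi_records:
        if not any(kw in rec.description.lower() for kw in ec.keywords):
            continue
        a, b = rec.pair
        if a in vectors and b in vectors:
            out.append(
                enrich_pair(vectors, (a, b), reactions, bundle.resources.soc_map, ec, k=20)
            )
    results[ec.name] = out

one = results[bundle.event_classes[0].name][0]
print(f"pair {one.pair}, class {one.event_class.name} — top 5 of {len(one.ranked)}:")
for rank, (r, cos) in enumerate(one.ranked[:5], start=1):
    soc = bundle.resources.soc_map.get(r, "?")
    print(f"  {rank}. reaction {r}  cosine {cos:.4f}  SOC: {soc}")
print(f"  -> enrichment {'valid' if one.valid else 'invalid'}\n")

table = accuracy_table(results)
print(table.format_tsv())
print("Accuracy is the fraction of interactions whose top-20 ranked")
print("reactions contain at least one under the class's organ system.")
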