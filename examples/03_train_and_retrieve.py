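"""Train the dose encoder by triplet loss and retrieve similar plans.

Small-scale demonstration: 12 plans in 3 beam classes, 60 training
iterations. A new query (a plan's virtual dose) is embedded and the three
nearest stored clinical-dose features are returned together with their
optimization-parameter payloads — the objects a treatment planning
system's optimizer would be seeded with.
"""

import doseret as dr

db = dr.generate_cohort(dr.CohortSpec(n_plans=12, n_classes=3, seed=2))
spec = dr.EncoderSpec(input_shape=(32, 32, 32))

result = dr.train_encoder(
    db, spec, dr.TrainConfig(iterations=60, batch_size=4, seed=0)
)
print(f"loss: first 10 iters {result.loss_history[:10].mean():.3f} -> "
      f"last 10 iters {result.loss_history[-10:].mean():.3f}")

index = dr.build_index(result.weights, db)
rec = db.records[5]
ranked, payloads = dr.end_to_end_query(result.weights, index, db, rec, k=3)

print(f"query: {rec.plan_id} (class {rec.class_label})")
for rank, ((pid, dist), ops) in enumerate(zip(ranked.hits, payloads), 1):
    print(f"  Search {rank}: {pid}  distance {dist:.4f}  "
          f"class {db[pid].class_label}  beams {ops['beam_angles_deg']}")

# Search 1 is the query's own plan (its virtual dose is closest to its own
# clinical dose); Searches 2-3 should come from the same beam class.
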