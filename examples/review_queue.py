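"""Flag low-confidence predictions for physician review.

Classifier confidences allow a triage workflow: codes assigned with high
confidence are accepted automatically, the rest are queued for a human
coder, least-certain first.
"""

import vacoder as vc

config = vc.GeneratorConfig(
    n_per_age_group={"adult": 300},
    csmf_by_age_group={"adult": vc.synth.SKEWED_CSMF_15},
    background_weight=0.5,
    misspelling_rate=0.1,
    seed=9,
)
corpus = vc.generate_corpus(config)
lexicon = vc.Lexicon.default(extra_terms=config.all_vocabulary())

train_records, test_records = corpus.records[:250], corpus.records[250:]
docs = vc.preprocess_corpus(corpus.records, lexicon)
doc_of = {d.record_id: d for d in docs}

vocab = vc.build_vocabulary([doc_of[r.record_id] for r in train_records])
X_train = vc.build_feature_matrix(
    [doc_of[r.record_id] for r in train_records], vocab,
    [r.age_group for r in train_records],
)
model = vc.train(
    vc.ModelConfig("naive_bayes", seed=0),
    X_train,
    [r.category for r in train_records],
)

X_test = vc.build_feature_matrix(
    [doc_of[r.record_id] for r in test_records], vocab,
    [r.age_group for r in test_records],
)
ranked = model.predict_with_confidence(X_test)
predictions = [(r.record_id, ranking) for r, ranking in zip(test_records, ranked)]

threshold = 0.8
queue = vc.flag_low_confidence(predictions, threshold)
print(f"test records: {len(test_records)}; flagged below {threshold}: {len(queue)}")
for record_id, category, confidence in queue[:5]:
    print(f"  {record_id}  top={category!r}  confidence={confidence:.3f}")

accepted = len(test_records) - len(queue)
print(
    f"\n{accepted} records would be auto-accepted; the {len(queue)} flagged"
    "\nrecords (listed least-certain first) go to a physician, replacing"
    "\ndual-physician coding of every record with review of a small subset."
)
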