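"""Walk one VA narrative through the preprocessing pipeline, stage by stage.

Shows how a noisy transcribed narrative (misspellings, punctuation,
function words) is reduced to the word stems that become bag-of-words
features.
"""

import vacoder as vc

text = (
    "Heart failure. The patient death due to breathlesness. "
    "On 15/03/01 the deceased was cryng with chest pain and high fevar."
)

lexicon = vc.Lexicon.default()
stopwords = vc.StopwordList.default()

tokens = vc.normalize(text)
print("normalized:  ", tokens)

corrections = []
corrected = vc.correct_spelling(tokens, lexicon, log=corrections)
print("corrected:   ", corrected)
for c in corrections:
    if c.corrected != c.original:
        print(f"  fixed {c.original!r} -> {c.corrected!r} (distance {c.distance})")

kept = vc.remove_stopwords(corrected, stopwords)
print("no stopwords:", kept)

stems = vc.stem(kept)
print("stemmed:     ", stems)

doc = vc.preprocess(text, lexicon, stopwords, record_id="example")
print("\nfinal tokens:", doc.tokens)
print(
    "\nEach stem above becomes one count feature; misspelled symptom words"
    "\n(breathlesness, cryng, fevar) were recovered, so they contribute to"
    "\nthe same feature columns as their correctly spelled forms."
)
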