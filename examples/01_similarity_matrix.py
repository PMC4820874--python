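"""Build a tiny disorder corpus and query phenotype similarity.

Five hand-written records share controlled-vocabulary concepts; the
script cleans them into a corpus, builds the globally-weighted cosine
matrix, and prints the neighbors of one record.  Scores near 1 mean
nearly identical concept profiles; shared concepts explain each match.
"""

import phenosim as ps

records = [
    ps.RawRecord("100100", "#", "EPILEPSY, FAMILIAL FOCAL, 1",
                 (("seizure", 3),), (("cortex", 2), ("eeg", 1))),
    ps.RawRecord("100200", "%", "EPILEPSY, FAMILIAL FOCAL, 2",
                 (("seizure", 2),), (("cortex", 1), ("eeg", 2))),
    ps.RawRecord("100300", "#", "CARDIOMYOPATHY, DILATED",
                 (("heart", 4),), (("arrhythmia", 2), ("eeg", 1))),
    ps.RawRecord("100400", "none", "CARDIOMYOPATHY, HYPERTROPHIC",
                 (("heart", 3),), (("arrhythmia", 1),)),
    ps.RawRecord("100500", "*", "ION CHANNEL GENE",  # gene record: filtered out
                 (("channel", 1),), (("seizure", 1),)),
]

kept = ps.filter_by_prefix(records)
print(f"{len(kept)} of {len(records)} records are phenotype records")
print("cleaned title:", ps.strip_subtype_designators(records[0].title))

corpus = ps.build_corpus(kept, stoplist=ps.default_stoplist())
matrix = ps.build_similarity_matrix(corpus, "global")
print(f"\ncorpus: {corpus.n_records} records, {len(corpus.vocabulary)} shared concepts")

print("\nrecords most similar to 100100 (epilepsy type 1):")
for rid, score, shared in ps.query_similar(matrix, "100100", k=3, corpus=corpus):
    print(f"  {rid}  score={score:.3f}  shared concepts: {', '.join(shared) or '-'}")
# the sibling epilepsy subtype scores highest because both records share
# the seizure/cortex/eeg concepts; the cardiomyopathies overlap on little
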