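# Generic concepts that appear across diverse phenotypes and carry no
# phenotype-specific information; one concept id per line.
DISEASE
DISEASES
DISORDER
DISORDERS
SYNDROME
SYNDROMES
PATIENT
PATIENTS
CLINICAL
PHENOTYPE
GENE
GENES
MUTATION
MUTATIONS
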