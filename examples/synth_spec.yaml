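# synthetic cohort: two planted correlation blocks + one stratified gene class
abundance:
  n_samples: 30
  n_taxa: 20
  depth: 10000
  blocks:
    - [[0, 1, 2, 3, 4, 5, 6, 7], 0.7]
    - [[8, 9, 10, 11, 12, 13, 14, 15], 0.7]
stratified:
  n_samples: 30
  n_taxa_pool: 20
  classes:
    - name: acetate kinase
      annotation: "Acetate kinase (EC 2.7.2.1)"
      n_contributors: 9
      concentration: 5.0
    - name: butyrate kinase
      annotation: "Butyrate kinase"
      n_contributors: 3
      concentration: 0.5
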