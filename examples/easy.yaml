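# Easy planted-category run: 10 categories x 8 words, zero frame overlap,
# ~200k tokens, hidden size 64, two architectures plus Skip-gram.
seed: 1
synthetic:
  n_categories: 10
  words_per_category: 8
  n_context_frames_per_category: 10
  frame_overlap: 0.0
  polysemy_rate: 0.0
  age_drift: 0.0
  zipf_exponent: 1.0
  n_documents: 32
  tokens_per_document: 6250
prep:
  vocab_size: 1024
  n_partitions: 8
  test_fraction: 0.05
train:
  - arch: srn
    replicates: 2
    hidden_size: 64
    local_iterations: 2
  - arch: lstm
    replicates: 2
    hidden_size: 64
    local_iterations: 2
  - arch: skipgram
    replicates: 1
    hidden_size: 64
    n_epochs: 5
evaluate:
  grid_step: 0.001
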