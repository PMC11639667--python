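"""Produce the two residue feature channels and their concatenation.

Tokens (0–20, alphabetical amino-acid order with 20 = unknown) feed a
learnable 21×96 embedding; the 1280-wide channel comes from an embedding
provider — here the deterministic synthetic stand-in for a protein language
model.  The 1376-wide concatenation is the joint input channel.
"""

from funfuse import SyntheticEmbeddingProvider, concat_features, provide_embeddings, tokenize_sequence
from funfuse.encodings import embed_tokens, make_embedding_table

sequence = "ACDWWWKLMX"
tokens = tokenize_sequence(sequence)
print(f"sequence : {sequence}")
print(f"tokens   : {tokens.tolist()}  (X → 20, the missing-position token)")

onehot = embed_tokens(tokens, make_embedding_table(seed=0))
print(f"one-hot embedding channel: {onehot.values.shape}  ({onehot.channel})")

provider = SyntheticEmbeddingProvider(seed=0)
lm = provide_embeddings(sequence, provider)
print(f"language-model channel   : {lm.values.shape}  ({lm.channel})")
print(f"  row mean ≈ {lm.values.mean():+.3f}, row scale ≈ {lm.values.std():.3f} "
      "(standardized by construction)")

both = concat_features(lm, onehot)
print(f"concatenated channel     : {both.values.shape}  ({both.channel})")

# determinism: the same (sequence, seed) always gives the same matrix
again = provide_embeddings(sequence, SyntheticEmbeddingProvider(seed=0))
print(f"bitwise reproducible: {(again.values == lm.values).all()}")
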