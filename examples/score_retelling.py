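"""Score a single retelling against its source story with G-match.

G-match is the token-count-weighted mean, over source sentences, of the
best cosine similarity any retelling sentence achieves against that source
sentence (negatives clamped to zero). It reads as the proportion of the
story's content present in the retelling: 1.0 for verbatim recall, 0.0
when nothing matches.
"""

from asrt.gmatch import gmatch

SOURCE = (
    "The baker opened his shop at dawn. "
    "A young girl asked for the last rye loaf. "
    "He wrapped it in brown paper and waved her goodbye."
)

# paraphrased partial retelling: covers sentences 1 and 2, misses the third
RETELLING = (
    "Um, the baker opened the shop at dawn. "
    "A girl asked him for the last rye loaf."
)

result = gmatch(SOURCE, RETELLING)
print(f"G-match: {result.gmatch:.3f}")
for sim, w in zip(result.per_unit_similarity, result.unit_weights):
    print(f"  source unit (weight {w:2d} tokens): best similarity {sim:.3f}")
print()
print("Interpretation: each line is one source sentence; a similarity near 1"
      "\nmeans that sentence was retold, near 0 that it was omitted. The"
      "\nheadline score is the token-weighted mean, so the unretold final"
      "\nsentence pulls the score below 1 in proportion to its length.")
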