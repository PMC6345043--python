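"""Classify short seeds as unique / repeat / unmapped against a reference.

A 40 bp seed taken from a unique locus maps uniquely even with a couple of
errors; a seed from a duplicated segment reports both copies (repeat); a
random 40-mer finds no window within the edit budget (unmapped).  These
three statuses drive the aligner's traversal and stage decisions.
"""

import numpy as np

from loraln import build_index, make_reference, map_seed
from loraln.io_formats import revcomp

# reference with a planted 2 kb duplication: [50k, 52k) == [400k, 402k)
ref = make_reference(500_000, rng_seed=11, repeat=(50_000, 2_000, 400_000))
index = build_index(ref)

clean = ref.seq[123_456 : 123_496]
mutated = clean[:20] + ("A" if clean[20] != "A" else "C") + clean[21:]
reverse = revcomp(clean)
repeat = ref.seq[50_500 : 50_540]
rng = np.random.default_rng(0)
random40 = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))

for label, seed in [
    ("exact seed from unique locus", clean),
    ("same seed with 1 substitution", mutated),
    ("reverse complement of it", reverse),
    ("seed from duplicated segment", repeat),
    ("uniform-random 40-mer", random40),
]:
    m = map_seed(index, seed, max_edits=4)
    hits = ", ".join(f"{h.offset}{h.strand}(e={h.edits})" for h in m.hits[:4])
    print(f"{label:32s} -> {m.status:8s} {hits}")
# The duplicated-segment seed lists both copies; an aligner that trusted a
# single such hit would misplace half of those reads.
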