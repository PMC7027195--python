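"""The 23 systematic nucleotide exchanges and their group structure.

Enumerates every non-identity bijection of {A,C,G,T}, applies one to a
sequence, and shows the inversion relationship that links a detected
asymmetric exchange to the exchange the polymerase must have performed.
"""

import sys

from swingerscan import (
    apply_transformation,
    enumerate_transformations,
    invert,
    parse_name,
)
from swingerscan.transforms import write_transformation_table

transformations = enumerate_transformations()
print(f"{len(transformations)} exchanges: "
      f"{sum(t.kind == 'symmetric' for t in transformations)} symmetric, "
      f"{sum(t.kind == 'asymmetric' for t in transformations)} asymmetric\n")

write_transformation_table(sys.stdout)

seq = "GATTACA"
t = parse_name("A↔T")
print(f"\n{t.name} applied to {seq}: {apply_transformation(t, seq)}")

t4 = parse_name("A→T→C→G→A")
print(f"inverse of {t4.name}: {invert(t4).name}")
print("→ a read detected under the first exchange was transcribed from its"
      " template using the second (symmetric exchanges are self-inverse).")
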