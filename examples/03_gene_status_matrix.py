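"""Classify genes as intact / pseudogene / lost / uncertain.

Simulates a heavily degraded plastome (the ndh suite largely lost or
pseudogenised, as seen in some Amaryllidaceae) plus an intact relative,
builds a reference panel, and prints the status matrix summary.
"""

from plastopart import build_reference_panel, status_matrix
from plastopart.synthetic_data import SynthSpec, build_plastome, strumaria_like_spec

degraded, truth = build_plastome(strumaria_like_spec(seed=3))
intact_rel, _ = build_plastome(SynthSpec.type_a(seed=3))

panel = build_reference_panel([intact_rel])
matrix, counts = status_matrix([degraded], panel)

print(counts.to_string(index=False))
print()
bad = matrix[matrix.status != "intact"][["gene", "status", "copy_count", "evidence"]]
print(bad.to_string(index=False))
# Lost means under 30% of the reference CDS is present in the genome;
# pseudogene means the sequence is there but carries internal stops, a
# missing stop, or a frameshift. The ndhH pseudogene sits inside the IR,
# hence copy_count 2.
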