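"""Mismatch-tolerant dispersed repeat scanning and tandem repeats.

First checks the published junction repeat pairs by direct mismatch
arithmetic, then scans a synthetic genome for planted repeats and tandem
arrays.
"""

from plastopart import compare_pair, scan_short_repeats, scan_tandem_repeats
from plastopart.core_io import Interval
from plastopart.repeats import mismatch_budget
from plastopart.synthetic_data import PlantedRepeat, PlantedTandem, SynthSpec, build_plastome

# the two 17-mers of the published inverted pair differ by 1 after
# reverse-complementing the second; its homolog differs by 2 and is
# rejected at the 10% threshold (floor(0.1 * 17) = 1)
m1 = compare_pair("TCATTATTAGGTTTATA", "TATAAACCCAATAATGA", "inverted")
m2 = compare_pair("TCATTATTAGGTTTATA", "TATAAACCCAATAATTA", "inverted")
print(f"inverted 17-mers: {m1} and {m2} mismatches; budget {mismatch_budget(17, 0.10)}")

spec = SynthSpec.type_a(
    seed=4,
    planted_dispersed=[PlantedRepeat("inverted", 17, 1)],
    planted_tandem=[PlantedTandem(unit_len=12, copies=3)],
)
record, truth = build_plastome(spec)

r = truth.repeats[0]
windows = [
    Interval(r["pos1"][0] - 50, r["pos1"][1] + 50),
    Interval(r["pos2"][0] - 50, r["pos2"][1] + 50),
]
for h in scan_short_repeats(record, windows):
    print(
        f"{h.direction} {h.length} bp at {h.pos1.start:,}-{h.pos1.end:,} / "
        f"{h.pos2.start:,}-{h.pos2.end:,}, {h.mismatches} mismatch(es)"
    )

arrays, summary = scan_tandem_repeats(record)
t = truth.tandems[0]
planted = [a for a in arrays if a.span.start == t["span"][0]]
print(
    f"tandem arrays: {summary['count']} covering {summary['percent_of_genome']}% "
    f"of the genome; planted {t['unit_len']} bp unit recovered:",
    bool(planted),
)
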