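"""Type the J_SA junction and reconstruct an IR expansion event.

Simulates an ancestral Type A plastome and a descendant whose IR expanded
into the single-copy region by a long double-strand-break-style event,
then recovers the event by comparing the two genomes.
"""

from plastopart import classify_jsa, detect_quadripartite, diff_junctions
from plastopart.synthetic_data import scenario_single_expansion

ancestor, derived, _truth = scenario_single_expansion(seed=2, with_repeat=True)

for rec in (ancestor, derived):
    m = detect_quadripartite(rec)
    jsa = classify_jsa(None, m, rec)
    print(
        f"{rec.id}: IR {m.ir_len:,} bp, SSC {m.ssc_len:,} bp, "
        f"J_SA type {jsa.type} ({jsa.ycf1_bp_in_ira:,} bp of ycf1 in IRa)"
    )

events = diff_junctions((derived, None), (ancestor, None))
for ev in events:
    print(
        f"expansion event: {ev.size:,} bp incorporated "
        f"(genes: {', '.join(ev.genes_incorporated) or 'none'}), "
        f"mechanism hypothesis: {ev.mechanism_hypothesis} "
        f"({len(ev.mediating_repeats)} mediating repeat pair(s))"
    )
# A short repeat pair shared between the old and new junction
# neighbourhoods is the classic substrate for recombination-driven IR
# expansion; when present the event is labelled repeat_mediated.
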