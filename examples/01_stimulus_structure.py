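"""Build the Type III rule-plus-exception stimulus set and inspect it.

Prints each stimulus' role, features and padded 10-unit encoding, then
the diagnostic Hamming distances that define the roles: prototypes are
maximally separated, rule-followers one step from their prototype, and
each exception two steps from its own but only one from the opposite
prototype — which is what makes exceptions hard.
"""

import hipporpe as hp

ss = hp.build_type3_structure()

print(f"{'id':>4} {'role':>14} cat  d1 d2 d3 d4  encoding")
for s in ss:
    f = s.features
    enc = "".join(map(str, s.encoding))
    print(f"{s.id:>4} {s.role:>14}  {s.category}   {f.d1}  {f.d2}  {f.d3}  {f.d4}  {enc}")

print("\nDiagnostic distances (d1-d3):")
print("  PA1 <-> PB1:", hp.pairwise_distance(ss["PA1"], ss["PB1"]), "(prototypes, maximal)")
print("  EA  <-> PA1:", hp.pairwise_distance(ss["EA"], ss["PA1"]), "(own prototype)")
print("  EA  <-> PB1:", hp.pairwise_distance(ss["EA"], ss["PB1"]), "(opposite prototype)")

def shared_d4_distance(eid):
    e = ss[eid]
    return sum(hp.pairwise_distance(e, s, include_nondiagnostic=True)
               for s in ss.by_category(e.category)
               if s.id != eid and s.features.d4 == e.features.d4)

print("\nNondiagnostic asymmetry (summed 4-dim distance to own-category")
print("members sharing the central-disc value; smaller = more embedded):")
print(f"  EA: {shared_d4_distance('EA')}   EB: {shared_d4_distance('EB')}")
print("EA sits closer to its own category than EB does, so EA tends to")
print("behave like a rule-follower while EB behaves like a true exception.")
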