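"""Parse one ISCN karyotype and assign its UKALL-HeH risk group.

The karyotype below carries +17 and +18 with a marker chromosome (+mar): the
marker could hide a gain of chromosome 5 or 20, so the good-risk call is
provisional (P-GR) rather than definite.
"""

from hehprofile import classify, parse_karyotype

TEXT = "57,XX,+X,+4,+6,+10,+14,+17,+18,+21,+21,+mar[12]/46,XX[8]"

pk = parse_karyotype(TEXT)
clone = pk.classification_clone
print(f"karyotype : {TEXT}")
print(f"clones    : {len(pk.clones)} (classified clone modal {clone.count_low})")
print(f"markers   : {pk.marker_count}, incomplete: {pk.is_incomplete}")

assignment = classify(pk)
print(f"risk group: {assignment.group.value}  (merged: {assignment.merged_group})")
print("reasons   :", " | ".join(assignment.reasons))
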