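"""Interface residues and a focal contact environment at the 5.5 Å cutoff.

Builds a small two-chain complex with seven planted cross-chain contacts
around a focal leucine, then detects the interface and the focal residue's
contact list.
"""

from structscope import interface, make_complex, residue_environment

fixture = make_complex(seed=11)
model = fixture.model
focal = fixture.truth["focal"]

report = interface(model, group_a=["A"], group_b=["B"])
print(f"interface contacts (<= 5.5 A heavy-atom pairs): {len(report.contacts)}")
print(f"focal residue {focal} in interface: {report.is_interface_residue(focal)}")

env = residue_environment(model, focal)
print(f"\ncontact environment of {focal} ({len(env)} residues, nearest first):")
for c in env:
    print(f"  {c.residue_b}  {c.aa_b}  {c.min_distance:.2f} A")

print(
    "\nEach listed residue has at least one heavy atom within 5.5 A of the"
    " focal leucine - the same criterion used for interface membership."
)
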