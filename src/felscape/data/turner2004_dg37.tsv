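# RNA nearest-neighbor helix free energies, dG37 in kcal/mol.
# Watson-Crick stack parameters of the Turner rule sets (identical in the
# 1999 and 2004 revisions; both adopt the Xia et al. 1998 optical-melting
# regression), plus duplex initiation and the terminal AU/GU end penalty.
# Stack key "XY/ZW" reads 5'-XY-3' paired with 3'-ZW-5'; keys are stored in
# one orientation and matched rotation-invariantly.
# GU-wobble-containing stacks are deliberately NOT bundled: lookups touching
# them raise a missing-entry error naming the stack.
kind	key	dG37_kcal_mol
stack	AA/UU	-0.93
stack	AU/UA	-1.10
stack	UA/AU	-1.33
stack	CU/GA	-2.08
stack	CA/GU	-2.11
stack	GU/CA	-2.24
stack	GA/CU	-2.35
stack	CG/GC	-2.36
stack	GG/CC	-3.26
stack	GC/CG	-3.42
init	duplex	4.09
penalty	terminal_au	0.45
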