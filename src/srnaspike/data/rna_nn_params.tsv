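# RNA nearest-neighbor free-energy parameters at 37 C (kcal/mol).
#
# Watson-Crick stack values follow the widely used Turner-style unified RNA
# nearest-neighbor table. Wobble (G.U) stack values are approximate literature
# values; wobble combinations not listed fall back to the `default_wobble`
# entry (a deliberately weak stack), which is conservative for the pass/fail
# hairpin filter this table serves.
#
# Stack keys read 5'XY3'/3'ZW5' written as XY/ZW: the outer pair is X.Z and
# the inner (stacked) pair is Y.W. Symmetric duplex rotations (XY/ZW == WZ/YX)
# are filled in automatically at load time.
#
# Hairpin loop initiation penalties are given for loop sizes 3-9; larger loops
# are extrapolated with the Jacobson-Stockmayer term
#   dG(n) = dG(9) + 1.75 * R * T * ln(n / 9).
#
# section	key	value
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
stack	AG/UU	-0.55
stack	AU/UG	-1.36
stack	CG/GU	-1.41
stack	CU/GG	-2.11
stack	GG/CU	-1.53
stack	GU/CG	-2.51
stack	UG/AU	-1.27
stack	UU/AG	-1.00
stack	GU/UG	0.47
stack	UG/GU	0.30
default_wobble	.	-0.50
loop	3	5.4
loop	4	5.6
loop	5	5.7
loop	6	5.4
loop	7	6.0
loop	8	5.5
loop	9	6.4
terminal_au	.	0.45
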