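# Hydrogen-bond donor/acceptor chemistry for standard amino acids.
# residue "*" applies to every residue type (backbone atoms).
# role: donor, acceptor or both.  antecedent: atom bonded to the donor/acceptor,
# used for the no-hydrogen angle rule.  h_computable: 1 when an amide hydrogen
# position can be rebuilt from backbone geometry (backbone N only).
# residue	atom	role	antecedent	h_computable
*	N	donor	CA	1
*	O	acceptor	C	0
*	OXT	acceptor	C	0
SER	OG	both	CB	0
THR	OG1	both	CB	0
TYR	OH	both	CZ	0
CYS	SG	both	CB	0
ASN	OD1	acceptor	CG	0
ASN	ND2	donor	CG	0
GLN	OE1	acceptor	CD	0
GLN	NE2	donor	CD	0
ASP	OD1	acceptor	CG	0
ASP	OD2	acceptor	CG	0
GLU	OE1	acceptor	CD	0
GLU	OE2	acceptor	CD	0
LYS	NZ	donor	CE	0
ARG	NE	donor	CD	0
ARG	NH1	donor	CZ	0
ARG	NH2	donor	CZ	0
HIS	ND1	both	CG	0
HIS	NE2	both	CD2	0
TRP	NE1	donor	CE2	0
MET	SD	acceptor	CG	0
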