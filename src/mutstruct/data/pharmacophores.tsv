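# Pharmacophore class assignment per heavy atom. Classes (semicolon-separated):
# Hydrophobic, Aromatic, PositiveIonizable, NegativeIonizable,
# HydrogenDonor, HydrogenAcceptor, Sulfur, Neutral.
# Rows with residue '*' apply to the backbone of every residue type and may
# be overridden by a residue-specific row. Editable configuration data.
residue	atom	classes
*	N	HydrogenDonor
*	CA	Neutral
*	C	Neutral
*	O	HydrogenAcceptor
PRO	N	Neutral
ALA	CB	Hydrophobic
VAL	CB	Hydrophobic
VAL	CG1	Hydrophobic
VAL	CG2	Hydrophobic
LEU	CB	Hydrophobic
LEU	CG	Hydrophobic
LEU	CD1	Hydrophobic
LEU	CD2	Hydrophobic
ILE	CB	Hydrophobic
ILE	CG1	Hydrophobic
ILE	CG2	Hydrophobic
ILE	CD1	Hydrophobic
MET	CB	Hydrophobic
MET	CG	Hydrophobic
MET	SD	Sulfur
MET	CE	Hydrophobic
CYS	CB	Neutral
CYS	SG	Sulfur;HydrogenDonor
PHE	CB	Hydrophobic
PHE	CG	Aromatic;Hydrophobic
PHE	CD1	Aromatic;Hydrophobic
PHE	CD2	Aromatic;Hydrophobic
PHE	CE1	Aromatic;Hydrophobic
PHE	CE2	Aromatic;Hydrophobic
PHE	CZ	Aromatic;Hydrophobic
TYR	CB	Hydrophobic
TYR	CG	Aromatic;Hydrophobic
TYR	CD1	Aromatic;Hydrophobic
TYR	CD2	Aromatic;Hydrophobic
TYR	CE1	Aromatic;Hydrophobic
TYR	CE2	Aromatic;Hydrophobic
TYR	CZ	Aromatic
TYR	OH	HydrogenDonor;HydrogenAcceptor
TRP	CB	Hydrophobic
TRP	CG	Aromatic;Hydrophobic
TRP	CD1	Aromatic
TRP	CD2	Aromatic;Hydrophobic
TRP	NE1	Aromatic;HydrogenDonor
TRP	CE2	Aromatic
TRP	CE3	Aromatic;Hydrophobic
TRP	CZ2	Aromatic;Hydrophobic
TRP	CZ3	Aromatic;Hydrophobic
TRP	CH2	Aromatic;Hydrophobic
SER	CB	Neutral
SER	OG	HydrogenDonor;HydrogenAcceptor
THR	CB	Neutral
THR	OG1	HydrogenDonor;HydrogenAcceptor
THR	CG2	Hydrophobic
ASN	CB	Hydrophobic
ASN	CG	Neutral
ASN	OD1	HydrogenAcceptor
ASN	ND2	HydrogenDonor
GLN	CB	Hydrophobic
GLN	CG	Hydrophobic
GLN	CD	Neutral
GLN	OE1	HydrogenAcceptor
GLN	NE2	HydrogenDonor
ASP	CB	Hydrophobic
ASP	CG	Neutral
ASP	OD1	NegativeIonizable;HydrogenAcceptor
ASP	OD2	NegativeIonizable;HydrogenAcceptor
GLU	CB	Hydrophobic
GLU	CG	Hydrophobic
GLU	CD	Neutral
GLU	OE1	NegativeIonizable;HydrogenAcceptor
GLU	OE2	NegativeIonizable;HydrogenAcceptor
LYS	CB	Hydrophobic
LYS	CG	Hydrophobic
LYS	CD	Hydrophobic
LYS	CE	Neutral
LYS	NZ	PositiveIonizable;HydrogenDonor
ARG	CB	Hydrophobic
ARG	CG	Hydrophobic
ARG	CD	Neutral
ARG	NE	PositiveIonizable;HydrogenDonor
ARG	CZ	PositiveIonizable
ARG	NH1	PositiveIonizable;HydrogenDonor
ARG	NH2	PositiveIonizable;HydrogenDonor
HIS	CB	Hydrophobic
HIS	CG	Aromatic
HIS	ND1	PositiveIonizable;Aromatic;HydrogenDonor;HydrogenAcceptor
HIS	CD2	Aromatic
HIS	CE1	Aromatic
HIS	NE2	PositiveIonizable;Aromatic;HydrogenDonor;HydrogenAcceptor
PRO	CB	Hydrophobic
PRO	CG	Hydrophobic
PRO	CD	Neutral
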