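# One-bead-per-residue HPS parameter set (Kapcha-Rossky hydropathy scale,
# Mittal-group normalization). sigma: van der Waals diameter (nm);
# lambda_hps: hydropathy in [0, 1] scaling the short-range attraction;
# charge: elementary charges at neutral pH (His carries +0.5);
# mass: residue mass (amu). type_class groups residues for contact
# aggregation: charged (C), hydrophobic (H, aromatics included), polar (P),
# other (O).
# version: 1.0
residue	name3	mass	charge	sigma	lambda_hps	type_class
A	ALA	71.08	0.0	0.504	0.730	hydrophobic
R	ARG	156.20	1.0	0.656	0.000	charged
N	ASN	114.10	0.0	0.568	0.432	polar
D	ASP	115.10	-1.0	0.558	0.378	charged
C	CYS	103.10	0.0	0.548	0.595	polar
Q	GLN	128.10	0.0	0.602	0.514	polar
E	GLU	129.10	-1.0	0.592	0.459	charged
G	GLY	57.05	0.0	0.450	0.649	other
H	HIS	137.10	0.5	0.608	0.514	charged
I	ILE	113.20	0.0	0.618	0.973	hydrophobic
L	LEU	113.20	0.0	0.618	0.973	hydrophobic
K	LYS	128.20	1.0	0.636	0.514	charged
M	MET	131.20	0.0	0.618	0.838	hydrophobic
F	PHE	147.20	0.0	0.636	1.000	hydrophobic
P	PRO	97.12	0.0	0.556	1.000	other
S	SER	87.08	0.0	0.518	0.595	polar
T	THR	101.10	0.0	0.562	0.676	polar
W	TRP	186.20	0.0	0.678	0.946	hydrophobic
Y	TYR	163.20	0.0	0.646	0.880	hydrophobic
V	VAL	99.07	0.0	0.586	0.892	hydrophobic
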