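# predblp physicochemical property table, version 1
# Nine residue-level scales used by the PCP feature block, one row per
# property, columns in the fixed alphabet ACDEFGHIKLMNPQRSTVWY.
# Sources: hydrophobicity = Kyte-Doolittle hydropathy; hydrophilicity =
# Hopp-Woods; polarity = Grantham; polarizability = Charton-Charton;
# transfer_free_energy = Janin (kcal/mol); solvent_contact_area = Chothia
# accessible surface area (A^2); positive_charge = side-chain charge
# indicator (His partial at physiological pH); flexibility =
# Bhaskaran-Ponnuswamy average flexibility.  protein_kinase_A is a
# CONSTRUCTED substrate-context propensity (S/T phosphoacceptors, R/K
# consensus recognition residues), shipped because no standard published
# residue scale exists under that name.  Substitute your own table with
# the same layout to change any scale.
property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydrophobicity	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
hydrophilicity	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
polarity	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
polarizability	0.046	0.128	0.105	0.151	0.290	0.000	0.230	0.186	0.219	0.186	0.221	0.134	0.131	0.180	0.291	0.062	0.108	0.140	0.409	0.298
transfer_free_energy	0.3	0.9	-0.6	-0.7	0.5	0.3	-0.1	0.7	-1.8	0.5	0.4	-0.5	-0.3	-0.7	-1.4	-0.1	-0.2	0.6	0.3	-0.4
solvent_contact_area	115	135	150	190	210	75	195	175	200	170	185	160	145	180	225	115	140	155	255	230
positive_charge	0.0	0.0	0.0	0.0	0.0	0.0	0.1	0.0	1.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0
flexibility	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.420
protein_kinase_A	0.10	0.05	0.05	0.05	0.05	0.15	0.10	0.05	0.50	0.10	0.05	0.10	0.10	0.10	0.90	1.00	0.80	0.05	0.05	0.10
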