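# base_sequence_factors v1
# Random-coil side-chain factors for base-catalyzed backbone-amide exchange,
# log10 scale, relative to poly-DL-alanine (alanine = 0 by definition).
# Source: Bai, Milne, Mayne & Englander, Proteins 17:75-86 (1993), Table 2
# (base-catalysis columns), including the N-terminal ammonium (NT) and
# C-terminal carboxylate (CT) corrections.
# Convention: the amide NH of residue i is multiplied by
# 10^(log_B_lambda(residue i-1) + log_B_rho(residue i)); NT adds to the
# lambda side of residue 2's amide, CT adds to the rho side of the last
# residue's amide.  D, E, H rows are the charged near-neutral forms;
# D+, E+, H+ are the protonated forms (selectable explicitly, not
# titrated automatically).  Proline has no backbone amide NH: its
# log_B_rho is NA and only its lambda (left-neighbor) entry is used.
# The published factors do not resolve the abstracting isotope, so the
# H_base and D_base rows carry identical values; the medium column is
# kept so isotope-resolved tables can drop in.
residue_code	log_B_lambda	log_B_rho	medium	notes
A	0.00	0.00	H_base	reference state
R	0.22	0.08	H_base
N	0.32	0.49	H_base
D	-0.18	-0.30	H_base	carboxylate (COO-)
D+	0.60	0.69	H_base	protonated (COOH)
C	0.55	0.62	H_base	reduced cysteine
E	-0.15	-0.51	H_base	carboxylate (COO-)
E+	0.39	0.24	H_base	protonated (COOH)
Q	0.20	0.06	H_base
G	0.17	0.27	H_base
H	0.14	-0.10	H_base	neutral imidazole
H+	0.83	0.80	H_base	imidazolium
I	-0.23	-0.73	H_base
L	-0.21	-0.58	H_base
K	0.12	-0.04	H_base
M	0.11	-0.01	H_base
F	0.06	-0.24	H_base
P	-0.24	NA	H_base	trans proline; no amide NH
S	0.30	0.37	H_base
T	0.20	-0.07	H_base
W	-0.11	-0.41	H_base
Y	0.05	-0.27	H_base
V	-0.14	-0.70	H_base
NT	1.62	NA	H_base	N-terminal ammonium, lambda side of residue 2
CT	NA	-1.80	H_base	C-terminal carboxylate, rho side of last residue
A	0.00	0.00	D_base	reference state
R	0.22	0.08	D_base
N	0.32	0.49	D_base
D	-0.18	-0.30	D_base	carboxylate (COO-)
D+	0.60	0.69	D_base	protonated (COOH)
C	0.55	0.62	D_base	reduced cysteine
E	-0.15	-0.51	D_base	carboxylate (COO-)
E+	0.39	0.24	D_base	protonated (COOH)
Q	0.20	0.06	D_base
G	0.17	0.27	D_base
H	0.14	-0.10	D_base	neutral imidazole
H+	0.83	0.80	D_base	imidazolium
I	-0.23	-0.73	D_base
L	-0.21	-0.58	D_base
K	0.12	-0.04	D_base
M	0.11	-0.01	D_base
F	0.06	-0.24	D_base
P	-0.24	NA	D_base	trans proline; no amide NH
S	0.30	0.37	D_base
T	0.20	-0.07	D_base
W	-0.11	-0.41	D_base
Y	0.05	-0.27	D_base
V	-0.14	-0.70	D_base
NT	1.62	NA	D_base	N-terminal ammonium, lambda side of residue 2
CT	NA	-1.80	D_base	C-terminal carboxylate, rho side of last residue
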