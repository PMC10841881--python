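# Transcribed round metadata: 37 targets, five categories (I-V), with
# oligomer class and assessment-unit membership. Size (residues) and BSA
# (A^2) are inert metadata, stored as printed ('/' separates chains,
# '-' marks a printed range); they are never recomputed.
capri_id	casp_id	category	kingdom	size	bsa	name	oligomer_class	au_ids
T198	T1123	I	V	266	1570	Capsid polyprotein VP90	homodimer	T198
T201	T1132	I	B	102	1125	Antibiotic biosynthesis monooxygenase	homodimer	T201
T211	T1153	I	E	299	550	Endonuclease/exonuclease/phosphatase family domain-containing protein 1	homodimer	T211
T225	T1178	I	V	306	3715	Unannotated viral protein	homodimer	T225
T226	T1179	I	V	261	1830	Unannotated viral protein	homodimer	T226
T229	T1187	I	E	166	935	Nictaba	homodimer	T229
T192	T1109	II	B	227	2100	Putative transcription regulator protein (D180A)	homodimer	T192
T193	T1110	II	B	227	2265	Putative transcription regulator protein	homodimer	T193
T194	T1113	II	V	193	2750	Uncharacterized protein	homodimer	T194
T197	T1121	II	B	381	1420	DUF3322 and DUF2220 domain-containing protein	homodimer	T197
T199	T1127	II	E	211	3355	L-ornithine N5-acetyltransferase NATA1	homodimer	T199
T213	T1160	II	designed	48	1080	Designed protein	homodimer	T213
T214	T1161	II	designed	48	1845	Designed protein	homodimer	T214
T222	T1173	II	B	204	2015	Cell wall surface anchor family protein	homotrimer	T222
T223	T1174	II	B	338	5715	Uncharacterized protein	homotrimer	T223
T224	T1176	II	B	170	5700	Hypothetical protein	homodimer	T224
T227	T1181	II	V	688	4940	Tail fiber protein	homotrimer	T227
T191	H1106	III	B	122/114	1440	Yop proteins translocation protein; Chaperone protein	heterodimer	T191
T200	H1129	III	V	747/640	2040	Ferrichrome outer membrane transporter; Receptor-binding protein pb5	heterodimer	T200
T202	H1134	III	B	230/313	2000	Ankyrin repeat domain-containing protein; Phospholipase	heterodimer	T202
T210	H1151	III	B	112/116	740	RNA polymerase sigma factor SigA; Transcriptional regulator WhiB6	heterodimer	T210
T212	H1157	III	E	1029/495	2250	Alpha-1,2-mannosidase; Protein disulphide-isomerase	heterodimer	T212
T205	H1140	IV	E	219/132	775	CNPase + Nb	heterodimer	T205
T206	H1141	IV	E	219/217	925	CNPase + Nb7e	heterodimer	T206
T207	H1142	IV	E	219/128	585	CNPase + Nb8c	heterodimer	T207
T208	H1143	IV	E	219/131	770	CNPase + Nb10e	heterodimer	T208
T209	H1144	IV	E	219/122	895	CNPase + Nb8d	heterodimer	T209
T216	H1166	IV	E	130/216/231	1690	Coronavirus nucleocapsid + S24-188 Fab	heterodimer	T216
T217	H1167	IV	E	130/212/218	1600	Coronavirus nucleocapsid + S24-188 Fab	heterodimer	T217
T218	H1168	IV	E	130/215/222	1820	Coronavirus nucleocapsid + S24-188 Fab	heterodimer	T218
T195	T1115	V	E	288	3350	Stomatin	large	T195
T203	H1135	V	E	195/25	550-1100	SUN domain-containing protein 1; IRAG2 peptide	large	AU203.1;AU203.2
T204	H1137	V	unannotated	266-653	750-6500	ABC transporter / MlaD hexamer assembly	large	AU204.1;AU204.2
T219	T1170	V	B	318	1900	RuvB	large	AU219
T220	H1171	V	B	318/48	1900/680	RuvB; RuvA	large	AU219;AU220
T221	H1172	V	B	318/48	1900/640	RuvB; RuvA	large	AU219;AU220
T230	T1192	V	E	418	2225	DNA repair protein RAD52 homolog	large	T230
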