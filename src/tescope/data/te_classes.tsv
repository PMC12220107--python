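# family	te_class
# Editable classification map: repeat family name -> major TE class.
# Classes: DNA, LINE, SINE, LTR, RC, Unknown, non-TE.
hAT-Ac	DNA
hAT-Charlie	DNA
hAT-hATm	DNA
hAT-Tip100	DNA
hAT-hAT5	DNA
hAT-Blackjack	DNA
hAT-Tag1	DNA
TcMar-Tc1	DNA
TcMar-Tc2	DNA
TcMar-Fot1	DNA
TcMar-Mariner	DNA
TcMar-Pogo	DNA
Maverick	DNA
Sola-2	DNA
Sola-1	DNA
Sola-3	DNA
MULE-MuDR	DNA
MULE-NOF	DNA
CMC-EnSpm	DNA
CMC-Transib	DNA
CMC-Chapaev	DNA
CMC-Chapaev-3	DNA
PIF-Harbinger	DNA
PiggyBac	DNA
Merlin	DNA
P	DNA
Ginger	DNA
Kolobok	DNA
Zisupton	DNA
Academ	DNA
Dada	DNA
IS3EU	DNA
Crypton	DNA
CR1	LINE
L1	LINE
L2	LINE
RTE	LINE
RTE-BovB	LINE
RTE-X	LINE
Rex-Babar	LINE
Jockey	LINE
I	LINE
I-Jockey	LINE
Penelope	LINE
Dong-R4	LINE
Proto2	LINE
Tad1	LINE
R2	LINE
CRE	LINE
Gypsy	LTR
Gypsy-12_family	LTR
Copia	LTR
Pao	LTR
Ngaro	LTR
DIRS	LTR
ERV1	LTR
ERVK	LTR
ERVL	LTR
Cassandra	LTR
Alu	SINE
MIR	SINE
tRNA	SINE
tRNA-Deu	SINE
tRNA-RTE	SINE
5S-Deu-L2	SINE
ID	SINE
B4	SINE
Helitron	RC
Helitron-2	RC
Simple_repeat	non-TE
Low_complexity	non-TE
Satellite	non-TE
rRNA	non-TE
snRNA	non-TE
tRNA-gene	non-TE
scRNA	non-TE
ARTEFACT	non-TE
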