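# Synthetic reconstruction of the 23-haplogroup Y tree used for
# hierarchical assignment.  Built from the printed haplogroup/diagnostic-SNP
# table and ISOGG-2016 nomenclature, not from the original figure; internal
# scaffold nodes carry markers from the genotyped 104-marker list.
# Columns: node name <TAB> parent ('-' for root) <TAB> comma-separated markers.
Y	-	-
CT	Y	M168,M294
CF-P143	CT	P143
C-M130	CF-P143	M130
C-M356	C-M130	M356
C-M217	C-M130	M217
D-M174	CT	M174
D-M15	D-M174	M15
E-M96	CT	M96
E-P173	E-M96	P173
H-M52	CF-P143	M69,M52
J-M304	CF-P143	M304
J-M172	J-M304	M172
K-P128	CF-P143	M9,P128
L-M76	K-P128	M11,M20,M76
NO-P195	K-P128	M214,P195
N-M231	NO-P195	M231
O1a-M119	NO-P195	M119
O-P203	O1a-M119	P203
O-M50	O1a-M119	M50
O1b-M95	NO-P195	M95
O-PK4	O1b-M95	PK4
O-M111	O-PK4	M111
O-M88	O-PK4	M88
O-M122	NO-P195	M122
O-M324	O-M122	M324
O-M7	O-M324	M7
O-M134	O-M324	M134
O-M117	O-M134	M117
P-M45	K-P128	M45
R-M306	P-M45	M306
R-M173	R-M306	M173
R-P249	R-M306	M124,P249
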