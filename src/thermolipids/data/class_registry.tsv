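class_label	domain	core_type	registry_order
G-AR	archaeal	AR_diether	1
G-GDGT	archaeal	GDGT	2
2G-GDGT	archaeal	GDGT	3
G-Uns-GDGT	archaeal	GDGT	4
G-Me-GDGT	archaeal	GDGT	5
G-2Me-GDGT	archaeal	GDGT	6
2G-Me-GDGT	archaeal	GDGT	7
2G-2Me-GDGT	archaeal	GDGT	8
G-H-GDGT	archaeal	H_GDGT	9
2G-H-GDGT	archaeal	H_GDGT	10
G-H-1Me-GDGT	archaeal	H_GDGT	11
G-H-2Me-GDGT	archaeal	H_GDGT	12
G-H-3Me-GDGT	archaeal	H_GDGT	13
G-H-4Me-GDGT	archaeal	H_GDGT	14
2G-H-1Me-GDGT	archaeal	H_GDGT	15
2G-H-2Me-GDGT	archaeal	H_GDGT	16
2G-H-3Me-GDGT	archaeal	H_GDGT	17
G	nonarchaeal	DAG	18
SQ	nonarchaeal	DAG	19
2G	nonarchaeal	DAG	20
BL	nonarchaeal	DAG	21
OL	nonarchaeal	DAG	22
PDME	nonarchaeal	DAG	23
PME	nonarchaeal	DAG	24
PE	nonarchaeal	DAG	25
PG	nonarchaeal	DAG	26
PC	nonarchaeal	DAG	27
CL	nonarchaeal	DAG	28
sPA	nonarchaeal	ceramide	29
sP-Uk1	nonarchaeal	ceramide	30
sP-Uk2	nonarchaeal	ceramide	31
sP-Uk3	nonarchaeal	ceramide	32
sP-Uk4	nonarchaeal	ceramide	33
sPI	nonarchaeal	ceramide	34
sPE	nonarchaeal	ceramide	35
sPG	nonarchaeal	ceramide	36
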