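locus	allele	position	residue
DRB1	01:01	13	F
DRB1	01:01	16	H
DRB1	01:01	70	Q
DRB1	01:01	71	R
DRB1	01:01	72	R
DRB1	01:01	73	A
DRB1	01:01	74	A
DRB1	01:01	86	G
DRB1	03:01	13	S
DRB1	03:01	16	H
DRB1	03:01	70	Q
DRB1	03:01	71	K
DRB1	03:01	72	R
DRB1	03:01	73	G
DRB1	03:01	74	R
DRB1	03:01	86	G
DRB1	04:01	13	H
DRB1	04:01	16	H
DRB1	04:01	70	Q
DRB1	04:01	71	K
DRB1	04:01	72	R
DRB1	04:01	73	A
DRB1	04:01	74	A
DRB1	04:01	86	G
DRB1	04:03	13	H
DRB1	04:03	16	H
DRB1	04:03	70	Q
DRB1	04:03	71	R
DRB1	04:03	72	R
DRB1	04:03	73	A
DRB1	04:03	74	E
DRB1	04:03	86	G
DRB1	04:04	13	H
DRB1	04:04	16	H
DRB1	04:04	70	Q
DRB1	04:04	71	R
DRB1	04:04	72	R
DRB1	04:04	73	A
DRB1	04:04	74	A
DRB1	04:04	86	V
DRB1	04:05	13	H
DRB1	04:05	16	H
DRB1	04:05	70	Q
DRB1	04:05	71	R
DRB1	04:05	72	R
DRB1	04:05	73	A
DRB1	04:05	74	A
DRB1	04:05	86	G
DRB1	04:06	13	H
DRB1	04:06	16	H
DRB1	04:06	70	Q
DRB1	04:06	71	R
DRB1	04:06	72	R
DRB1	04:06	73	A
DRB1	04:06	74	E
DRB1	04:06	86	G
DRB1	04:07	13	H
DRB1	04:07	16	H
DRB1	04:07	70	Q
DRB1	04:07	71	R
DRB1	04:07	72	R
DRB1	04:07	73	A
DRB1	04:07	74	E
DRB1	04:07	86	G
DRB1	04:10	13	H
DRB1	04:10	16	H
DRB1	04:10	70	Q
DRB1	04:10	71	R
DRB1	04:10	72	R
DRB1	04:10	73	A
DRB1	04:10	74	A
DRB1	04:10	86	G
DRB1	07:01	13	Y
DRB1	07:01	16	H
DRB1	07:01	70	D
DRB1	07:01	71	R
DRB1	07:01	72	R
DRB1	07:01	73	G
DRB1	07:01	74	Q
DRB1	07:01	86	G
DRB1	08:02	13	G
DRB1	08:02	16	Y
DRB1	08:02	70	D
DRB1	08:02	71	R
DRB1	08:02	72	R
DRB1	08:02	73	A
DRB1	08:02	74	L
DRB1	08:02	86	G
DRB1	08:03	13	G
DRB1	08:03	16	Y
DRB1	08:03	70	D
DRB1	08:03	71	R
DRB1	08:03	72	R
DRB1	08:03	73	A
DRB1	08:03	74	L
DRB1	08:03	86	G
DRB1	08:23	13	G
DRB1	08:23	16	Y
DRB1	08:23	70	D
DRB1	08:23	71	R
DRB1	08:23	72	R
DRB1	08:23	73	A
DRB1	08:23	74	L
DRB1	08:23	86	G
DRB1	09:01	13	Y
DRB1	09:01	16	H
DRB1	09:01	70	R
DRB1	09:01	71	R
DRB1	09:01	72	R
DRB1	09:01	73	A
DRB1	09:01	74	E
DRB1	09:01	86	G
DRB1	10:01	13	F
DRB1	10:01	16	H
DRB1	10:01	70	R
DRB1	10:01	71	R
DRB1	10:01	72	R
DRB1	10:01	73	A
DRB1	10:01	74	A
DRB1	10:01	86	G
DRB1	11:01	13	S
DRB1	11:01	16	H
DRB1	11:01	70	D
DRB1	11:01	71	R
DRB1	11:01	72	R
DRB1	11:01	73	A
DRB1	11:01	74	A
DRB1	11:01	86	G
DRB1	12:01	13	S
DRB1	12:01	16	H
DRB1	12:01	70	D
DRB1	12:01	71	R
DRB1	12:01	72	R
DRB1	12:01	73	A
DRB1	12:01	74	A
DRB1	12:01	86	G
DRB1	12:02	13	S
DRB1	12:02	16	H
DRB1	12:02	70	D
DRB1	12:02	71	R
DRB1	12:02	72	R
DRB1	12:02	73	A
DRB1	12:02	74	A
DRB1	12:02	86	G
DRB1	13:01	13	S
DRB1	13:01	16	H
DRB1	13:01	70	D
DRB1	13:01	71	E
DRB1	13:01	72	R
DRB1	13:01	73	A
DRB1	13:01	74	A
DRB1	13:01	86	G
DRB1	13:02	13	S
DRB1	13:02	16	H
DRB1	13:02	70	D
DRB1	13:02	71	E
DRB1	13:02	72	R
DRB1	13:02	73	A
DRB1	13:02	74	A
DRB1	13:02	86	V
DRB1	14:02	13	S
DRB1	14:02	16	H
DRB1	14:02	70	Q
DRB1	14:02	71	R
DRB1	14:02	72	R
DRB1	14:02	73	A
DRB1	14:02	74	A
DRB1	14:02	86	G
DRB1	14:03	13	S
DRB1	14:03	16	H
DRB1	14:03	70	Q
DRB1	14:03	71	R
DRB1	14:03	72	R
DRB1	14:03	73	A
DRB1	14:03	74	E
DRB1	14:03	86	G
DRB1	14:05	13	S
DRB1	14:05	16	H
DRB1	14:05	70	R
DRB1	14:05	71	R
DRB1	14:05	72	R
DRB1	14:05	73	A
DRB1	14:05	74	E
DRB1	14:05	86	V
DRB1	14:06	13	S
DRB1	14:06	16	H
DRB1	14:06	70	Q
DRB1	14:06	71	R
DRB1	14:06	72	R
DRB1	14:06	73	A
DRB1	14:06	74	A
DRB1	14:06	86	G
DRB1	14:07	13	S
DRB1	14:07	16	H
DRB1	14:07	70	Q
DRB1	14:07	71	R
DRB1	14:07	72	R
DRB1	14:07	73	A
DRB1	14:07	74	E
DRB1	14:07	86	G
DRB1	14:54	13	S
DRB1	14:54	16	H
DRB1	14:54	70	R
DRB1	14:54	71	R
DRB1	14:54	72	R
DRB1	14:54	73	A
DRB1	14:54	74	E
DRB1	14:54	86	G
DRB1	15:01	13	R
DRB1	15:01	16	H
DRB1	15:01	70	Q
DRB1	15:01	71	A
DRB1	15:01	72	R
DRB1	15:01	73	A
DRB1	15:01	74	A
DRB1	15:01	86	V
DRB1	15:02	13	R
DRB1	15:02	16	H
DRB1	15:02	70	Q
DRB1	15:02	71	A
DRB1	15:02	72	R
DRB1	15:02	73	A
DRB1	15:02	74	A
DRB1	15:02	86	G
DRB1	16:02	13	R
DRB1	16:02	16	H
DRB1	16:02	70	Q
DRB1	16:02	71	A
DRB1	16:02	72	R
DRB1	16:02	73	A
DRB1	16:02	74	A
DRB1	16:02	86	G
DQB1	02:01	87	F
DQB1	03:01	87	F
DQB1	03:02	87	F
DQB1	03:03	87	F
DQB1	03:06	87	F
DQB1	04:01	87	F
DQB1	04:02	87	F
DQB1	05:01	87	F
DQB1	05:02	87	L
DQB1	05:03	87	F
DQB1	06:01	87	L
DQB1	06:02	87	F
DQB1	06:03	87	F
DQB1	06:04	87	F
DQB1	06:09	87	F
DPB1	01:01	35	Y
DPB1	01:01	55	D
DPB1	01:01	56	A
DPB1	01:01	84	D
DPB1	01:01	85	E
DPB1	01:01	86	A
DPB1	01:01	87	V
DPB1	01:01	96	K
DPB1	02:01	35	Y
DPB1	02:01	55	E
DPB1	02:01	56	A
DPB1	02:01	84	G
DPB1	02:01	85	G
DPB1	02:01	86	P
DPB1	02:01	87	M
DPB1	02:01	96	K
DPB1	02:02	35	Y
DPB1	02:02	55	E
DPB1	02:02	56	A
DPB1	02:02	84	G
DPB1	02:02	85	G
DPB1	02:02	86	P
DPB1	02:02	87	M
DPB1	02:02	96	K
DPB1	03:01	35	Y
DPB1	03:01	55	D
DPB1	03:01	56	A
DPB1	03:01	84	D
DPB1	03:01	85	E
DPB1	03:01	86	A
DPB1	03:01	87	V
DPB1	03:01	96	K
DPB1	04:01	35	Y
DPB1	04:01	55	D
DPB1	04:01	56	A
DPB1	04:01	84	G
DPB1	04:01	85	G
DPB1	04:01	86	P
DPB1	04:01	87	M
DPB1	04:01	96	K
DPB1	04:02	35	Y
DPB1	04:02	55	D
DPB1	04:02	56	A
DPB1	04:02	84	G
DPB1	04:02	85	G
DPB1	04:02	86	P
DPB1	04:02	87	M
DPB1	04:02	96	K
DPB1	05:01	35	F
DPB1	05:01	55	A
DPB1	05:01	56	E
DPB1	05:01	84	D
DPB1	05:01	85	E
DPB1	05:01	86	A
DPB1	05:01	87	V
DPB1	05:01	96	R
DPB1	06:01	35	Y
DPB1	06:01	55	D
DPB1	06:01	56	A
DPB1	06:01	84	D
DPB1	06:01	85	E
DPB1	06:01	86	A
DPB1	06:01	87	V
DPB1	06:01	96	K
DPB1	09:01	35	Y
DPB1	09:01	55	D
DPB1	09:01	56	A
DPB1	09:01	84	D
DPB1	09:01	85	E
DPB1	09:01	86	A
DPB1	09:01	87	V
DPB1	09:01	96	R
DPB1	13:01	35	Y
DPB1	13:01	55	D
DPB1	13:01	56	A
DPB1	13:01	84	D
DPB1	13:01	85	E
DPB1	13:01	86	A
DPB1	13:01	87	V
DPB1	13:01	96	K
DPB1	14:01	35	Y
DPB1	14:01	55	D
DPB1	14:01	56	A
DPB1	14:01	84	D
DPB1	14:01	85	E
DPB1	14:01	86	A
DPB1	14:01	87	V
DPB1	14:01	96	K
DPB1	17:01	35	Y
DPB1	17:01	55	D
DPB1	17:01	56	A
DPB1	17:01	84	D
DPB1	17:01	85	E
DPB1	17:01	86	A
DPB1	17:01	87	V
DPB1	17:01	96	K
DPB1	19:01	35	Y
DPB1	19:01	55	D
DPB1	19:01	56	A
DPB1	19:01	84	D
DPB1	19:01	85	E
DPB1	19:01	86	A
DPB1	19:01	87	V
DPB1	19:01	96	K
DPB1	38:01	35	F
DPB1	38:01	55	A
DPB1	38:01	56	E
DPB1	38:01	84	D
DPB1	38:01	85	E
DPB1	38:01	86	A
DPB1	38:01	87	V
DPB1	38:01	96	R
DPB1	41:01	35	Y
DPB1	41:01	55	D
DPB1	41:01	56	A
DPB1	41:01	84	D
DPB1	41:01	85	E
DPB1	41:01	86	A
DPB1	41:01	87	V
DPB1	41:01	96	K
DPB1	47:01	35	Y
DPB1	47:01	55	D
DPB1	47:01	56	A
DPB1	47:01	84	D
DPB1	47:01	85	E
DPB1	47:01	86	A
DPB1	47:01	87	V
DPB1	47:01	96	K
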