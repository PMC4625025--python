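protein	substrate	SDP1	SDP2	SDP3	SDP4	SDP5	SDP6	SDP7	SDP8	SDP9
RcTIP2;2	NH3	T	K	T	V	A	S	A	P	S
RcNIP1;1	NH3	F	K	F	T	A	D	L	E	T
RcPIP1;1	boric acid	T	I	H	P	E	L	L	T	P
RcPIP1;2	boric acid	T	I	H	P	E	L	L	T	P
RcPIP1;3	boric acid	T	I	H	P	E	L	L	T	P
RcPIP1;4	boric acid	T	I	H	P	E	L	L	T	P
RcPIP1;5	boric acid	T	I	H	P	E	L	L	T	P
RcNIP5;1	boric acid	T	I	H	P	E	L	L	A	P
RcPIP1;1	CO2	V	M	C	A	I	D	W	D	W
RcPIP1;3	CO2	L	M	C	A	I	D	W	D	W
RcPIP1;4	CO2	L	M	C	A	I	D	W	D	W
RcPIP1;5	CO2	I	M	C	A	V	D	W	D	W
RcPIP2;2	CO2	I	M	C	A	V	D	W	D	W
RcPIP2;4	CO2	V	M	C	A	V	D	W	D	W
RcPIP1;1	H2O2	A	G	V	L	I	H	F	V	P
RcPIP1;2	H2O2	A	G	V	F	I	H	F	V	P
RcPIP1;3	H2O2	A	G	V	F	I	H	F	V	P
RcPIP1;4	H2O2	A	G	V	F	I	H	F	V	P
RcPIP1;5	H2O2	A	G	V	F	I	H	F	V	P
RcPIP2;1	H2O2	A	G	V	F	I	Q	F	V	P
RcPIP2;2	H2O2	A	G	V	F	I	Q	F	V	P
RcPIP2;3	H2O2	A	G	V	F	I	Q	F	V	P
RcPIP2;4	H2O2	A	G	V	F	I	H	F	V	P
RcPIP2;5	H2O2	A	G	V	F	I	H	F	V	P
RcTIP5;1	H2O2	S	A	L	A	I	Q	Y	V	P
RcNIP2;1	H2O2	A	A	L	L	V	I	Y	V	P
RcNIP3;1	H2O2	S	A	L	L	I	L	F	V	P
RcNIP4;2	H2O2	S	A	L	V	V	L	Y	V	P
RcNIP5;1	H2O2	S	A	L	V	V	L	Y	V	P
RcXIP1;1	H2O2	A	G	L	V	S	H	F	V	P
RcXIP1;2	H2O2	A	G	L	V	S	H	F	V	P
RcXIP1;3	H2O2	A	A	L	V	S	H	F	V	P
RcNIP2;1	silicic acid	S	F	V	H	G	N	R	T	Q
RcPIP1;1	urea	H	P	F	F	L	P	G	G	N
RcPIP1;2	urea	H	P	F	F	L	P	G	G	N
RcPIP1;3	urea	H	P	F	F	L	P	G	G	N
RcPIP1;4	urea	H	P	F	F	L	P	G	G	N
RcPIP1;5	urea	H	P	F	L	L	P	G	G	N
RcPIP2;1	urea	H	P	L	F	L	P	G	G	N
RcPIP2;2	urea	H	P	F	F	L	P	G	G	N
RcPIP2;3	urea	H	P	F	F	L	P	G	G	N
RcPIP2;4	urea	H	P	F	F	L	P	G	G	N
RcPIP2;5	urea	H	P	F	L	L	P	G	G	N
RcTIP1;1	urea	H	P	F	F	L	A	G	S	N
RcTIP1;2	urea	H	P	F	F	L	A	G	S	N
RcTIP1;3	urea	H	P	F	F	L	A	G	S	N
RcTIP1;4	urea	H	P	F	F	L	A	G	S	N
RcTIP2;1	urea	H	P	F	A	L	P	G	S	N
RcTIP2;2	urea	H	P	F	A	L	P	G	S	N
RcTIP3;1	urea	H	P	F	L	L	P	G	S	N
RcTIP4;1	urea	H	P	L	L	L	P	G	S	N
RcTIP5;1	urea	H	P	F	A	L	P	G	S	N
RcNIP1;1	urea	H	P	L	A	L	P	G	S	N
RcNIP2;1	urea	H	P	T	A	M	P	G	S	N
RcNIP3;1	urea	H	P	I	A	L	P	G	S	N
RcNIP4;1	urea	H	P	I	A	L	P	G	S	N
RcNIP5;1	urea	H	P	I	A	L	P	G	S	N
RcNIP6;1	urea	H	P	I	A	L	E	G	S	N
RcNIP7;1	urea	H	P	I	A	M	P	G	S	N
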