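population	clone_nt	A	C	G	T
unselected	A	23656	18	27	182
unselected	C	65	18045	1	184
unselected	G	282	4	11176	29
unselected	T	270	29	19	15439
selected	A	24024	11	12	80
selected	C	24	18058	1	72
selected	G	154	0	11203	9
selected	T	71	27	7	15673
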