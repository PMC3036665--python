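COI	H7	H8a-e	H4	H5	H6	H1	H2	H3
H7	-
H8a-e	0,019	0,005
H4	0,188	0,184	-
H5	0,197	0,200	0,023	-
H6	0,165	0,161	0,032	0,040	-
H1	0,148	0,149	0,055	0,059	0,024	-
H2	0,147	0,145	0,039	0,042	0,013	0,022	-
H3	0,155	0,155	0,040	0,045	0,014	0,023	0,014	-
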