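28S	H7	H8	H4	H5	H6	H1	H2	H3
H7	-
H8	0,001	-
H4	0,033	0,031	-
H5	0,028	0,026	0,001	-
H6	0,026	0,024	0,007	0,004	-
H1	0,020	0,019	0,012	0,010	0,008	-
H2	0,023	0,021	0,012	0,010	0,010	0,005	-
H3	0,020	0,019	0,009	0,006	0,005	0,003	0,005	-
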