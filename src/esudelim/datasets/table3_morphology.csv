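specimen,locality,large_style,tornotes,acanthostrongyle,chela,esu
M2004-02,ROC,smooth,fusiform,truncate,<30,H8
M2004-03,ROC,smooth,fusiform,truncate,<30,H8
P2,ROC,smooth,fusiform,truncate,<30,H8
P3,ROC,smooth,fusiform,truncate,<30,H8
P4,ROC,smooth,fusiform,truncate,<30,H8
P11,ROC,smooth,fusiform,truncate,<30,H8
P14,ROC,smooth,fusiform,truncate,<30,H8
B05-01,ROC,smooth,fusiform,truncate,<30,H8
P9,POR,smooth,fusiform,truncate,<30,H8
P10 a,POR,smooth,fusiform,truncate,<30,H8
P23 a,MIN,smooth,fusiform,truncate,<30,H8
P25,MIN,smooth,fusiform,truncate,<30,H8
P29a,MIN,smooth,fusiform,truncate,<30,H8
P30d,MIN,smooth,fusiform,truncate,<30,H8
P31,MIN,smooth,fusiform,truncate,<30,H8
P32b,MIN,smooth,fusiform,truncate,<30,H8
B06-03,MIN,smooth,fusiform,truncate,<30,H8
B06-04,MIN,smooth,fusiform,truncate,<30,H8
B06-05,MIN,smooth,fusiform,truncate,<30,H8
B06-06,MIN,smooth,fusiform,truncate,<30,H8
B07-05,SKA,smooth,fusiform,truncate,<30,H8
B07-06,SKA,smooth,fusiform,truncate,<30,H8
B07-07,SKA,smooth,fusiform,truncate,<30,H8
B07-08,SKA,smooth,fusiform,truncate,<30,H8
B07-09,SKA,smooth,fusiform,truncate,<30,H8
P22c,SKA,smooth,fusiform,truncate,<30,H8
P6,CAD,smooth,fusiform,truncate,>30,H8
P5,ROC,smooth,fusiform,truncate,<30,H7
P12,ROC,smooth,fusiform,truncate,<30,H7
B07-03,SKA,spined,tylote,simple shape,<30,H6
B07-04,SKA,spined,tylote,simple shape,<30,H6
B07-10,SKA,spined,tylote,simple shape,<30,H6
MC3539,ire,spined,tylote,simple shape,<30,H6
MC4049,ire,spined,tylote,simple shape,<30,H6
P28,MIN,spined,mucronate,simple shape,<30,H5
P29c,MIN,spined,mucronate,simple shape,<30,H5
B06-07,MIN,spined,mucronate,simple shape,<30,H5
MC3992,ire,spined,mucronate,simple shape,<30,H5
MC3982,ire,spined,mucronate,simple shape,<30,H5
MC3983,ire,spined,mucronate,simple shape,<30,H5
P20b,SKA,spined,mucronate,simple shape,>30,H4
B07-01,SKA,spined,mucronate,simple shape,>30,H4
BER82-01,BER,spined,mucronate,simple shape,>30,H4
CPOR08-01,CAD,spined,tylote,simple shape,>30,H3
P8,CAD,spined,tylote,simple shape,>30,H2
P7,CAD,spined,tylote,simple shape,>30,H1
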