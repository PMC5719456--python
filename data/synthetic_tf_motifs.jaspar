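>SYN0001.1 PU1_ETS_synthetic
A [  2 90  2  2  2  2  2  4  4 ]
C [ 90  4 90  2  2 90 90 45 45 ]
G [  4  2  4  2  2  2  2  2  2 ]
T [  4  4  4 94 94  6  6 49 49 ]
>SYN0002.1 AP1_FosJun_synthetic
A [  2  2 90 45  2  2 90 ]
C [  2  2  4  2  2 90  4 ]
G [  4 90  4  2  4  4  4 ]
T [ 92  6  2 51 92  4  2 ]
>SYN0003.1 CEBP_synthetic
A [  2  2  4  2  4  2 90 90 ]
C [  4  4  4 90  4 92  4  4 ]
G [  2  2 88  4 88  2  4  4 ]
T [ 92 92  4  4  4  4  2  2 ]
>SYN0004.1 RUNX_synthetic
A [  2  2  2  4  4  2  2  2 ]
C [  4  2  4  2  2  4  4  4 ]
G [  2 92  2 90 90  2  2  2 ]
T [ 92  4 92  4  4 92 92 92 ]
>SYN0005.1 KLF_synthetic
A [  2  2  2  2 88  2  2  2  2 ]
C [  4  4  4  4  4  4  4  4  4 ]
G [ 92 92 92 92  6 92 92 92 92 ]
T [  2  2  2  2  2  2  2  2  2 ]
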