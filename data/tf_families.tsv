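# matrix_id	family	macrophage_expressed
# Synthetic position-frequency matrices built from published consensus
# motifs of macrophage-relevant transcription-factor families; edit or
# replace with real database matrices and their ids as needed.
SYN0001.1	ETS	yes
SYN0002.1	AP1	yes
SYN0003.1	CEBP	yes
SYN0004.1	RUNX	yes
SYN0005.1	KLF	yes
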