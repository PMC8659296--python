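>SYN0001 brZ4_like_synthetic
A [ 2 1 17 14 2 3 16 4 2 12 ]
C [ 1 1 1 1 0 1 1 1 2 3 ]
G [ 1 2 1 1 1 0 2 1 2 2 ]
T [ 16 16 1 4 17 16 1 14 14 3 ]
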