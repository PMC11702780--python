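>synthetic_pseudoexon_202bp frame_offset=0 planted_stop_codons=2
ATGAGTTACTCTGATTAGACCCCACGGGCCCTCCAAAGCGGGGTAAACACGCGTCCTTGC
CTTCGCCGGGGAGATAGGGTCGTGTTCGTTCACCATGCTGCTGGGTCTCACTTAAAAACA
TTGTTACAGAGACATAAGTGCGGAGATATGCTAAGTGTTTAGAACATTGGTCTTCCGATT
ACCGCCGGACTTTGTTGTATAA
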