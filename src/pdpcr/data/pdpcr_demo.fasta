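>template
GCGCGCATGCATGTGACTGACGATCGATCGATCAGTACTGACTGACAAATGACTGGATCC
GGGAAGCTTGTGTTTAAAGTGTGAGGGTTGGCTGGGGTGTGGGGGTGGATGGGTAGCCGC
>PCR-1
GCGGCTACCCATCCACCCCCAC
>PCR-2
GCGCGCATGCATGTGACTGAC
>PD-PCR-1
CGCGCGTACGTACACTGACTGC
>PD-PCR-2
CGCCGATGGGTAGGTGGGGG
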