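>NFI_full NFI_full
A [    5    5    5    5   85   25   25   25    5    5    5    5   85 ]
C [    5    5    5   85    5   25   25   25    5    5   85   85    5 ]
G [    5   85   85    5    5   25   25   25    5   85    5    5    5 ]
T [   85    5    5    5    5   25   25   25   85    5    5    5    5 ]
>NFI_half_TGCCAA NFI_half_TGCCAA
A [    5    5    5    5   85   85 ]
C [    5    5   85   85    5    5 ]
G [    5   85    5    5    5    5 ]
T [   85    5    5    5    5    5 ]
>NFI_half_GCCAA NFI_half_GCCAA
A [    5    5    5   85   85 ]
C [    5   85   85    5    5 ]
G [   85    5    5    5    5 ]
T [    5    5    5    5    5 ]
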