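>YP_009664501.1 uracil-DNA glycosylase inhibitor Ugi [Bacillus phage PBS1]
MTNLSDIIEKETGKQLVIQESILMLPEEVEEVIGNKPESDILVHTAYDESTDENVMLLTS
DAPEYKPWALVIQDSNGENKIKML
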