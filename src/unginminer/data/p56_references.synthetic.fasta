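>P56_PZA_standin synthetic stand-in for p56 (NP_040721.1, Bacillus phage PZA); constructed, not the native sequence
MKWNEKSTNALAVLILMAFESKYDGQLLDDIGEMFVDSYTDEEIVFNKEQPEMFMS
>P56_VMY22_standin synthetic stand-in for VMY22 p56 (Gene ID 26625151, Bacillus phage VMY22); constructed, not the native sequence
MFDALLLMDYLLPAKVALDGWEQTYGEVMLFFVAEAWLDSYIMLAEAIHLADPVEAES
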