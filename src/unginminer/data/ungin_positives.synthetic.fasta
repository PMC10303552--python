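>UGI2_standin synthetic stand-in for Ugi-2 (ALN97938, Bacillus phage vB_BpuM-BpSp); constructed, not the native sequence
MNFNSVDATMNDQLDAKEQEAILMLPEDLEEIEEPLNVLITLDNKICHSTSLLAYAVLAV
DYAIKWDLEKELLAIIKSENETDEHDMA
>SAUGI_standin synthetic stand-in for SAUGI (UniProtKB Q936H5, Staphylococcus aureus); constructed, not the native sequence
MNWQVNIMSVYSGTEWELVAVMMECESIEEIFGTEDEWAADDSSMVLTKILMAVVFQLLG
VSLPKDMIALKTVTEGDAMLNLHVDKMQMVTHETPKSLTFNVDTIQNAVMVM
>MCUGI1_standin synthetic stand-in for MCUGI1 (WP_101156358.1, Macrococcus sp.); constructed, not the native sequence
MMALLLMVMFNMYEMHQDSMYFPLTEFVQLGTDEEDNIVHQIAITEKTESEPYLLNDLLK
NVMADNKEPADGVNASGKHVAKAPSLTIEWETIMASYVDDITQTFHQNLV
>MCUGI2_standin synthetic stand-in for MCUGI2 (WP_101143899.1, Macrococcus sp.); constructed, not the native sequence
MVDSLVNDTKDALKAEHMIPAFVLKEAIDSFEEATPPAATTTNIDVEMMSSMVAKYLQES
SLAQISPLVDGQDQNAMDMWFLVMIDWSIHHTTILLGEYAAAELMTKY
>MBUGI_standin synthetic stand-in for MBUGI (WP_165958605.1, Macrococcus sp.); constructed, not the native sequence
MNGNLFNLNVTLNNFEANTPEGNAESLQNWDEDMAVMHFSDYILKENGENANSGIPIAVI
MKIVDMSSNMWLADASSTEEQIEISEQSEQVLYAHKSNTHAMNEISTKHKALD
>SYUGI_standin synthetic stand-in for SYUGI (WP_052256111.1, Salinicoccus sp. YB14-2); constructed, not the native sequence
MLLEDVTVELHSLVSMANGDEAALNLETIEGMDDSQPDNLLINENQAFMVLMNIVYTQWD
NQLDQPENNDTFIVANVVIKAWQLMKWWMKHIQINIVASKDNKQN
>JMUGI_standin synthetic stand-in for JMUGI (WP_185124884.1, Jeotgalicoccus meleagridis); constructed, not the native sequence
MTQVDIDEEVLSATTYIYPNNNVEHVSKTEETMNPALDDDMTANLYMEEEAMTAKVTHFP
VSVLTAGDKTNVLVKIMGLTNDFMIPLMNKLVMSYINFSSMNMSETQMDIT
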