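>mafb_site_1
tgtctatgctcag
>mafb_site_2
cttttgtgctgtt
>mafb_site_3
ccaaactgctgac
>mafb_site_4
cgtaactgctgac
>mafb_site_5
caaatttgcagac
>mafb_site_6
taaagttgctgaa
>mafb_site_7
catttctgctgac
>mafb_site_8
aggatgtgatgac
>mafb_site_9
tgttgttgctcac
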