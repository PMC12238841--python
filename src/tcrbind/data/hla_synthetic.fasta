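>HLA-A*01:01 synthetic
PYKQCRNNNYICVRPNGVEEMRIMFFGDCHCMYFPYRSSNRTPVKETHLVQGASKINENR
AMDNMKAPYCMIMLDSDFIADIEWNQFFTPRLAYKWSNVITKILRCCADAIGQHQMAGQW
ILCMMASNSIHETRPTNWAKIFRSITGMSALEGLDTEKARTTWFNRSVWTKTIMSDSNPR
CILAYHKYRGISWKTWIMCGIPFYLFHFPAMECIWKYYHAPRWTSPHPYSAPCLQMGVGL
EFFWWSVWTMCRACYQPTPYSNAERDGIFWRPFTT
>HLA-A*02:01 synthetic
PYKQKLDNNYICVRPNGVEEMVIDFFGESSCMYFPYRSSLWTPVKETHNVQGASPINENR
AMLPFKQPPCMIMNDGDFIADIEWLQFFYPRMAPWWSCVITKILRCCADAIGEHQMAGQW
ILCLVASNSIHETRPTNFAKIFRSITYWSALIGLDTEKQRSAWGNRSEWTKTIQSDSNPV
CILAYHPKRGISWKTSIMCGWPFYLFHFPAMECVWKEPHAPRWTSPHPYSPPCLQMGVGL
EFFWWSRQTMCRACYQAQPLSNAERDGIFWRPPTT
>HLA-A*03:01 synthetic
PYAQCNQNNYIWVRPNGYEEMVIMFFGESHKRYFPYRSSYRTWVKETHLVKGASKINTNV
AMLPFKQPWCMIMLDGDFIADIEWNQFFYMRMAYKWSNTITKILRCCADAIGEHQMAGQW
ILCMMASNSIHETRPCNWRDIFRSITYMSALIGLDTEKAHTAWGNRSVWTKTIRSDSNLR
GILAYHKKRGISWKTSSMCGIPFYLFHFPPMECVWKYFHAPRWFSPHPYSPPCLQMGVGL
EGFWWSVWTMCRACYQTTPFSRAERDGIFWRNPTT
>HLA-A*11:01 synthetic
PYKQCLQNNYICVYPNGVEEMVIMFAGESFCMYFPYRSSLRTPVKETKLVQEASYIMENR
VMLPFKQPNCMIMLDGDFIADIEWNQFFYPRMAYKWSNVITKILRCCAGAIGESQMAGQH
ILCMMASNSIHETRRTNWAKWFRHITYMSALIGLDKEKARTAWGNRSVWTKSIISDSNRR
CILAYHKKRGISWKTSIMCGQPKYLFHFPAHECVWKYFHAYRWTSFWNYSPPCLQMGVHR
EFFWVSVWTMCRACYQATPYSNAERDGIFWRPPTT
>HLA-A*24:02 synthetic
PYKQCLQNNYICVRPNGVEEMVIMFFGESHCMYFPSRSSLRAPVKETHLVQGASKWNENR
AYLPFKQPYCMIVKFNDFIADIEWNQFFYPRMKYKWSNVITKIERCCADAIREHQMAGQW
ILCMMASRSIHETRITNWAKICRSITYMSALIGLDFGKARTAWGNRLVWLKTIASDSSPR
CILAYDKKRGISWKTSIMCGIPFYLFHFPAMGCVWKFFHAPRWTSPHPYYPPCLQMGVGL
EFFWMSVWDMCRACIQATPYSNAERDGKFWRPPTT
>HLA-B*07:02 synthetic
PYKQCLQNNQICVRPTFVNEMVIMFFGFSHCMAYPYRSSLRTPVKETHLVQGRSKINENR
AMLPFKQPYCMIMLDGDFIAFIEWNQFFYPRMAYKWSVVITKILRCCADAIGEHQMAGQC
ILCMMASNSIHLTRPTNWAKIFPSITTMSALIYLDTHKARTAWGNRSVWTKTIISDSNPR
CILAYHMKRGISWKKSIMCFIPFYLFHFKAMECVWKYFHAPRWTSPHPYSPPCLQVGLGL
QFFWWSVWTMMRAQQQATPYSEAERDGIFWCPWTT
>HLA-B*08:01 synthetic
PYKQCLQNNYICLRPNGVEEMVIMDFGECHCMYFPYRSSLITPVKETHLVQGASKINENR
AMLPFKQPKCMIMLDGDFCADIEWNQFWYPRMAYKWSNVITKILRCCADAIGEHQMAGQW
ILLMMAQNSFHETRPTNWAQIFRSITNMSALIGLDTEKARTAWGNFHVWTKTIISFSNPR
CILAYHKFRGISWKRSIMCGIPFYLFMFPAMEQVIKYFHAPRWTSPHPRSPPCLLMGVGL
EFMWWSVWTMCRACYAATPYSNAENDKILWRPPTT
>HLA-C*07:01 synthetic
PYKQCLANNRICVRPNGVEEMVIMFFGESHCMYFPYRSDLRTPVKETPWVQGASKINENR
AMHFFCQPYCPIMLDGDFIADDEWNQFFYPRMAYLWSNVITKILRCCADAISEHQMAGQW
ILCMMASNSIHETRPTNWAKIFRSVTYMSMLIFLDTEKARTAWGNRIVWTKTIISDDLPR
RILAYHKTRGISWKTSIMCGIPFYLFHPPAMECVWKYFHAPRWTSPHPYSPPCLMMGTGL
EFFKWSVWTMCRACYGATPYSNALRDGRFPRPPTT
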