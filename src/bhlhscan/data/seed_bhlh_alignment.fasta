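>seed01
TRPGFRWPKWEMENDRFHNNLEWMCRRRKLNHLVPGSALSKASMLAETQRLAKELQNQFE
>seed02
RQGIMCPVKARYEKARRHNMLELERRRMKLNELVPGGALSKASVNMEQIPYIKELQMQVK
>seed03
AEDYPWIWKTIHESVRTHKMIERARRRMGLNELVPGGMLSKAAVLAETIRYIKELQIYVQ
>seed04
VNWMIVFRKVANPDYRRHNMLERERCRMTANELVPGGALSKASVLAETIRYIKELQNQVE
>seed05
TRPGFRWPKWEMENDRRHNMLEREHRRMKLNELVPYGALSDCYWEAETIESIKELQNQVE
>seed06
RQGIMCPVKARYEKARRHNMLKRERRRMKLNRLVPGGALSIASIKAEPIRYIKELNNQVL
>seed07
AEDYPWIWKTIHESVPRHNTLEKERFFMVLNQLVPGGALSPAQVLHETPLYFKELQLTGE
>seed08
VNWMIVFRSVANEDYRTHNMLQRETDSMKENELVPGGALSKASVLAETIRYISELQNGVE
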