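>HUMA human ortholog of PROTA
MGELFNKSAMPDYINKDDSAYLQGKNQSEYFDTKSAILR
>HUMB human ortholog of PROTB
MVSTDNPEAGKGGSTSPLYQDEKMEGVVYADLRAGLNK
>HUMC human ortholog of PROTC
MGGEYTVVMKLDNGGFYLSKEPLNR
>HUMD human ortholog of PROTD
MVDSTLKGGEYTVVMKQSVNR
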