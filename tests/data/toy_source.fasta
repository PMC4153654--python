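>PROTA kinase A-like
MLAGELFNKSAMPDYINKDDSAYLQGKNQSEYFDTKTAILR
>PROTB receptor B-like
MVSTDNPEAGKTSPLYQDEKMEGVVYADLRAGLNK
>PROTC kinase C-like
MGGEYTVVMKLDNGGFYLSKEPLNR
>PROTD kinase D-like
MAVDSTLKGGEYTVVMKQSVNR
>ACTL1 actin-like contaminant protein
MGLSDEIANKAVFPSIVGR
>KRTL1 keratin-like contaminant protein
MTTPELGFNRSLDLDSIIAK
>VTGL1 vitellogenin-like contaminant protein
MEGVNDNEEGFFSARLSPIQNK
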