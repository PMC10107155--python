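name	length_bp
chr1	230218
chr2	813184
chr3	316620
chr4	1531933
chr5	576874
chr6	270161
chr7	1090940
chr8	562643
chr9	439888
chr10	745751
chr11	666816
chr12	1078177
chr13	924431
chr14	784333
chr15	1091291
chr16	948066
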