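Source Target Type
miR200 ZEB1 2
ZEB1 miR200 2
ZEB1 ZEB1 1
SLUG miR200 2
SLUG CDH1 2
ZEB1 CDH1 2
SLUG ZEB1 1
miR200 PDL1 2
PDL1 CDH1 2
ERa66 ERa36 2
ERa36 ERa66 2
ERa66 SLUG 2
SLUG ERa66 2
ERa66 ZEB1 2
ZEB1 ERa66 2
ERa66 PDL1 2
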