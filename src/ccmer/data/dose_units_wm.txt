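mg
g
ml
ug
IU
U
毫克
克
毫升
单位
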