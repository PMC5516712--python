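丸
汤
散
膏
颗粒
口服液
合剂
滴丸
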