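PO
IV
ivgtt
口服
静滴
静脉滴注
静推
肌注
皮下注射
外用
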