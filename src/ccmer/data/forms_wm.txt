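片
胶囊
注射液
缓释片
软膏
滴眼液
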