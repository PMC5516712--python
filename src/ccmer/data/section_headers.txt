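# Admission-note section headers, priority = file order (15 defaults).
主诉
现病史
既往史
个人史
家族史
婚育史
过敏史
手术史
体格检查
辅助检查
实验室检查
入院诊断
初步诊断
诊疗计划
用药情况
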