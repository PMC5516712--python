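# Traditional-Chinese-medicine drug names (default small dictionary).
黄芪
当归
党参
人参
丹参
三七
茯苓
甘草
柴胡
金银花
连翘
板蓝根
枸杞
川贝母
大枣
白芍
红景天
鱼腥草
桂枝
陈皮
半夏
桃仁
红花
大青龙汤
小柴胡汤
六味地黄丸
银翘散
藿香正气水
丹参滴丸
鱼腥草注射液
板蓝根颗粒
甘草片
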