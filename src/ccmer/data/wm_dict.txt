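# Western-medicine drug names (default small dictionary for tests/demos).
左氧氟沙星
氧氟沙星
阿莫西林
头孢拉定
硝苯地平
氨氯地平
地高辛
青霉素
红霉素
万古霉素
环丙沙星
美托洛尔
卡托普利
雷米普利
阿托伐他汀
辛伐他汀
奥美拉唑
兰索拉唑
泮托拉唑
紫杉醇
顺铂
吉非替尼
布洛芬
肝素钠
胰岛素
恩度
维生素A
维生素C
维生素B
葡萄糖
阿司匹林
氯吡格雷
华法林
二甲双胍
多巴胺
曲马多
苯妥英钠
地西泮
卡马西平
替硝唑
甲硝唑
氯沙坦
法莫替丁
西咪替丁
多潘立酮
亚胺培南
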