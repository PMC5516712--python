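# Character -> toneless lowercase pinyin (one reading per character; the
# clinically dominant reading is chosen where a character is polyphonic).
阿	a
啊	a
安	an
氨	an
胺	an
按	an
奥	ao
澳	ao
白	bai
百	bai
板	ban
半	ban
般	ban
伴	ban
包	bao
孢	bao
胞	bao
贝	bei
倍	bei
本	ben
苯	ben
比	bi
吡	bi
便	bian
变	bian
丙	bing
病	bing
并	bing
铂	bo
伯	bo
不	bu
布	bu
步	bu
草	cao
测	ce
侧	ce
查	cha
茶	cha
差	cha
柴	chai
常	chang
陈	chen
晨	chen
持	chi
冲	chong
虫	chong
初	chu
出	chu
川	chuan
船	chuan
醇	chun
纯	chun
次	ci
刺	ci
大	da
丹	dan
单	dan
淡	dan
当	dang
党	dang
岛	dao
道	dao
到	dao
低	di
地	di
滴	di
碘	dian
点	dian
电	dian
定	ding
丁	ding
断	duan
短	duan
对	dui
多	duo
朵	duo
度	du
杜	du
恶	e
鹅	e
恩	en
摁	en
尔	er
二	er
发	fa
法	fa
伐	fa
乏	fa
方	fang
访	fang
非	fei
肺	fei
菲	fei
分	fen
芬	fen
氛	fen
酚	fen
粪	fen
否	fou
夫	fu
氟	fu
福	fu
服	fu
茯	fu
辅	fu
腹	fu
复	fu
敷	fu
付	fu
改	gai
钙	gai
甘	gan
肝	gan
酐	gan
感	gan
干	gan
高	gao
膏	gao
格	ge
个	ge
给	gei
根	gen
跟	gen
功	gong
工	gong
枸	gou
古	gu
骨	gu
瓜	gua
胍	gua
管	guan
冠	guan
规	gui
桂	gui
归	gui
果	guo
过	guo
含	han
汗	han
毫	hao
好	hao
合	he
河	he
红	hong
洪	hong
后	hou
胡	hu
湖	hu
花	hua
华	hua
划	hua
缓	huan
环	huan
患	huan
黄	huang
磺	huang
婚	hun
藿	huo
基	ji
吉	ji
肌	ji
剂	ji
级	ji
即	ji
急	ji
既	ji
计	ji
继	ji
加	jia
家	jia
甲	jia
钾	jia
间	jian
煎	jian
检	jian
见	jian
建	jian
监	jian
件	jian
金	jin
今	jin
进	jin
静	jing
景	jing
经	jing
精	jing
就	jiu
酒	jiu
久	jiu
胶	jiao
交	jiao
结	jie
节	jie
解	jie
卡	ka
咔	ka
抗	kang
颗	ke
科	ke
咳	ke
可	ke
克	ke
口	kou
扣	kou
矿	kuang
况	kuang
拉	la
啦	la
蓝	lan
兰	lan
类	lei
雷	lei
力	li
立	li
利	li
粒	li
莉	li
连	lian
莲	lian
两	liang
良	liang
疗	liao
灵	ling
苓	ling
临	lin
林	lin
磷	lin
六	liu
龙	long
隆	long
洛	luo
罗	luo
络	luo
氯	lv
吗	ma
马	ma
满	man
慢	man
酶	mei
每	mei
美	mei
镁	mei
霉	mei
眠	mian
面	mian
敏	min
民	min
秒	miao
苗	miao
明	ming
莫	mo
末	mo
母	mu
木	mu
钠	na
纳	na
那	na
囊	nang
能	neng
你	ni
尼	ni
泥	ni
年	nian
尿	niao
浓	nong
农	nong
诺	nuo
挪	nuo
呕	ou
欧	ou
盘	pan
泮	pan
潘	pan
培	pei
皮	pi
匹	pi
片	pian
偏	pian
平	ping
瓶	ping
扑	pu
普	pu
葡	pu
七	qi
芪	qi
杞	qi
气	qi
奇	qi
钱	qian
前	qian
青	qing
清	qing
轻	qing
情	qing
氢	qing
翘	qiao
桥	qiao
区	qu
曲	qu
去	qu
染	ran
热	re
人	ren
仁	ren
认	ren
日	ri
入	ru
软	ruan
三	san
散	san
伞	san
沙	sha
杀	sha
山	shan
杉	shan
善	shan
少	shao
芍	shao
舍	she
射	she
深	shen
参	shen
神	shen
肾	shen
升	sheng
生	sheng
时	shi
识	shi
实	shi
食	shi
史	shi
使	shi
示	shi
室	shi
释	shi
适	shi
失	shi
手	shou
搜	sou
嗽	sou
舒	shu
术	shu
述	shu
双	shuang
水	shui
睡	shui
顺	shun
瞬	shun
司	si
四	si
苏	su
素	su
速	su
诉	su
酸	suan
蒜	suan
随	sui
岁	sui
索	suo
锁	suo
所	suo
他	ta
太	tai
台	tai
泰	tai
痰	tan
谈	tan
汤	tang
糖	tang
桃	tao
萄	tao
体	ti
替	ti
提	ti
天	tian
田	tian
甜	tian
停	ting
汀	ting
通	tong
痛	tong
投	tou
头	tou
土	tu
吐	tu
推	tui
托	tuo
妥	tuo
外	wai
万	wan
丸	wan
完	wan
晚	wan
王	wang
往	wang
韦	wei
维	wei
卫	wei
味	wei
位	wei
未	wei
微	wei
温	wen
文	wen
无	wu
五	wu
西	xi
希	xi
息	xi
下	xia
夏	xia
现	xian
显	xian
酰	xian
线	xian
香	xiang
向	xiang
消	xiao
硝	xiao
小	xiao
效	xiao
谢	xie
泻	xie
心	xin
辛	xin
新	xin
腥	xing
星	xing
行	xing
醒	xing
性	xing
需	xu
续	xu
血	xue
学	xue
压	ya
牙	ya
炎	yan
验	yan
眼	yan
阳	yang
杨	yang
氧	yang
样	yang
药	yao
要	yao
液	ye
夜	ye
一	yi
乙	yi
以	yi
异	yi
胰	yi
意	yi
议	yi
义	yi
银	yin
饮	yin
阴	yin
用	yong
又	you
有	you
于	yu
予	yu
余	yu
鱼	yu
欲	yu
育	yu
元	yuan
院	yuan
月	yue
越	yue
云	yun
晕	yun
在	zai
再	zai
枣	zao
早	zao
脏	zang
展	zhan
占	zhan
张	zhang
胀	zhang
转	zhuan
专	zhuan
真	zhen
诊	zhen
正	zheng
症	zheng
支	zhi
枝	zhi
之	zhi
治	zhi
止	zhi
中	zhong
重	zhong
周	zhou
主	zhu
助	zhu
注	zhu
竹	zhu
子	zi
自	zi
紫	zi
族	zu
左	zuo
作	zuo
唑	zuo
佐	zuo
巴	ba
吧	ba
化	hua
案	an
为	wei
南	nan
楠	nan
咪	mi
米	mi
来	lai
莱	lai
殊	shu
物	wu
特	te
者	zhe
脉	mai
麦	mai
英	ying
应	ying
亚	ya
坦	tan
酮	tong
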