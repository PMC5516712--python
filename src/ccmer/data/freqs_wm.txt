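QD
BID
TID
QID
Q.D
QN
每日一次
每日两次
每日三次
一日三次
每晚一次
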