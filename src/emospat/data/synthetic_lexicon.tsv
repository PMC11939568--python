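word	category	subcategory	intensity	polarity
开心	joy	happiness	7	positive
高兴	joy	happiness	5	positive
快乐	joy	happiness	5	positive
幸福	joy	happiness	7	positive
喜悦	joy	happiness	5	positive
兴奋	joy	happiness	7	positive
放心	joy	relief	3	positive
安心	joy	relief	3	positive
欣慰	joy	relief	5	positive
顺利	joy	relief	3	positive
平安	joy	relief	5	positive
胜利	joy	relief	7	positive
康复	joy	relief	5	positive
好转	joy	relief	3	positive
解封	joy	relief	5	positive
清零	joy	relief	5	positive
复课	joy	relief	3	positive
复工	joy	relief	3	positive
鼓掌	joy	happiness	3	positive
笑	joy	happiness	3	positive
哈哈	joy	happiness	3	positive
乐观	joy	happiness	5	positive
感动	like	gratitude	5	positive
感谢	like	gratitude	5	positive
感恩	like	gratitude	5	positive
点赞	like	praise	3	positive
支持	like	praise	3	positive
加油	like	encourage	5	positive
希望	like	wish	5	positive
期待	like	wish	3	positive
自豪	like	praise	7	positive
骄傲	like	praise	5	positive
佩服	like	praise	5	positive
致敬	like	praise	7	positive
温暖	like	fondness	5	positive
美好	like	fondness	5	positive
健康	like	wish	3	positive
祝福	like	wish	5	positive
祈祷	like	wish	3	positive
棒	like	praise	3	positive
赞	like	praise	3	positive
优秀	like	praise	5	positive
给力	like	praise	5	positive
安全	like	fondness	3	positive
信心	like	wish	5	positive
难过	sadness	grief	5	negative
伤心	sadness	grief	5	negative
悲伤	sadness	grief	7	negative
心痛	sadness	grief	7	negative
心碎	sadness	grief	9	negative
哭	sadness	grief	3	negative
流泪	sadness	grief	3	negative
痛苦	sadness	grief	7	negative
绝望	sadness	despair	9	negative
失望	sadness	despair	5	negative
沮丧	sadness	despair	5	negative
无奈	sadness	despair	3	negative
委屈	sadness	grief	5	negative
愤怒	anger	rage	7	negative
生气	anger	rage	5	negative
气愤	anger	rage	7	negative
恼火	anger	rage	5	negative
可恶	anger	blame	5	negative
谴责	anger	blame	5	negative
抗议	anger	blame	5	negative
害怕	fear	dread	5	negative
恐惧	fear	dread	7	negative
恐慌	fear	panic	7	negative
担心	fear	worry	3	negative
担忧	fear	worry	3	negative
焦虑	fear	worry	5	negative
紧张	fear	worry	3	negative
不安	fear	worry	3	negative
崩溃	fear	panic	7	negative
失控	fear	panic	5	negative
严重	fear	worry	3	negative
危险	fear	dread	5	negative
疯狂	fear	panic	3	negative
讨厌	disgust	dislike	5	negative
厌恶	disgust	dislike	7	negative
恶心	disgust	dislike	5	negative
烦	disgust	annoyance	3	negative
烦躁	disgust	annoyance	5	negative
糟糕	disgust	blame	5	negative
垃圾	disgust	blame	7	negative
谣言	disgust	blame	3	negative
隐瞒	disgust	blame	5	negative
混乱	disgust	blame	5	negative
自私	disgust	blame	5	negative
冷漠	disgust	blame	5	negative
震惊	surprise	shock	5	ambiguous
惊讶	surprise	shock	3	ambiguous
意外	surprise	shock	3	ambiguous
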