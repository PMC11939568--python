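emoji	replacement
[拳头]	加油
[加油]	加油
[蜡烛]	祈祷
[泪]	哭
[悲伤]	伤心
[怒]	愤怒
[允悲]	无奈
[赞]	赞
[鼓掌]	鼓掌
[笑cry]	哈哈
[心]	温暖
[作揖]	感谢
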