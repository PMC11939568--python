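的
了
是
我
你
他
她
它
我们
你们
他们
这
那
这个
那个
都
也
就
还
又
在
有
和
与
及
或
吗
吧
啊
呢
么
嘛
什么
怎么
一个
被
让
对
向
把
于
为
到
说
去
来
会
要
能
可以
因为
所以
但是
而且
如果
没有
不
很
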