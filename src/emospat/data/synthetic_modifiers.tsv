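word	kind	weight
不	negation	-1
没有	negation	-1
没	negation	-1
并非	negation	-1
最	degree	2.0
非常	degree	1.75
很	degree	1.5
太	degree	1.25
稍微	degree	0.75
略	degree	0.5
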