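type	family	copies
1	SLMULE18	13
2	SLMULE18	1
2	SLMULE33	1
2	SLMULE46	33
3	SLMULE26	1
3	SLMULE46	4
3	SLMULE57	1
4	SLMULE05	1
4	SLMULE08	1
4	SLMULE26	1
4	SLMULE46	1
5	SLMULE09	1
5	SLMULE24	1
6	SLMULE37	1
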