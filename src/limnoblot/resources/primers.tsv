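label	forward	reverse
Lim-ITS	GMAAGYCTGATCCAGCCATT	TTAKTCACTTGACCCTATAACTTTGA
universal-ITS	TGYACACACCGCCCGT	GGGTTBCCCCATTCRG
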