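start_gen	end_gen	size
124	0	613285
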