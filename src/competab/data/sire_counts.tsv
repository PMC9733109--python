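room	CB	MC	undetermined
113	11	5	3
114	33	3	10
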