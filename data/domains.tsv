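name	start	end
BH3	461	474
KD	2206	2615
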