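ENSMUSG00000064341
ENSMUSG00000064345
ENSMUSG00000064360
ENSMUSG00000064363
ENSMUSG00000065947
ENSMUSG00000064367
ENSMUSG00000064368
ENSMUSG00000064351
ENSMUSG00000064354
ENSMUSG00000064358
ENSMUSG00000064357
ENSMUSG00000064356
ENSMUSG00000064370
ENSMUSG00000064337
ENSMUSG00000064339
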