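4535
4536
4537
4538
4539
4540
4541
4512
4513
4514
4508
4509
4519
4549
4550
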