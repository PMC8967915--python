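17716
17717
17718
17719
17720
17721
17722
17708
17709
17710
17705
17706
17711
17724
17725
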