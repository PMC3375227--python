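>seq1
MKVPEILAQGAT
>seq2
MKVPEILAQGCT
>seq3
MKVPDILAQGAT
>seq4
MKVHEILSQGAT
>seq5
MRVHEILSQGAT
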