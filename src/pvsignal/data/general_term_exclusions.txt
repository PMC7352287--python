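# Administrative / general preferred terms excluded from analysis.
# One term per line; '#' lines are comments. Edit to taste.
off-label use
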