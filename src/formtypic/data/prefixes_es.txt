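# Default Spanish prefix list for orthographic prefix stripping.
# One prefix per line; lines starting with '#' are ignored.
# Purely orthographic matching: known false positives (e.g. "interés") are
# accepted as a limitation of the rule.
in
im
des
dis
anti
re
pre
sub
sobre
contra
super
ultra
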