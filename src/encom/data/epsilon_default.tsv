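type	hydrophilic	acceptor	donor	hydrophobic	aromatic	neutral	neutral_donor	neutral_acceptor
hydrophilic	3	3	3	0.5	1	1	2	2
acceptor	3	0.5	3	0.5	1	1	2	1
donor	3	3	0.5	0.5	1	1	1	2
hydrophobic	0.5	0.5	0.5	2	2	1	1	1
aromatic	1	1	1	2	2	1	1	1
neutral	1	1	1	1	1	1	1	1
neutral_donor	2	2	1	1	1	1	1	1.5
neutral_acceptor	2	1	2	1	1	1	1.5	1
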