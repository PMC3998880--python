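type	hydrophilic	acceptor	donor	hydrophobic	aromatic	neutral	neutral_donor	neutral_acceptor
hydrophilic	1	1	1	1	1	1	1	1
acceptor	1	1	1	1	1	1	1	1
donor	1	1	1	1	1	1	1	1
hydrophobic	1	1	1	1	1	1	1	1
aromatic	1	1	1	1	1	1	1	1
neutral	1	1	1	1	1	1	1	1
neutral_donor	1	1	1	1	1	1	1	1
neutral_acceptor	1	1	1	1	1	1	1	1
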