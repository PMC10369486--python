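# Chothia-style van der Waals radii per element (heavy atoms), Angstrom.
element	radius
C	1.87
N	1.65
O	1.40
S	1.85
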