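"""Phase label constants shared across modules.

LD is the marker-bright liquid-disordered phase; LO the marker-dark
liquid-ordered phase; EXCLUDED marks bins removed by masking, arc-length
filtering, or the boundary guard band.
"""

LO = "LO"
LD = "LD"
EXCLUDED = "EXCLUDED"
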