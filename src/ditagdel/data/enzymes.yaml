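# Built-in restriction enzyme table: recognition sequence (IUPAC, top strand)
# and cut_offset = bases left of the top-strand cut.  Representative 4-, 5-
# and 6-cutters; extend with a user YAML of the same shape.
TaqI:    {recognition: TCGA,   cut_offset: 1}   # T^CGA
MseI:    {recognition: TTAA,   cut_offset: 1}   # T^TAA
DpnII:   {recognition: GATC,   cut_offset: 0}   # ^GATC
Sau3AI:  {recognition: GATC,   cut_offset: 0}
HaeIII:  {recognition: GGCC,   cut_offset: 2}   # GG^CC (blunt)
AluI:    {recognition: AGCT,   cut_offset: 2}
HpaII:   {recognition: CCGG,   cut_offset: 1}   # C^CGG
MspI:    {recognition: CCGG,   cut_offset: 1}
RsaI:    {recognition: GTAC,   cut_offset: 2}
NlaIII:  {recognition: CATG,   cut_offset: 4}   # CATG^
HinfI:   {recognition: GANTC,  cut_offset: 1}   # G^ANTC
DdeI:    {recognition: CTNAG,  cut_offset: 1}
ApoI:    {recognition: RAATTY, cut_offset: 1}
EcoRI:   {recognition: GAATTC, cut_offset: 1}   # G^AATTC
BamHI:   {recognition: GGATCC, cut_offset: 1}
HindIII: {recognition: AAGCTT, cut_offset: 1}
EcoRV:   {recognition: GATATC, cut_offset: 3}   # blunt
PstI:    {recognition: CTGCAG, cut_offset: 5}
NspI:    {recognition: RCATGY, cut_offset: 5}
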