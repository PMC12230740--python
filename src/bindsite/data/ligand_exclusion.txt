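# Component ids treated as biologically irrelevant by default.
# Stand-in for a BioLiP-style crystallisation-artifact list; replace with
# the real artifact list by pointing the config at another file.
# Waters (also excluded unconditionally)
HOH
DOD
WAT
# Buffers and cryoprotectants
GOL   # glycerol
EDO   # ethylene glycol
PEG   # di(hydroxyethyl)ether
PGE   # triethylene glycol
PG4   # tetraethylene glycol
1PE   # pentaethylene glycol
P6G   # hexaethylene glycol
MPD   # 2-methyl-2,4-pentanediol
BME   # beta-mercaptoethanol
DTT   # dithiothreitol
TRS   # tris buffer
EPE   # HEPES
MES   # MES buffer
MOPS  # MOPS buffer
CAC   # cacodylate
IMD   # imidazole
DMS   # dimethyl sulfoxide
ACE   # acetyl group
ACT   # acetate
ACY   # acetic acid
FMT   # formic acid
CIT   # citrate
FLC   # citrate anion
TLA   # tartaric acid
MLI   # malonate
SCN   # thiocyanate
NO3   # nitrate
AZI   # azide
BCT   # bicarbonate
CO3   # carbonate
# Monoatomic ions
NA
K
CL
BR
IOD
F
MG
CA
ZN
MN
FE
FE2
NI
CO
CU
CU1
CD
HG
SO4
PO4
BO3
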