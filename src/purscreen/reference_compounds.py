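"""SMILES of published reference compounds used in similarity analyses.

The three BET bromodomain inhibitors below share the
6-methyl-7-oxo-6,7-dihydro-1H-pyrrolo[2,3-c]pyridine core; ABBV-744 is the
P2Y6 receptor antagonist hit, and the other two were picked as its MACCS
Tanimoto analogs (similarity > 0.60).  Structures were transcribed from the
published 2D depictions / IUPAC names.
"""

# N-ethyl-4-[2-(4-fluoro-2,6-dimethylphenoxy)-5-(2-hydroxypropan-2-yl)phenyl]-
# 6-methyl-7-oxo-6,7-dihydro-1H-pyrrolo[2,3-c]pyridine-2-carboxamide
ABBV_744 = "CCNC(=O)c1cc2c(-c3cc(C(C)(C)O)ccc3Oc3c(C)cc(F)cc3C)cn(C)c(=O)c2[nH]1"

# mivebresib: N-[4-(2,4-difluorophenoxy)-3-(6-methyl-7-oxo-6,7-dihydro-1H-
# pyrrolo[2,3-c]pyridin-4-yl)phenyl]ethanesulfonamide
ABBV_075 = "CCS(=O)(=O)Nc1ccc(Oc2ccc(F)cc2F)c(-c2cn(C)c(=O)c3[nH]ccc23)c1"
MIVEBRESIB = ABBV_075

# 4-[2-(cyclopropylmethoxy)-5-(methanesulfonyl)phenyl]-6-methyl-
# 6,7-dihydro-1H-pyrrolo[2,3-c]pyridin-7-one
INCB_057643 = "CS(=O)(=O)c1ccc(OCC2CC2)c(-c2cn(C)c(=O)c3[nH]ccc23)c1"

REFERENCE_SMILES = {
    "ABBV-744": ABBV_744,
    "mivebresib": MIVEBRESIB,
    "INCB-057643": INCB_057643,
}
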