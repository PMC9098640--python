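# SYNTHETIC placeholder intrinsic-reactivity table (dimensionless, normalized
# relative scale). These values are made up for demonstration and testing only:
# they preserve the qualitative ordering of hydroxyl-radical reactivities
# (aromatic/sulfur types fast, aliphatic slower) but are NOT measurements.
# Supply a measured free-amino-acid reactivity table for real analyses.
restype,reactivity
TRP,1.00
TYR,0.78
PHE,0.60
HIS,0.55
LEU,0.35
ILE,0.33
MET,0.95
CYS,0.85
ARG,0.22
VAL,0.20
PRO,0.18
THR,0.12
LYS,0.12
GLN,0.10
GLU,0.09
ASP,0.08
SER,0.07
ASN,0.07
ALA,0.05
GLY,0.04
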