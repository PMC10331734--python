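# EGFP conjugated-bond name map for bond-length model scoring:
# bondname atom1 atom2
# Assembled from the structural units of the conjugated system: the
# five-membered imidazolidinone ring and its carbonyl, the bridging bond
# pair, the phenolate ring, and the carbonyl-like CZ-OH bond.
C1-N2    C1  N2
N2-CA2   N2  CA2
CA2-C2   CA2 C2
C2-N3    C2  N3
N3-C1    N3  C1
C2-O2    C2  O2
CA2-CB2  CA2 CB2
CB2-CG2  CB2 CG2
CG2-CD1  CG2 CD1
CD1-CE1  CD1 CE1
CE1-CZ   CE1 CZ
CZ-CE2   CZ  CE2
CE2-CD2  CE2 CD2
CD2-CG2  CD2 CG2
CZ-OH    CZ  OH
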