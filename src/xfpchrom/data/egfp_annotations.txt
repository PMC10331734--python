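# EGFP chromophore terminal-atom annotations: atom_name atom_type role terminal_flag
# Only atoms with explicitly documented roles are listed here (the terminal
# amide N-H and carbonyl C-O pair used by the amide_fix charge scheme).
# Cap-group membership and the full per-atom type assignment vary with the
# user's topology and should be supplied in a complete annotation file.
N1 N  chromophore amide_N
H1 H  chromophore amide_H
C3 C  chromophore carbonyl_C
O3 O  chromophore carbonyl_O
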