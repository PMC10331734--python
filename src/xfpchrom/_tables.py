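"""Transcribed parameter data for the seven fluorescent-protein chromophores.

All numeric values are stored as the strings printed in the published
parameter set so that the frcmod emitter reproduces them digit-for-digit.
Sources name the force field each value was drawn from (gaff 1.81,
ff14SB/PARM10, or PARM19).

Sections:
  BOND_ROWS       22 bond parameters      (kcal/mol/A^2, A)
  ANGLE_ROWS      56 angle parameters     (kcal/mol/rad^2, degrees)
  TORSION_ROWS    40 dihedral rows; negative periodicity marks a
                  continuation row of a multi-term torsion (kcal/mol, deg)
  IMPROPER_ROWS   13 improper dihedrals   (kcal/mol, deg; 3rd atom central)
  NONBONDED_ROWS  10 atom types           (g/mol, A^3, A, kcal/mol)
  REGISTRY_ROWS    7 chromophores (EBFP in both HID and HIE histidine forms)
"""

# (type_i, type_j, K_r, r_eq, source)
BOND_ROWS = [
    ("cc", "cd", "500.9", "1.3729", "gaff cc-cd"),
    ("cd", "cd", "419.8", "1.4278", "gaff cd-cd"),
    ("cc", "nc", "441.1", "1.3694", "gaff cc-nc"),
    ("cd", "nc", "525.4", "1.3172", "gaff cd-nc"),
    ("cd", "nd", "441.1", "1.3694", "gaff cd-nd"),
    ("cc", "c", "371.0", "1.4676", "gaff c-cc"),
    ("c", "nd", "416.9", "1.3867", "gaff c-nd"),
    ("cc", "ha", "349.1", "1.0837", "gaff cc-ha"),
    ("cd", "ha", "349.1", "1.0837", "gaff cd-ha"),
    ("cf", "cf", "382.8", "1.4574", "gaff cf-cf"),
    ("cf", "ne", "564.4", "1.2964", "gaff cf-ne"),
    ("cf", "nf", "406.9", "1.3942", "gaff cf-nf"),
    ("c", "nf", "411.2", "1.3909", "gaff c-nf"),
    ("c", "o", "637.7", "1.2183", "gaff c-o"),
    ("cd", "CX", "334.8", "1.5015", "gaff c3-cd"),
    ("nd", "CX", "334.7", "1.4560", "gaff c3-nd"),
    ("cf", "2C", "320.9", "1.5157", "gaff c3-cf"),
    ("ne", "C", "411.2", "1.3909", "gaff c-ne"),
    ("cd", "CC", "419.8", "1.4278", "gaff cd-cd"),
    ("cd", "C*", "419.8", "1.4278", "gaff cd-cd"),
    ("nc", "cf", "525.4", "1.3172", "gaff nc-cd"),
    ("nf", "CX", "334.7", "1.4560", "gaff c3-nd"),
]

# (type_i, type_j, type_k, K_theta, theta_eq, source)
ANGLE_ROWS = [
    ("cc", "nc", "cd", "71.800", "105.490", "gaff cc-nc-cd"),
    ("cc", "c", "cc", "64.600", "115.840", "gaff cc-c-cc"),
    ("cc", "c", "nd", "67.800", "116.240", "gaff cc-c-nd"),
    ("cc", "c", "nf", "69.000", "112.220", "gaff cc-c-nf"),
    ("cc", "c", "o", "69.100", "123.930", "gaff cc-c-o"),
    ("cc", "cd", "ha", "48.500", "121.760", "gaff cc-cd-ha"),
    ("cd", "cd", "cc", "68.200", "114.190", "gaff cc-cd-cd"),
    ("cd", "cc", "nc", "72.200", "111.650", "gaff cd-cc-nc"),
    ("cd", "cd", "ha", "47.100", "121.070", "gaff cd-cd-ha"),
    ("cd", "cc", "ha", "48.500", "121.760", "gaff cd-cc-ha"),
    ("nc", "cd", "nd", "74.000", "115.830", "gaff nc-cd-nd"),
    ("nd", "c", "o", "73.900", "123.180", "gaff nd-c-o"),
    ("nf", "c", "o", "73.000", "125.810", "gaff nf-c-o"),
    ("c", "cc", "cd", "65.100", "121.350", "gaff c-cc-cd"),
    ("c", "cc", "nc", "66.200", "123.320", "gaff c-cc-nc"),
    ("c", "cc", "ha", "46.900", "116.640", "gaff c-cc-ha"),
    ("cf", "cf", "ne", "68.600", "120.790", "gaff cf-cf-ne"),
    ("cf", "cf", "nf", "68.600", "120.790", "gaff cf-cf-ne"),
    ("CX", "cd", "nd", "66.000", "120.950", "gaff c3-cd-nd"),
    ("CX", "cd", "nc", "66.500", "122.410", "gaff c3-cd-nc"),
    ("2C", "cf", "ne", "66.900", "120.680", "gaff c3-cf-ne"),
    ("2C", "cf", "cf", "63.400", "117.120", "gaff c3-cf-cf"),
    ("N", "CX", "cd", "63.000", "110.100", "PARM10 C-CX-N"),
    ("C", "CX", "nd", "63.000", "110.100", "PARM10 C-CX-N"),
    ("C", "CX", "nf", "63.000", "110.100", "PARM10 C-CX-N"),
    ("O", "C", "ne", "80.000", "122.900", "PARM10 N-C-O"),
    ("CX", "C", "ne", "70.000", "116.600", "PARM10 CX-C-N"),
    ("XC", "C", "ne", "70.000", "116.600", "PARM19 XC-C-N"),
    ("H1", "CX", "cd", "50.000", "109.500", "PARM10 C-CX-H1"),
    ("H1", "CX", "nd", "50.000", "109.500", "PARM10 H1-CX-N"),
    ("H1", "CX", "nf", "50.000", "109.500", "PARM10 H1-CX-N"),
    ("3C", "CX", "cd", "63.000", "111.100", "ff14SB C-CX-3C"),
    ("2C", "CX", "cd", "63.000", "111.100", "ff14SB C-CX-2C"),
    ("cf", "2C", "2C", "63.000", "111.100", "ff14SB C-2C-2C"),
    ("cf", "2C", "HC", "50.000", "109.500", "ff14SB C-2C-HC"),
    ("cc", "cd", "CC", "68.200", "114.190", "gaff cc-cd-cd"),
    ("CC", "cd", "ha", "47.100", "121.070", "gaff cd-cd-ha"),
    ("cc", "cd", "C*", "68.200", "114.190", "gaff cc-cd-cd"),
    ("C*", "cd", "ha", "47.100", "121.070", "gaff cd-cd-ha"),
    ("cd", "C*", "CB", "70.00", "128.60", "PARM10 CT-C*-CB"),
    ("cd", "C*", "CW", "70.00", "125.00", "PARM10 CT-C*-CW"),
    ("cd", "CC", "NA", "70.00", "120.00", "PARM10 CT-CC-NA"),
    ("cd", "CC", "CV", "70.00", "120.00", "PARM10 CT-CC-CV"),
    ("cd", "CC", "NB", "70.00", "120.00", "PARM10 CT-CC-NB"),
    ("cd", "CC", "CW", "70.00", "120.00", "PARM10 CT-CC-CW"),
    ("cd", "cd", "cd", "66.600", "120.020", "gaff ca-ca-ca"),
    ("cd", "nd", "CX", "66.700", "120.490", "gaff c-nd-cc"),
    ("cd", "nd", "c", "66.700", "120.490", "gaff c-nd-cc"),
    ("c", "nd", "CX", "66.700", "120.490", "gaff c-nd-cc"),
    ("cf", "nf", "c", "66.500", "120.830", "gaff c2-nf-ca"),
    ("cf", "nf", "CX", "66.500", "120.830", "gaff c2-nf-ca"),
    ("c", "nf", "CX", "66.500", "120.830", "gaff c2-nf-ca"),
    ("cc", "nc", "cf", "71.800", "105.490", "gaff cc-nc-cd"),
    ("nf", "cf", "nc", "70.200", "127.960", "gaff nf-cf-ne"),
    ("cf", "cf", "nc", "68.600", "120.790", "gaff cf-cf-ne"),
    ("C", "ne", "cf", "67.700", "118.530", "gaff c-ne-c2"),
]

# (t1, t2, t3, t4, paths_divisor, V_n/2, phase, periodicity, source)
# A negative periodicity marks a continuation row (AMBER convention):
# the row belongs to the same four-type torsion as the row before it.
TORSION_ROWS = [
    ("X", "cc", "cd", "X", "4", "16.0", "180", "2", "gaff X-cc-cd-X"),
    ("X", "cc", "nc", "X", "2", "9.5", "180", "2", "gaff X-cc-nc-X"),
    ("X", "cc", "c", "X", "4", "11.5", "180", "2", "gaff X-cc-c-X"),
    ("X", "cd", "cd", "X", "4", "16.0", "180", "2", "gaff X-cd-cd-X"),
    ("X", "cd", "nc", "X", "2", "9.5", "180", "2", "gaff X-cd-nc-X"),
    ("X", "cd", "nd", "X", "2", "9.5", "180", "2", "gaff X-cd-nd-X"),
    ("X", "c", "nd", "X", "2", "8.0", "180", "2", "gaff X-c-nd-X"),
    ("X", "c", "nf", "X", "2", "0.4", "180", "2", "gaff X-c-nf-X"),
    ("X", "cf", "nf", "X", "2", "1.6", "180", "2", "gaff X-cf-nf-X"),
    ("X", "cf", "cf", "X", "4", "4.0", "180", "2", "gaff X-cf-cf-X"),
    ("X", "cd", "CC", "X", "4", "16.0", "180", "2", "gaff X-cd-cd-X"),
    ("X", "cd", "C*", "X", "4", "16.0", "180", "2", "gaff X-cd-cd-X"),
    ("X", "C", "ne", "X", "2", "0.4", "180", "2", "gaff X-c-ne-X"),
    ("X", "CX", "cd", "X", "6", "0.0", "0", "3", "gaff X-c3-cd-X"),
    ("X", "CX", "nf", "X", "6", "0.0", "0", "3", "gaff X-c3-n2-X and X-c3-nf-X"),
    ("X", "CX", "nd", "X", "6", "0.0", "0", "3", "gaff X-c3-n2-X and X-c3-nf-X"),
    ("X", "2C", "cf", "X", "6", "0.0", "0", "3", "gaff X-c3-ca-X and X-c3-cc-X"),
    ("X", "cf", "nc", "X", "2", "9.5", "180", "2", "gaff X-cd-nc-X"),
    ("X", "cf", "ne", "X", "2", "8.3", "180", "2", "gaff X-c2-ne-X and X-c2-n2-X"),
    ("cd", "CX", "3C", "CT", "1", "0.112", "0", "-4", "ff14SB C-CX-3C-CT"),
    ("cd", "CX", "3C", "CT", "1", "0.148", "0", "-3", "component 2"),
    ("cd", "CX", "3C", "CT", "1", "0.289", "180", "-2", "component 3"),
    ("cd", "CX", "3C", "CT", "1", "0.406", "180", "1", "component 4"),
    ("cd", "CX", "3C", "OH", "1", "0.156", "0", "-4", "ff14SB C-CX-3C-OH"),
    ("cd", "CX", "3C", "OH", "1", "0.315", "0", "-3", "component 2"),
    ("cd", "CX", "3C", "OH", "1", "0.119", "180", "-2", "component 3"),
    ("cd", "CX", "3C", "OH", "1", "0.697", "180", "1", "component 4"),
    ("cd", "CX", "2C", "OH", "1", "0.129", "0", "-4", "ff14SB C-CX-2C-OH"),
    ("cd", "CX", "2C", "OH", "1", "0.401", "0", "-3", "component 2"),
    ("cd", "CX", "2C", "OH", "1", "0.218", "180", "-2", "component 3"),
    ("cd", "CX", "2C", "OH", "1", "0.661", "180", "1", "component 4"),
    ("cf", "2C", "2C", "HC", "1", "0.160", "0", "3", "ff14SB CX-2C-2C-HC"),
    ("cf", "2C", "2C", "C", "1", "0.138", "0", "-4", "ff14SB CX-2C-2C-C"),
    ("cf", "2C", "2C", "C", "1", "0.412", "180", "-3", "component 2"),
    ("cf", "2C", "2C", "C", "1", "0.083", "0", "-2", "component 3"),
    ("cf", "2C", "2C", "C", "1", "0.196", "180", "1", "component 4"),
    ("cf", "2C", "2C", "S", "1", "0.028", "0", "-4", "ff14SB CX-2C-2C-S"),
    ("cf", "2C", "2C", "S", "1", "0.016", "0", "-3", "component 2"),
    ("cf", "2C", "2C", "S", "1", "0.245", "0", "-2", "component 3"),
    ("cf", "2C", "2C", "S", "1", "0.417", "0", "1", "component 4"),
]

# (t1, t2, t3, t4, V_n/2, phase, periodicity, source); third atom is central
IMPROPER_ROWS = [
    ("X", "X", "c", "o", "10.5", "180", "2", "gaff X-X-c-o and PARM10 X-X-C-O"),
    ("X", "X", "cc", "ha", "1.1", "180", "2", "sp2 center"),
    ("X", "X", "cd", "ha", "1.1", "180", "2", "sp2 center"),
    ("c", "cd", "nd", "CX", "1.1", "180", "2", "sp2 center"),
    ("c", "cf", "nf", "CX", "1.1", "180", "2", "sp2 center"),
    ("cf", "ne", "cf", "2C", "1.1", "180", "2", "sp2 center"),
    ("nd", "nc", "cd", "CX", "1.1", "180", "2", "sp2 center"),
    ("nf", "nc", "cf", "cf", "1.1", "180", "2", "sp2 center"),
    ("cd", "cd", "cd", "cd", "1.1", "180", "2", "sp2 center"),
    ("nc", "c", "cc", "cd", "1.1", "180", "2", "sp2 center"),
    ("NA", "CV", "CC", "cd", "1.1", "180", "2", "PARM10 CT-CV-CC-NA"),
    ("NB", "CW", "CC", "cd", "1.1", "180", "2", "PARM10 CT-CW-CC-NB"),
    ("CW", "CB", "C*", "cd", "1.1", "180", "2", "PARM10 CB-CT-C*-CW"),
]

# (atom_type, mass, polarizability, R*, epsilon)
NONBONDED_ROWS = [
    ("nd", "14.01", "0.530", "1.8240", "0.1700"),
    ("nc", "14.01", "0.530", "1.8240", "0.1700"),
    ("ne", "14.01", "0.530", "1.8240", "0.1700"),
    ("nf", "14.01", "0.530", "1.8240", "0.1700"),
    ("cc", "12.01", "0.360", "1.9080", "0.0860"),
    ("cd", "12.01", "0.360", "1.9080", "0.0860"),
    ("cf", "12.01", "0.360", "1.9080", "0.0860"),
    ("c", "12.01", "0.616", "1.9080", "0.0860"),
    ("ha", "1.008", "0.135", "1.4590", "0.0150"),
    ("o", "16.00", "0.434", "1.6612", "0.2100"),
]

# (protein_name, tripeptide, pdb_chromophore_code, reference_pdb_id, net_charge)
REGISTRY_ROWS = [
    ("EGFP", "TYG", "CRO", "2Y0G", -1),
    ("EBFP-HID", "SHG", "IIC", "1BFP", 0),
    ("EBFP-HIE", "SHG", "IIC", "1BFP", 0),
    ("ECFP", "TWG", "CRF", "2WSN", 0),
    ("EYFP", "GYG", "CR2", "3V3D", -1),
    ("DsRed", "QYG", "CRQ", "2VAD", -1),
    ("mCherry", "MYG", "CH6", "2H5Q", -1),
]

TRIPEPTIDE_NAMES = {
    "EGFP": "Thr-Tyr-Gly",
    "EBFP-HID": "Ser-His-Gly",
    "EBFP-HIE": "Ser-His-Gly",
    "ECFP": "Thr-Trp-Gly",
    "EYFP": "Gly-Tyr-Gly",
    "DsRed": "Gln-Tyr-Gly",
    "mCherry": "Met-Tyr-Gly",
}
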