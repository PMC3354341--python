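"""Bundled model data: the structure-motif SCFG and its published weights.

The default model ships as data so no training database is needed: the
54-rule SCFG with its exact rational rule probabilities (relative
frequencies trained on an SSU/LSU rRNA secondary-structure database), the
105-rule reweighting-normal-form grammar derived from it, the 4-decimal
rounded weights of that grammar, and the integer weights obtained with the
common denominators s = c = 10000.

Probabilities are stored as (numerator, denominator) pairs and never as
floats.  Chain nonterminals introduced by the normal-form transformation are
named ``A_{X,via}`` for a collapsed derivation chain A => ... => X through
the intermediate nonterminals spelled in ``via`` (``ε`` when direct).
"""

# 26 nonterminals of the motif grammar, in listing order; axiom S'.
GSTO_HAT_NONTERMINALS = [
    "S'", "E", "S", "T", "C", "A", "L", "G", "D", "B", "F", "H", "P",
    "Q", "R", "V", "W", "O", "J", "K", "M", "X", "Y", "Z", "N", "U",
]

# (premise, conclusion tokens, probability numerator, denominator);
# rule ids are 1-based listing positions.
GSTO_HAT_RULES = [
    ("S'", "E", 1, 1),                 # 1
    ("E", "S", 137, 6476),             # 2
    ("E", "S C", 6339, 6476),          # 3
    ("S", "A", 177, 12952),            # 4
    ("S", "T A", 12775, 12952),        # 5
    ("T", "E", 11086, 12775),          # 6
    ("T", "C", 1689, 12775),           # 7
    ("C", "|", 14367, 148978),         # 8
    ("C", "C |", 134611, 148978),      # 9
    ("A", "( L )", 1, 1),              # 10
    ("L", "A", 605069, 792975),        # 11
    ("L", "M", 31912, 792975),         # 12
    ("L", "P", 4912, 264325),          # 13
    ("L", "Q", 5821, 158595),          # 14
    ("L", "R", 1893, 264325),          # 15
    ("L", "F", 2723, 31719),           # 16
    ("L", "G", 38399, 792975),         # 17
    ("G", "A |", 11667, 38399),        # 18
    ("G", "A D", 7235, 38399),         # 19
    ("G", "| A", 11831, 38399),        # 20
    ("G", "D A", 7666, 38399),         # 21
    ("D", "B |", 1, 1),                # 22
    ("B", "|", 4967, 12748),           # 23
    ("B", "B |", 7781, 12748),         # 24
    ("F", "| | |", 3912, 68075),       # 25
    ("F", "| | | |", 23208, 68075),    # 26
    ("F", "| | | | H", 8191, 13615),   # 27
    ("H", "|", 8191, 40700),           # 28
    ("H", "H |", 32509, 40700),        # 29
    ("P", "| A |", 533, 4912),         # 30
    ("P", "| A | |", 1053, 4912),      # 31
    ("P", "| | A |", 2963, 14736),     # 32
    ("P", "| | A | |", 7015, 14736),   # 33
    ("Q", "| | O | |", 4986, 29105),   # 34
    ("Q", "| | V |", 24119, 29105),    # 35
    ("R", "| O | |", 2357, 5679),      # 36
    ("R", "| | W |", 3322, 5679),      # 37
    ("V", "J O", 1, 1),                # 38
    ("W", "J A", 1, 1),                # 39
    ("O", "A K", 1, 1),                # 40
    ("J", "|", 27441, 84620),          # 41
    ("J", "J |", 57179, 84620),        # 42
    ("K", "|", 15731, 53725),          # 43
    ("K", "K |", 37994, 53725),        # 44
    ("M", "X Y", 1, 1),                # 45
    ("X", "A", 6196, 87035),           # 46
    ("X", "U A", 80839, 87035),        # 47
    ("Y", "Z", 1, 1),                  # 48
    ("Z", "X", 2812, 55123),           # 49
    ("Z", "X N", 52311, 55123),        # 50
    ("N", "Z", 7737, 17437),           # 51
    ("N", "U", 9700, 17437),           # 52
    ("U", "|", 109939, 518817),        # 53
    ("U", "U |", 408878, 518817),      # 54
]

# 3-decimal published roundings of the 54 probabilities (units of 1e-3).
TABLE2_WEIGHTS_E3 = [
    1000, 21, 979, 14, 986, 868, 132, 96, 904, 1000,
    763, 40, 19, 37, 7, 86, 48, 304, 188, 308,
    200, 1000, 390, 610, 57, 341, 602, 201, 799, 109,
    214, 201, 476, 171, 829, 415, 585, 1000, 1000, 1000,
    324, 676, 293, 707, 1000, 71, 929, 1000, 51, 949,
    444, 556, 212, 788,
]

# Nonterminals of the normal-form grammar: 22 surviving originals plus the
# 32 chain symbols, in listing order.
GSTO_STAR_NONTERMINALS = [
    "S'", "E", "S", "C", "A", "G", "D", "B", "F", "H", "P", "Q", "R",
    "V", "W", "O", "J", "K", "M", "X", "Z", "U",
    "E_{S,ε}", "E_{A,S}", "S_{A,ε}",
    "T_{E,ε}", "T_{C,ε}", "T_{|,C}", "T_{S,E}", "T_{A,ES}",
    "C_{|,ε}",
    "L_{A,ε}", "L_{M,ε}", "L_{P,ε}", "L_{Q,ε}", "L_{R,ε}", "L_{F,ε}", "L_{G,ε}",
    "B_{|,ε}", "H_{|,ε}", "J_{|,ε}", "K_{|,ε}",
    "X_{A,ε}", "Y_{Z,ε}", "Y_{X,Z}", "Y_{A,ZX}", "Z_{X,ε}", "Z_{A,X}",
    "N_{Z,ε}", "N_{U,ε}", "N_{|,U}", "N_{X,Z}", "N_{A,ZX}", "U_{|,ε}",
]

# (premise, conclusion tokens); rules 1..73 are the main productions, rules
# 74..105 the weight-1 chain rules.
GSTO_STAR_RULES = [
    ("S'", "E"),                        # 1
    ("S'", "E_{S,ε}"),                  # 2
    ("S'", "E_{A,S}"),                  # 3
    ("E", "S C"),                       # 4
    ("E", "S_{A,ε} C"),                 # 5
    ("E", "S C_{|,ε}"),                 # 6
    ("E", "S_{A,ε} C_{|,ε}"),           # 7
    ("S", "T_{E,ε} A"),                 # 8
    ("S", "T_{C,ε} A"),                 # 9
    ("S", "T_{|,C} A"),                 # 10
    ("S", "T_{S,E} A"),                 # 11
    ("S", "T_{A,ES} A"),                # 12
    ("C", "C |"),                       # 13
    ("C", "C_{|,ε} |"),                 # 14
    ("A", "( L_{A,ε} )"),               # 15
    ("A", "( L_{M,ε} )"),               # 16
    ("A", "( L_{P,ε} )"),               # 17
    ("A", "( L_{Q,ε} )"),               # 18
    ("A", "( L_{R,ε} )"),               # 19
    ("A", "( L_{F,ε} )"),               # 20
    ("A", "( L_{G,ε} )"),               # 21
    ("G", "A |"),                       # 22
    ("G", "A D"),                       # 23
    ("G", "| A"),                       # 24
    ("G", "D A"),                       # 25
    ("D", "B |"),                       # 26
    ("D", "B_{|,ε} |"),                 # 27
    ("B", "B |"),                       # 28
    ("B", "B_{|,ε} |"),                 # 29
    ("F", "| | |"),                     # 30
    ("F", "| | | |"),                   # 31
    ("F", "| | | | H"),                 # 32
    ("F", "| | | | H_{|,ε}"),           # 33
    ("H", "H |"),                       # 34
    ("H", "H_{|,ε} |"),                 # 35
    ("P", "| A |"),                     # 36
    ("P", "| A | |"),                   # 37
    ("P", "| | A |"),                   # 38
    ("P", "| | A | |"),                 # 39
    ("Q", "| | O | |"),                 # 40
    ("Q", "| | V |"),                   # 41
    ("R", "| O | |"),                   # 42
    ("R", "| | W |"),                   # 43
    ("V", "J O"),                       # 44
    ("V", "J_{|,ε} O"),                 # 45
    ("W", "J A"),                       # 46
    ("W", "J_{|,ε} A"),                 # 47
    ("O", "A K"),                       # 48
    ("O", "A K_{|,ε}"),                 # 49
    ("J", "J |"),                       # 50
    ("J", "J_{|,ε} |"),                 # 51
    ("K", "K |"),                       # 52
    ("K", "K_{|,ε} |"),                 # 53
    ("M", "X Y_{Z,ε}"),                 # 54
    ("M", "X Y_{X,Z}"),                 # 55
    ("M", "X Y_{A,ZX}"),                # 56
    ("M", "X_{A,ε} Y_{Z,ε}"),           # 57
    ("M", "X_{A,ε} Y_{X,Z}"),           # 58
    ("M", "X_{A,ε} Y_{A,ZX}"),          # 59
    ("X", "U A"),                       # 60
    ("X", "U_{|,ε} A"),                 # 61
    ("Z", "X N_{Z,ε}"),                 # 62
    ("Z", "X N_{U,ε}"),                 # 63
    ("Z", "X N_{|,U}"),                 # 64
    ("Z", "X N_{X,Z}"),                 # 65
    ("Z", "X N_{A,ZX}"),                # 66
    ("Z", "X_{A,ε} N_{Z,ε}"),           # 67
    ("Z", "X_{A,ε} N_{U,ε}"),           # 68
    ("Z", "X_{A,ε} N_{|,U}"),           # 69
    ("Z", "X_{A,ε} N_{X,Z}"),           # 70
    ("Z", "X_{A,ε} N_{A,ZX}"),          # 71
    ("U", "U |"),                       # 72
    ("U", "U_{|,ε} |"),                 # 73
    ("E_{S,ε}", "S"),                   # 74
    ("E_{A,S}", "A"),                   # 75
    ("S_{A,ε}", "A"),                   # 76
    ("T_{E,ε}", "E"),                   # 77
    ("T_{C,ε}", "C"),                   # 78
    ("T_{|,C}", "|"),                   # 79
    ("T_{S,E}", "S"),                   # 80
    ("T_{A,ES}", "A"),                  # 81
    ("C_{|,ε}", "|"),                   # 82
    ("L_{A,ε}", "A"),                   # 83
    ("L_{M,ε}", "M"),                   # 84
    ("L_{P,ε}", "P"),                   # 85
    ("L_{Q,ε}", "Q"),                   # 86
    ("L_{R,ε}", "R"),                   # 87
    ("L_{F,ε}", "F"),                   # 88
    ("L_{G,ε}", "G"),                   # 89
    ("B_{|,ε}", "|"),                   # 90
    ("H_{|,ε}", "|"),                   # 91
    ("J_{|,ε}", "|"),                   # 92
    ("K_{|,ε}", "|"),                   # 93
    ("X_{A,ε}", "A"),                   # 94
    ("Y_{Z,ε}", "Z"),                   # 95
    ("Y_{X,Z}", "X"),                   # 96
    ("Y_{A,ZX}", "A"),                  # 97
    ("Z_{X,ε}", "X"),                   # 98
    ("Z_{A,X}", "A"),                   # 99
    ("N_{Z,ε}", "Z"),                   # 100
    ("N_{U,ε}", "U"),                   # 101
    ("N_{|,U}", "|"),                   # 102
    ("N_{X,Z}", "X"),                   # 103
    ("N_{A,ZX}", "A"),                  # 104
    ("U_{|,ε}", "|"),                   # 105
]

# Published 4-decimal weights of rules 1..73, stored in units of 1e-4.
TABLE5_WEIGHTS_E4 = [
    10000, 212, 3,                      # S'
    9788, 134, 944, 13,                 # E
    8559, 1304, 126, 181, 2,            # S
    9036, 871,                          # C
    7630, 402, 186, 367, 72, 858, 484,  # A
    3038, 1884, 3081, 1996,             # G
    10000, 3896,                        # D
    6104, 2378,                         # B
    575, 3409, 6016, 1211,              # F
    7987, 1608,                         # H
    1085, 2144, 2011, 4760,             # P
    1713, 8287,                         # Q
    4150, 5850,                         # R
    10000, 3243,                        # V
    10000, 3243,                        # W
    10000, 2928,                        # O
    6757, 2191,                         # J
    7072, 2071,                         # K
    10000, 510, 36, 712, 36, 3,         # M
    9288, 1968,                         # X
    4211, 5279, 1119, 215, 15, 300, 376, 80, 15, 1,  # Z
    7881, 1670,                         # U
]

# Published integer weights of rules 1..73 (s = c = 10000).
TABLE6_WEIGHTS = [
    10000, 212, 3,
    9788, 134, 944, 13,
    8559, 1304, 126, 181, 2,
    9036, 871,
    76300000, 4020000, 1860000, 3670000, 720000, 8580000, 4840000,
    3038, 1884, 3081, 1996,
    10000, 3896,
    6104, 2378,
    5750000, 340900000000, 6016000000000000, 1211000000000000,
    7987, 1608,
    10850000, 214400000000, 201100000000, 4760000000000000,
    1713000000000000, 828700000000,
    415000000000, 585000000000,
    10000, 3243,
    10000, 3243,
    10000, 2928,
    6757, 2191,
    7072, 2071,
    10000, 510, 36, 712, 36, 3,
    9288, 1968,
    4211, 5279, 1119, 215, 15, 300, 376, 80, 15, 1,
    7881, 1670,
]
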