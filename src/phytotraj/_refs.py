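"""Reference angles of the synthetic bilin world (degrees, unwrapped).

These constants fix the stated world shared by the generators and the
state classifier: the resting Pfr geometry (ZZEssa), the Lumi-F starting
geometry reached by the ccw hula twist of D6 with cw D5 counter-rotation,
and the windows that make the BV-Pr / BV-Pr' / BV-Pr'' taxonomy
operational.  All are package conventions; the underlying taxonomy is
qualitative.
"""

# Pfr resting geometry (D1..D6); stereo code ZZEssa.
PFR_ANGLES = {"D1": 10.0, "D2": 5.0, "D3": -8.0, "D4": 5.0, "D5": 160.0, "D6": 180.0}

# End of the reactive excited-state phase (Lumi-F entry): D6 has rotated
# ccw through 90 deg to the Z region, D5 has counter-rotated cw by the
# hula-twist amplitude.
HULA_D5_AMPLITUDE = 60.0           # cw D5 rotation during the excited phase
LUMI_START_D5 = PFR_ANGLES["D5"] + HULA_D5_AMPLITUDE   # 220
LUMI_START_D6 = 0.0

# Relaxed-photoproduct windows (unwrapped on the branch reached by the
# continued cw D5 rotation; wrapped equivalents in parentheses).
PR_D5_CENTER = 260.0               # (-100 wrapped): synthetic Pr reference for D5
PR_D5_HALFWIDTH = 30.0
PFR_D5_HALFWIDTH = 30.0
D5_INTERMEDIATE = (200.0, 230.0)   # between the Pfr and Pr windows
D6_PR_HALFWIDTH = 90.0             # Z region
PLANARITY_TOL = 20.0               # |theta| within this of 0 or 180 counts planar
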