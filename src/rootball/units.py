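"""Central unit table.

Conventions used throughout the package:

===========  =====
quantity     unit
===========  =====
depth        mm
area         cm^2
length       cm
diameter     um
volume       cm^3
===========  =====
"""

MM_PER_CM = 10.0
UM_PER_CM = 1.0e4
MM2_PER_CM2 = 100.0


def mm_to_cm(x: float) -> float:
    return x / MM_PER_CM


def mm2_to_cm2(x: float) -> float:
    return x / MM2_PER_CM2


def cm_to_um(x: float) -> float:
    return x * UM_PER_CM


def um_to_cm(x: float) -> float:
    return x / UM_PER_CM
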