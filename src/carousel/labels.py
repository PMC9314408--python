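"""Strategy label vocabulary.

Five stereotyped behaviours discovered in the rotating-arena place-avoidance
task, plus the ``unidentified`` bin used when the voting ensemble draws.
"""

THIGMOTAXIS = "thigmotaxis"   # wall-following along the arena periphery
INCURSION = "incursion"       # excursions from the wall into the inner arena
FOCUSED = "focused"           # movement confined to a room-frame region away from the sector
CHAINING = "chaining"         # near-stationary animal passively carried by the rotation
AVOIDANCE = "avoidance"       # active angular retreat from the sector boundary

STRATEGIES = (THIGMOTAXIS, INCURSION, FOCUSED, CHAINING, AVOIDANCE)

UNIDENTIFIED = "unidentified"

ALL_LABELS = STRATEGIES + (UNIDENTIFIED,)
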