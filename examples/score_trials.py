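"""Score a single preferential-looking trial.

Builds a 10 s trial by hand — the infant starts on the no-change display,
releases fixation after the first change, and settles on the changing
display — and prints the four looking measures.
"""

import numpy as np

from gazecog import TaskConfig
from gazecog.gaze_io import GazeTrial
from gazecog import looking

# (t_ms, AOI) segments: right display changes, infant starts left
segments = [(0, "left"), (1600, "away"), (2100, "right"),
            (5200, "left"), (6000, "right")]
t = np.array([s[0] for s in segments], dtype=float)
aoi = np.array([s[1] for s in segments], dtype=object)
trial = GazeTrial("infant01", year=1, trial_index=0, t_ms=t, aoi=aoi,
                  source_used="video", load=2, load_level="medium",
                  change_side="right")

cfg = TaskConfig()
print("first look:        ", looking.classify_first_look(trial, cfg))
print("change preference: ", round(looking.change_preference(trial, cfg), 3))
print("shift rate (1/s):  ", round(looking.shift_rate(trial, cfg), 3))
print("LookingWindow1:    ", round(looking.looking_window1(trial, cfg), 3))
print("away fraction:     ", round(looking.away_fraction(trial, cfg), 3))

# The first look (at the 1000 ms change onset) is to the left, no-change
# display; the change preference is the share of on-display time spent on
# the changing display inside the 1750-6750 ms window, and the shift rate
# counts switches between displays per second of on-display looking.
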