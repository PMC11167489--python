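"""Closure and isometric log-ratio coordinates of a day's time budget.

A day's minutes of Sleep, SB, LPA and MVPA only carry relative
information, so they are treated as a composition: rescaled (closed) to
a 1440-min day, expressed as %/day, and mapped to three ILR balance
coordinates that live on the real line and can enter ordinary models.
"""

import numpy as np

from actiprofile import closure, compositional_mean, ilr_inverse, ilr_transform

# A participant's averaged day: 7 h 30 min sleep, 10 h SB, 4 h 40 min LPA,
# 80 min MVPA — a 1410-min recorded day (days are rarely exactly 24 h).
raw_minutes = np.array([450.0, 600.0, 280.0, 80.0])
closed = closure(raw_minutes, 1440.0)
pct = closure(raw_minutes, 100.0)
print("closed to 1440 min:", np.round(closed, 2))
print("as %/day:          ", np.round(pct, 2))

coords = ilr_transform(pct)
print("ILR coordinates:   ", np.round(coords, 4))
# ilr1 balances MVPA against everything else (negative: MVPA is a small
# share); ilr2 balances SB against LPA+Sleep (positive: SB dominates);
# ilr3 balances LPA against Sleep (negative: less LPA than sleep).

back = ilr_inverse(coords, kappa=100.0)
print("inverse ILR:       ", np.round(back, 2), "(round-trips exactly)")

# The compositional mean of a sample is the part-wise geometric mean,
# re-closed — equivalently the inverse ILR of the mean ILR vector.
sample = np.array([[29.0, 45.0, 20.0, 6.0], [31.0, 42.0, 19.5, 7.5], [30.0, 44.0, 20.0, 6.0]])
print("compositional mean:", np.round(compositional_mean(sample, kappa=100.0), 2))
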